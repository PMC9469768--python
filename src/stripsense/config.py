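"""Run configuration: every pipeline tunable in one validated schema.

Loaded from / saved to YAML; validated with pydantic before any processing.
Defaults reproduce the package's standard study conditions.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class BalanceConfig(BaseModel):
    white_threshold: float = Field(200.0, gt=0, lt=255, description="min-channel threshold for white-pixel selection")
    white_variant: str = Field("gain", description="white-reference scaling: 'gain' (255/white) or 'reciprocal'")


class FiducialConfig(BaseModel):
    blur_sigma: float = Field(1.2, ge=0, description="Gaussian blur sigma before edge detection")
    canny_low: float = Field(0.05, description="Canny low threshold (normalized luminance)")
    canny_high: float = Field(0.2, description="Canny high threshold")


class RectangleConfig(BaseModel):
    min_area: float = Field(20000.0, gt=0, description="min filled area (design-frame px^2)")
    aspect_min: float = Field(1.5, gt=0)
    aspect_max: float = Field(5.0, gt=0)
    max_mean_luminance: float = Field(90.0, description="darkness gate on candidate components")


class StripConfig(BaseModel):
    aspect_min: float = Field(4.0, gt=0)
    aspect_max: float = Field(12.0, gt=0)


class PadConfig(BaseModel):
    total_frac: float = Field(0.10, ge=0, le=1, description="total pad center, fraction of strip length from top")
    free_frac: float = Field(0.45, ge=0, le=1, description="free pad center, fraction of strip length from top")
    side_frac: float = Field(0.64, gt=0, le=1, description="sampled pad square side as a fraction of strip width (inset from the physical pad to avoid edge spill)")
    min_pixels: int = Field(20, ge=1, description="minimum pixel count inside the pad circle")
    orientation: str = Field("up", description="'up' (total pad at strip top) or 'down'")


class ModelConfig(BaseModel):
    family: str = Field("polynomial_sq", description="calibration family to fit/use")
    use_published: bool = Field(False, description="use the built-in paper-2022 coefficients instead of fitting")
    train_fraction: float = Field(0.67, gt=0, le=1)


class RunConfig(BaseModel):
    seed: int = Field(0, ge=0)
    scheme: str = Field("multiclass", description="tier scheme for reports: 'binary' or 'multiclass'")
    balance: BalanceConfig = BalanceConfig()
    fiducial: FiducialConfig = FiducialConfig()
    rectangle: RectangleConfig = RectangleConfig()
    strip: StripConfig = StripConfig()
    pad: PadConfig = PadConfig()
    model: ModelConfig = ModelConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
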