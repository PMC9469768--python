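"""Geometry of the standard background shared by the renderer and the detector.

All dimensions are in pixels of the design canvas (the canonical frame that
photo alignment maps every image into).  Coordinates are 0-based (row, col).
The printed card carries a QR-style fiducial block (three nested-square
finder patterns) and a black rectangle about three times the strip width, so
the strip can be placed with some lateral slack.  The card's absolute
dimensions and the fiducial placement are design choices of this package and
are exposed here for configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Layout:
    canvas_shape: tuple[int, int] = (768, 1024)  # (rows, cols), landscape

    # fiducial block: white square carrying three finder patterns
    block_origin: tuple[int, int] = (130, 100)   # (row, col) of top-left
    block_size: int = 160
    finder_size: int = 56                        # 7 modules x 8 px
    finder_margin: int = 10                      # inset of finders from block edge

    # black rectangle on which the strip sits
    rect_origin: tuple[int, int] = (100, 560)
    rect_shape: tuple[int, int] = (580, 200)     # (height, width); width ~ 3x strip

    # test strip (vertical, inside the rectangle)
    strip_length: int = 500
    strip_width: int = 66
    strip_top_row: int = 140

    # pads: squares centered on the strip axis at fractions of strip length
    pad_side: int = 50
    total_pad_frac: float = 0.10
    free_pad_frac: float = 0.45

    # colors (single channel value for neutral surfaces)
    background_value: float = 128.0
    paper_white: float = 215.0                   # strip body and block background
    ink_dark: float = 20.0                       # finder pattern ink
    rect_dark: float = 22.0

    # capture condition emulation
    cast_gains: dict = field(
        default_factory=lambda: {
            "neutral": (1.0, 1.0, 1.0),
            "warm": (1.15, 1.0, 0.87),
            "cool": (0.87, 1.0, 1.15),
        }
    )
    resolution_budgets: dict = field(
        default_factory=lambda: {"high": 1024, "mid": 640, "low": 320}
    )
    low_res_pixelation: float = 0.5              # extra down/up pixelation at low res
    tilt_focal_factor: float = 2.0               # pinhole focal length, x long edge
    max_tilt_deg: float = 10.0

    @property
    def strip_col_center(self) -> float:
        r0, c0 = self.rect_origin
        return c0 + self.rect_shape[1] / 2.0

    def block_corners(self) -> np.ndarray:
        """Fiducial block corners (row, col), order TL, TR, BR, BL."""
        r0, c0 = self.block_origin
        s = self.block_size
        return np.array(
            [[r0, c0], [r0, c0 + s], [r0 + s, c0 + s], [r0 + s, c0]], dtype=float
        )

    def rect_corners(self) -> np.ndarray:
        r0, c0 = self.rect_origin
        h, w = self.rect_shape
        return np.array(
            [[r0, c0], [r0, c0 + w], [r0 + h, c0 + w], [r0 + h, c0]], dtype=float
        )

    def finder_origins(self) -> dict[str, tuple[int, int]]:
        """Block-local (row, col) of each finder pattern's top-left corner."""
        m, f, s = self.finder_margin, self.finder_size, self.block_size
        return {
            "tl": (m, m),
            "tr": (m, s - m - f),
            "bl": (s - m - f, m),
        }

    def pad_center_rows(self, flipped: bool = False) -> dict[str, float]:
        top, length = self.strip_top_row, self.strip_length
        total = top + self.total_pad_frac * length
        free = top + self.free_pad_frac * length
        if flipped:
            bottom = top + length
            total, free = bottom - self.total_pad_frac * length, bottom - self.free_pad_frac * length
        return {"total": total, "free": free}


DEFAULT_LAYOUT = Layout()
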