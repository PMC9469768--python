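"""End-to-end orchestration: photo in, concentration tier out.

The per-photo chain is: gray-world balance the whole photo, locate the
fiducial and rectify into the canonical frame, find the black rectangle,
crop to the strip, white-reference balance the crop against the strip body,
place the pads, and sample each pad's mean RGB inside its inscribed circle.
A calibration model then maps the free pad's color to a concentration, which
is binned into binary and multiclass tiers (negative predictions land in the
lowest bin).  Content failures never raise: each photo carries a status and
the failing stage, and batch summaries tally failures by stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, classify, geometry, whitebalance
from .calibration import FittedModel
from .config import RunConfig
from .geometry import PadSample, ProcessingFailure


@dataclass
class PhotoResult:
    source: str
    status: str                                  # "ok" | "failed"
    failure_stage: str | None = None
    message: str = ""
    free_sample: PadSample | None = None
    total_sample: PadSample | None = None
    concentration: float | None = None
    binary_tier: str | None = None
    multiclass_tier: str | None = None
    model_id: str = ""

    def as_dict(self) -> dict:
        d = {
            "source": self.source,
            "status": self.status,
            "failure_stage": self.failure_stage,
            "message": self.message,
            "concentration": self.concentration,
            "binary_tier": self.binary_tier,
            "multiclass_tier": self.multiclass_tier,
            "model_id": self.model_id,
        }
        for name, sample in (("free", self.free_sample), ("total", self.total_sample)):
            if sample is not None:
                d[f"{name}_r"], d[f"{name}_g"], d[f"{name}_b"] = sample.rgb
                d[f"{name}_pixels"] = sample.pixel_count
        return d


def extract_pads(img: np.ndarray, config: RunConfig, source: str = "") -> tuple[PadSample, PadSample] | ProcessingFailure:
    """Run the geometric chain and return (free, total) pad samples."""
    try:
        balanced = whitebalance.gray_world_balance(img)
    except whitebalance.BalanceError as exc:
        return ProcessingFailure("fiducial", f"unbalanceable image: {exc}")
    fid = geometry.detect_fiducial(
        balanced,
        blur_sigma=config.fiducial.blur_sigma,
        canny_thresholds=(config.fiducial.canny_low, config.fiducial.canny_high),
    )
    if isinstance(fid, ProcessingFailure):
        return fid
    try:
        aligned = geometry.align_photo(balanced, fid)
    except geometry.GeometryError as exc:
        return ProcessingFailure("fiducial", f"alignment failed: {exc}")
    rect = geometry.detect_black_rectangle(
        aligned,
        min_area=config.rectangle.min_area,
        aspect_bounds=(config.rectangle.aspect_min, config.rectangle.aspect_max),
        max_mean_luminance=config.rectangle.max_mean_luminance,
    )
    if isinstance(rect, ProcessingFailure):
        return rect
    strip = geometry.crop_strip(
        aligned, rect, aspect_bounds=(config.strip.aspect_min, config.strip.aspect_max)
    )
    if isinstance(strip, ProcessingFailure):
        return strip
    mask = whitebalance.select_white_pixels(strip.image, config.balance.white_threshold)
    try:
        ref = whitebalance.white_reference_from_mask(strip.image, mask)
        strip_balanced = whitebalance.white_reference_balance(
            strip.image, ref, variant=config.balance.white_variant
        )
    except whitebalance.BalanceError as exc:
        return ProcessingFailure("strip", f"white reference failed: {exc}")
    pads = geometry.locate_pads(
        strip,
        total_frac=config.pad.total_frac,
        free_frac=config.pad.free_frac,
        pad_side_frac=config.pad.side_frac,
        orientation=config.pad.orientation,
    )
    if isinstance(pads, ProcessingFailure):
        return pads
    free_region, total_region = pads
    samples = []
    for region in (free_region, total_region):
        try:
            samples.append(
                geometry.extract_mean_rgb(
                    strip_balanced,
                    region.circle_center,
                    region.radius,
                    min_pixels=config.pad.min_pixels,
                    source=source,
                    identity=region.identity,
                )
            )
        except geometry.GeometryError as exc:
            return ProcessingFailure("pad", f"{region.identity} pad extraction failed: {exc}")
    return samples[0], samples[1]


def process_photo(path_or_img, config: RunConfig | None = None, model: FittedModel | None = None) -> PhotoResult:
    """Process one photo (path or array) into a PhotoResult; never raises on content."""
    config = config or RunConfig()
    source = str(path_or_img) if isinstance(path_or_img, (str, Path)) else "<array>"
    if isinstance(path_or_img, (str, Path)):
        img = whitebalance.load_image(path_or_img)  # unreadable file: let it raise
    else:
        img = np.asarray(path_or_img, dtype=np.float64)
    result = extract_pads(img, config, source=source)
    if isinstance(result, ProcessingFailure):
        return PhotoResult(source=source, status="failed", failure_stage=result.stage, message=result.message)
    free, total = result
    if model is None:
        if config.model.use_published:
            model = calibration.published_model(config.model.family)
        else:
            return PhotoResult(
                source=source, status="ok", free_sample=free, total_sample=total,
                message="no calibration model supplied; colors extracted only",
            )
    conc = calibration.predict_concentration(model, free)
    return PhotoResult(
        source=source,
        status="ok",
        free_sample=free,
        total_sample=total,
        concentration=conc,
        binary_tier=classify.bin_concentration(conc, classify.BINARY),
        multiclass_tier=classify.bin_concentration(conc, classify.MULTICLASS),
        model_id=model.notes.get("source", model.family),
    )


@dataclass
class BatchReport:
    results: list[PhotoResult]
    summary: pd.DataFrame = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.results])


def summarize_failures(results: list[PhotoResult]) -> pd.DataFrame:
    """Per-stage failure counts and percentages for a batch."""
    n = len(results)
    rows = []
    for stage in geometry.STAGES:
        k = sum(1 for r in results if r.status == "failed" and r.failure_stage == stage)
        rows.append({"stage": stage, "failures": k, "percent": 100.0 * k / n if n else 0.0})
    failed = sum(1 for r in results if r.status == "failed")
    rows.append({"stage": "total", "failures": failed, "percent": 100.0 * failed / n if n else 0.0})
    return pd.DataFrame(rows)


def process_batch(paths, config: RunConfig | None = None, model: FittedModel | None = None) -> BatchReport:
    """Process many photos; one PhotoResult each plus a per-stage failure summary."""
    paths = list(paths)
    if not paths:
        raise ValueError("no images to process")
    results = [process_photo(p, config, model) for p in paths]
    return BatchReport(results=results, summary=summarize_failures(results))


def extract_calibration_rows(
    manifest: pd.DataFrame, images_dir, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run extraction over a manifest of labeled photos.

    Returns (rows, failures): rows has columns r, g, b, concentration, group
    for every successfully processed photo; failures records skipped photos
    by stage, mirroring a field campaign's processing-failure accounting.
    """
    config = config or RunConfig()
    images_dir = Path(images_dir)
    rows, fails = [], []
    for rec in manifest.to_dict("records"):
        res = process_photo(images_dir / rec["file"], config, model=None)
        if res.status == "ok":
            rows.append(
                {
                    "file": rec["file"],
                    "r": res.free_sample.mean_r,
                    "g": res.free_sample.mean_g,
                    "b": res.free_sample.mean_b,
                    "concentration": float(rec["concentration"]),
                    "group": rec.get("group", 0),
                }
            )
        else:
            fails.append({"file": rec["file"], "stage": res.failure_stage, "message": res.message})
    return pd.DataFrame(rows), pd.DataFrame(fails)


def train(
    rows: pd.DataFrame, config: RunConfig | None = None, seed: int | None = None
) -> dict:
    """Stratified split, fit the configured family, evaluate both binnings.

    ``rows`` is a calibration table (r, g, b, concentration, group).  Returns
    a dict with the fitted model, the split, and train/test metric reports
    for the binary and multiclass schemes.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    train_rows, test_rows = classify.stratified_split(rows, config.model.train_fraction, seed=seed)
    fit_func = calibration.FIT_FUNCS[config.model.family]
    model = fit_func(train_rows)
    out: dict = {"model": model, "train_rows": train_rows, "test_rows": test_rows, "metrics": {}}
    for split_name, split_rows in (("train", train_rows), ("test", test_rows)):
        preds = [predict_row(model, rec) for rec in split_rows.to_dict("records")]
        for scheme in (classify.BINARY, classify.MULTICLASS):
            true_tiers = [classify.bin_concentration(c, scheme) for c in split_rows["concentration"]]
            pred_tiers = [classify.bin_concentration(p, scheme) for p in preds]
            cm = classify.confusion(true_tiers, pred_tiers, scheme)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out["metrics"][(split_name, scheme)] = classify.metrics(cm)
            out.setdefault("confusions", {})[(split_name, scheme)] = cm
    return out


def predict_row(model: FittedModel, rec: dict) -> float:
    return calibration.predict_concentration(model, (rec["r"], rec["g"], rec["b"]))


def save_report(report: BatchReport, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out_dir / "photo_results.csv", index=False)
    report.summary.to_csv(out_dir / "failure_summary.csv", index=False)
    (out_dir / "photo_results.json").write_text(
        json.dumps([r.as_dict() for r in report.results], indent=2)
    )
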