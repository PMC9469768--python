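"""Seeded synthetic renderer of test-strip photographs with full ground truth.

Each scene shows a free/total chlorine test strip lying on the standard
background: a mid-gray card carrying a black rectangle (about three times the
strip width) and a QR-style fiducial block built from three nested-square
finder patterns.  The renderer emulates the capture conditions of a phone
photo campaign — three lighting casts (neutral / warm / cool, applied as
per-channel gains), three camera resolution levels, a small perspective tilt,
and Gaussian pixel noise — and returns pixel-exact ground truth (geometry,
pad colors, concentration tier) alongside every image.

The concentration-to-color model is piecewise-linear interpolation of
per-channel anchors.  Anchors are placed so that each tier's mean channel
values sit at the midpoints of the observed per-tier channel ranges (red
193-122, 182-133, 170-98; green 193-125, 170-111, 146-57; blue 179-135,
175-128, 170-114 for tiers <=0.2, 0.2-0.5, >0.5 mg/L), and so that the mean
RGB sum decreases strictly with concentration over 0-4 mg/L — lighter pads
mean less chlorine.  Per-pad Gaussian color noise is truncated to the tier's
channel bounds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import ProjectiveTransform, resize, warp

from .classify import MULTICLASS, bin_concentration
from .layout import DEFAULT_LAYOUT, Layout
from .whitebalance import save_image

LIGHTING_CASTS = ("neutral", "warm", "cool")
RESOLUTION_LEVELS = ("low", "mid", "high")

#: Per-tier channel bounds (min, max) observed per channel.
TIER_CHANNEL_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "le_0.2": {"r": (122.0, 193.0), "g": (125.0, 193.0), "b": (135.0, 179.0)},
    "mid_0.2_0.5": {"r": (133.0, 182.0), "g": (111.0, 170.0), "b": (128.0, 175.0)},
    "gt_0.5": {"r": (98.0, 170.0), "g": (57.0, 146.0), "b": (114.0, 170.0)},
}

#: Anchor concentrations (mg/L) and per-channel anchor values.  Tier-midpoint
#: anchors sit at 0.1, 0.35 and 1.0 mg/L; the channel sums (517, 473.5, 464,
#: 449.5, 429, 377.5, 330, 276) are strictly decreasing, so the piecewise
#: linear interpolant's RGB sum is strictly decreasing on [0, 4].
ANCHOR_CONCENTRATIONS = (0.0, 0.1, 0.2, 0.35, 0.5, 1.0, 2.0, 4.0)
ANCHOR_VALUES = {
    "r": (175.0, 157.5, 160.0, 157.5, 150.0, 134.0, 120.0, 100.0),
    "g": (180.0, 159.0, 150.0, 140.5, 130.0, 101.5, 80.0, 60.0),
    "b": (162.0, 157.0, 154.0, 151.5, 149.0, 142.0, 130.0, 116.0),
}


@dataclass(frozen=True)
class ColorModel:
    """Concentration -> pad color mapping with per-tier truncation bounds."""

    tier_bounds: dict = field(default_factory=lambda: dict(TIER_CHANNEL_BOUNDS))
    anchor_c: tuple = ANCHOR_CONCENTRATIONS
    anchors: dict = field(default_factory=lambda: dict(ANCHOR_VALUES))
    color_noise_sd: float = 6.0  # per-channel pad color variation between strips

    def mean_rgb(self, c: float) -> np.ndarray:
        """Noiseless interpolated pad color at concentration c (clamped at 4)."""
        if c < 0:
            raise ValueError("concentration must be >= 0")
        cc = min(c, self.anchor_c[-1])
        return np.array(
            [np.interp(cc, self.anchor_c, self.anchors[ch]) for ch in ("r", "g", "b")]
        )


def concentration_to_pad_color(c: float, model: ColorModel, seed: int) -> tuple[float, float, float]:
    """Draw a pad color for concentration c: anchor mean + truncated Gaussian noise.

    Deterministic for a fixed seed; with ``color_noise_sd == 0`` the anchor
    color is returned exactly.  Noise is clipped to the channel bounds of the
    concentration's tier, so the drawn color always classifies into the tier
    it was generated for.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    mean = model.mean_rgb(c)
    tier = bin_concentration(c, MULTICLASS)
    bounds = model.tier_bounds[tier]
    rng = np.random.default_rng(seed)
    noisy = mean + rng.normal(0.0, model.color_noise_sd, size=3)
    out = []
    for v, ch in zip(noisy, ("r", "g", "b")):
        lo, hi = bounds[ch]
        out.append(float(np.clip(v, lo, hi)))
    return tuple(out)


@dataclass(frozen=True)
class SceneSpec:
    """Capture conditions for one rendered scene."""

    concentration: float
    lighting_cast: str = "neutral"
    resolution_level: str = "high"
    tilt_deg: float = 0.0
    noise_sd: float = 2.0          # pixel noise, color-value units
    seed: int = 0
    lateral_offset_px: float = 0.0  # strip offset within the rectangle
    flip_strip: bool = False        # render with the total pad at the bottom

    def validate(self, layout: Layout) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lighting_cast not in layout.cast_gains:
            raise ValueError(f"unknown lighting cast {self.lighting_cast!r}")
        if self.resolution_level not in layout.resolution_budgets:
            raise ValueError(f"unknown resolution level {self.resolution_level!r}")
        if abs(self.tilt_deg) > layout.max_tilt_deg:
            raise ValueError(f"|tilt_deg| must be <= {layout.max_tilt_deg}")
        if abs(self.lateral_offset_px) > (layout.rect_shape[1] - layout.strip_width) / 2 - 2:
            raise ValueError("strip offset does not fit inside the rectangle")


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene, in final image pixel coordinates."""

    concentration: float
    tier: str
    pad_rgb_free: tuple[float, float, float]    # true pad color before lighting/noise
    pad_rgb_total: tuple[float, float, float]
    pad_rgb_free_ref: tuple[float, float, float]  # same color in reference-white coords
    pad_rgb_total_ref: tuple[float, float, float]
    fiducial_corners: np.ndarray                # 4x2 (row, col), TL TR BR BL
    rectangle_corners: np.ndarray
    strip_bbox: tuple[float, float, float, float]  # (row0, col0, row1, col1)
    pad_centers: dict[str, tuple[float, float]]
    scale: float                                # final px per design px
    design_fiducial_corners: np.ndarray         # canonical-frame geometry (pre-tilt)
    design_rectangle_corners: np.ndarray
    design_strip_bbox: tuple[float, float, float, float]
    design_pad_centers: dict[str, tuple[float, float]]


class _TiltModel:
    """Pinhole perspective of the card plane rotated about its horizontal axis."""

    def __init__(self, tilt_deg: float, shape: tuple[int, int], focal_factor: float):
        self.theta = np.deg2rad(tilt_deg)
        self.h, self.w = shape
        self.f = focal_factor * max(shape)

    def apply(self, points_rc: np.ndarray) -> np.ndarray:
        """Map (row, col) design points to tilted-image points."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        yc = pts[:, 0] - self.h / 2.0
        xc = pts[:, 1] - self.w / 2.0
        y3 = yc * np.cos(self.theta)
        z3 = yc * np.sin(self.theta)
        denom = self.f + z3
        out = np.column_stack([y3 * self.f / denom + self.h / 2.0, xc * self.f / denom + self.w / 2.0])
        return out if points_rc.ndim == 2 else out[0]

    def transform(self) -> ProjectiveTransform:
        """skimage transform ((x, y) convention) equivalent to :meth:`apply`."""
        src_rc = np.array(
            [[0, 0], [0, self.w - 1], [self.h - 1, self.w - 1], [self.h - 1, 0]], dtype=float
        )
        dst_rc = self.apply(src_rc)
        tf = ProjectiveTransform.from_estimate(src_rc[:, ::-1], dst_rc[:, ::-1])
        if not tf:
            raise RuntimeError("tilt transform estimation failed")
        return tf


def _draw_finder(canvas: np.ndarray, r0: int, c0: int, size: int, ink: float, paper: float) -> None:
    u = size // 7
    canvas[r0 : r0 + size, c0 : c0 + size] = ink
    canvas[r0 + u : r0 + size - u, c0 + u : c0 + size - u] = paper
    canvas[r0 + 2 * u : r0 + size - 2 * u, c0 + 2 * u : c0 + size - 2 * u] = ink


def render_scene(
    spec: SceneSpec, model: ColorModel | None = None, layout: Layout = DEFAULT_LAYOUT
) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene and its ground truth.

    Processing order: draw the design-resolution scene, apply the lighting
    cast (per-channel gains), warp by the perspective tilt, add pixel noise,
    then degrade to the requested resolution level.
    """
    model = model or ColorModel()
    spec.validate(layout)
    rng = np.random.default_rng(spec.seed)
    h, w = layout.canvas_shape
    canvas = np.full((h, w, 3), layout.background_value, dtype=np.float64)

    # fiducial block
    br, bc = layout.block_origin
    s = layout.block_size
    canvas[br : br + s, bc : bc + s] = layout.paper_white
    for r_off, c_off in layout.finder_origins().values():
        _draw_finder(canvas, br + r_off, bc + c_off, layout.finder_size, layout.ink_dark, layout.paper_white)

    # black rectangle
    rr, rc = layout.rect_origin
    rh, rw = layout.rect_shape
    canvas[rr : rr + rh, rc : rc + rw] = layout.rect_dark

    # strip
    col_center = layout.strip_col_center + spec.lateral_offset_px
    sc0 = int(round(col_center - layout.strip_width / 2))
    sc1 = sc0 + layout.strip_width
    sr0 = layout.strip_top_row
    sr1 = sr0 + layout.strip_length
    canvas[sr0:sr1, sc0:sc1] = layout.paper_white

    # pads: child seeds keep color draws independent of pixel noise draws
    pad_seed_free = int(rng.integers(0, 2**31 - 1))
    pad_seed_total = int(rng.integers(0, 2**31 - 1))
    pad_rgb_free = concentration_to_pad_color(spec.concentration, model, pad_seed_free)
    pad_rgb_total = concentration_to_pad_color(spec.concentration, model, pad_seed_total)
    pad_rows = layout.pad_center_rows(flipped=spec.flip_strip)
    pad_centers = {}
    for name, color in (("free", pad_rgb_free), ("total", pad_rgb_total)):
        prow = pad_rows[name]
        half = layout.pad_side / 2
        pr0, pr1 = int(round(prow - half)), int(round(prow + half))
        pc0 = int(round(col_center - half))
        canvas[pr0:pr1, pc0 : pc0 + layout.pad_side] = color
        pad_centers[name] = ((pr0 + pr1) / 2.0, pc0 + layout.pad_side / 2.0)

    # lighting cast
    gains = np.array(layout.cast_gains[spec.lighting_cast])
    canvas = canvas * gains

    # perspective tilt
    tilt = _TiltModel(spec.tilt_deg, (h, w), layout.tilt_focal_factor)
    if abs(spec.tilt_deg) > 1e-9:
        tf = tilt.transform()
        canvas = warp(
            canvas, tf.inverse, output_shape=(h, w), order=1,
            cval=layout.background_value, mode="constant", preserve_range=True,
        )
        map_pts = tilt.apply
    else:
        map_pts = lambda p: np.asarray(p, dtype=float)

    # pixel noise
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)

    # resolution degradation
    budget = layout.resolution_budgets[spec.resolution_level]
    scale = budget / max(h, w)
    out_shape = (int(round(h * scale)), int(round(w * scale)))
    if out_shape != (h, w):
        canvas = resize(canvas, out_shape, anti_aliasing=True, preserve_range=True)
    if spec.resolution_level == "low" and layout.low_res_pixelation < 1.0:
        small = (
            max(1, int(round(out_shape[0] * layout.low_res_pixelation))),
            max(1, int(round(out_shape[1] * layout.low_res_pixelation))),
        )
        canvas = resize(canvas, small, anti_aliasing=True, preserve_range=True)
        canvas = resize(canvas, out_shape, order=0, anti_aliasing=False, preserve_range=True)
    canvas = np.clip(canvas, 0.0, 255.0)

    # ground truth in final pixel coordinates
    def final(points: np.ndarray) -> np.ndarray:
        return map_pts(np.asarray(points, dtype=float)) * scale

    strip_quad = np.array([[sr0, sc0], [sr0, sc1], [sr1, sc1], [sr1, sc0]], dtype=float)
    strip_warped = final(strip_quad)
    strip_bbox = (
        float(strip_warped[:, 0].min()), float(strip_warped[:, 1].min()),
        float(strip_warped[:, 0].max()), float(strip_warped[:, 1].max()),
    )
    ref_gain = 255.0 / layout.paper_white
    truth = SceneTruth(
        concentration=spec.concentration,
        tier=bin_concentration(spec.concentration, MULTICLASS),
        pad_rgb_free=pad_rgb_free,
        pad_rgb_total=pad_rgb_total,
        pad_rgb_free_ref=tuple(v * ref_gain for v in pad_rgb_free),
        pad_rgb_total_ref=tuple(v * ref_gain for v in pad_rgb_total),
        fiducial_corners=final(layout.block_corners()),
        rectangle_corners=final(layout.rect_corners()),
        strip_bbox=strip_bbox,
        pad_centers={k: tuple(final(np.array(v))) for k, v in pad_centers.items()},
        scale=scale,
        design_fiducial_corners=layout.block_corners(),
        design_rectangle_corners=layout.rect_corners(),
        design_strip_bbox=(float(sr0), float(sc0), float(sr1), float(sc1)),
        design_pad_centers=pad_centers,
    )
    return canvas, truth


def sample_concentrations(n: int, rng: np.random.Generator,
                          group_weights: dict[int, tuple[tuple[float, float], int]] | None = None
                          ) -> list[tuple[float, int]]:
    """Draw n (concentration, group) pairs with the campaign's group proportions.

    Groups partition (0, 4] mg/L as (0, 0.125], (0.125, 0.2], (0.2, 0.5],
    (0.5, 1], (1, 2], (2, 4]; counts are apportioned to the groups'
    published photo-count proportions (largest remainder), and concentrations
    are uniform within each group's interval.
    """
    if group_weights is None:
        from .reference import PUBLISHED_GROUPS

        group_weights = {g: (iv, total) for g, (iv, total, _train) in PUBLISHED_GROUPS.items()}
    groups = sorted(group_weights)
    weights = np.array([group_weights[g][1] for g in groups], dtype=float)
    quotas = weights / weights.sum() * n
    counts = np.floor(quotas).astype(int)
    for idx in np.argsort(-(quotas - counts), kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    out: list[tuple[float, int]] = []
    for g, k in zip(groups, counts):
        (lo, hi), _ = group_weights[g]
        for _ in range(k):
            out.append((float(rng.uniform(lo, hi)), g))
    return out


def make_dataset(
    n: int,
    out_dir,
    spec_template: SceneSpec | None = None,
    concentration_grid: list[float] | None = None,
    seed: int = 0,
    model: ColorModel | None = None,
    layout: Layout = DEFAULT_LAYOUT,
    casts: tuple[str, ...] = ("neutral",),
    resolutions: tuple[str, ...] = ("high",),
) -> "pd.DataFrame":
    """Render n scenes to PNG plus a ground-truth CSV manifest.

    Concentrations come from ``concentration_grid`` (cycled) if given,
    otherwise they are sampled with the published campaign's six-group
    proportions.  Casts and resolution levels are cycled across scenes.
    Reproducible given ``seed``: the same seed yields a byte-identical
    manifest.
    """
    import pandas as pd  # local: keep module import light

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or ColorModel()
    template = spec_template or SceneSpec(concentration=0.0)
    rng = np.random.default_rng(seed)
    if concentration_grid is not None:
        pairs = [(float(concentration_grid[i % len(concentration_grid)]), _group_of(concentration_grid[i % len(concentration_grid)])) for i in range(n)]
    else:
        pairs = sample_concentrations(n, rng)
    rows = []
    for i, (c, group) in enumerate(pairs):
        spec = replace(
            template,
            concentration=c,
            lighting_cast=casts[i % len(casts)],
            resolution_level=resolutions[i % len(resolutions)],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, truth = render_scene(spec, model, layout)
        fname = f"scene_{i:04d}.png"
        save_image(img, out_dir / fname)
        rows.append(
            {
                "file": fname,
                "concentration": round(c, 6),
                "group": group,
                "tier": truth.tier,
                "cast": spec.lighting_cast,
                "resolution": spec.resolution_level,
                "tilt_deg": spec.tilt_deg,
                "seed": spec.seed,
                "pad_r": round(truth.pad_rgb_free[0], 3),
                "pad_g": round(truth.pad_rgb_free[1], 3),
                "pad_b": round(truth.pad_rgb_free[2], 3),
                "fiducial_corners": ";".join(
                    f"{r:.2f},{c_:.2f}" for r, c_ in truth.fiducial_corners
                ),
                "rectangle_corners": ";".join(
                    f"{r:.2f},{c_:.2f}" for r, c_ in truth.rectangle_corners
                ),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    return manifest


def _group_of(c: float) -> int:
    from .reference import PUBLISHED_GROUPS

    for g, ((lo, hi), _, _) in PUBLISHED_GROUPS.items():
        if lo < c <= hi:
            return g
    return 1 if c <= 0 else 6
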