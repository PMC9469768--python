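"""Fiducial localization, alignment, rectangle/strip detection, pad extraction.

The processing chain locates the QR-style fiducial block (three nested-square
finder patterns), uses it to rectify the photo into the canonical design
frame, finds the black rectangle, isolates the bright strip inside it,
places the two colorimetric pads at known fractions of the strip length, and
samples each pad's mean RGB inside the largest circle inscribed in the pad
polygon.  Every stage returns a typed :class:`ProcessingFailure` instead of
raising on bad photo content, so batch runs can tally failures by stage.

Detection is contour-based: Gaussian blur, Canny edge detection as a
content gate, and marching-squares contours at an Otsu level.  A finder
pattern is recognized by its nesting signature — three concentric closed
contours (ring outer boundary, ring inner boundary, core) with the area
ratios of nested squares — rather than by decoding any QR payload.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage import measure
from skimage.feature import canny
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import ProjectiveTransform, warp

from .layout import DEFAULT_LAYOUT, Layout

STAGES = ("fiducial", "rectangle", "strip", "pad")


class GeometryError(ValueError):
    """Degenerate geometric input (collinear corners, zero-area polygon, ...)."""


@dataclass(frozen=True)
class ProcessingFailure:
    stage: str
    message: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")


@dataclass(frozen=True)
class Quad:
    """Four corners (row, col), canonical order TL, TR, BR, BL."""

    corners: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise GeometryError("Quad needs 4 (row, col) corners")
        object.__setattr__(self, "corners", c)
        if self.area() <= 1e-9:
            raise GeometryError("degenerate quadrilateral (zero area / collinear)")
        if not Polygon(c[:, ::-1]).is_valid:
            raise GeometryError("self-intersecting quadrilateral")

    def area(self) -> float:
        c = np.asarray(self.corners, dtype=float)
        x, y = c[:, 1], c[:, 0]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @staticmethod
    def from_points(points: np.ndarray) -> "Quad":
        """Canonicalize 4 points into TL, TR, BR, BL order (near-axis-aligned)."""
        pts = np.asarray(points, dtype=float)
        s = pts[:, 0] + pts[:, 1]
        d = pts[:, 0] - pts[:, 1]
        tl = pts[np.argmin(s)]
        br = pts[np.argmax(s)]
        tr = pts[np.argmin(d)]
        bl = pts[np.argmax(d)]
        return Quad(np.array([tl, tr, br, bl]))


def _corner_points(contour: np.ndarray) -> np.ndarray:
    """Subpixel corners of a near-axis-aligned square contour, TL TR BR BL.

    Marching-squares contours round off square corners, so extreme points
    alone are biased inward.  Instead, contour points are assigned to the
    four sides (excluding a margin around each rough corner), a total
    least-squares line is fitted per side, and adjacent side lines are
    intersected.
    """
    s = contour[:, 0] + contour[:, 1]
    d = contour[:, 0] - contour[:, 1]
    rough = np.array(
        [contour[np.argmin(s)], contour[np.argmin(d)], contour[np.argmax(s)], contour[np.argmax(d)]]
    )
    side_len = np.median(np.linalg.norm(np.roll(rough, -1, axis=0) - rough, axis=1))
    margin = 0.18 * side_len
    lines = []
    for k in range(4):
        a, b = rough[k], rough[(k + 1) % 4]
        ab = b - a
        nrm = np.linalg.norm(ab)
        t = (contour - a) @ ab / nrm**2
        rel = contour - a
        dist = np.abs(ab[0] * rel[:, 1] - ab[1] * rel[:, 0]) / nrm
        sel = contour[(t > margin / nrm) & (t < 1 - margin / nrm) & (dist < 0.15 * side_len)]
        if len(sel) < 2:
            sel = np.array([a, b])
        centroid = sel.mean(axis=0)
        _, _, vt = np.linalg.svd(sel - centroid)
        direction = vt[0]
        lines.append((centroid, direction))
    corners = []
    for k in range(4):
        (p1, d1), (p2, d2) = lines[(k - 1) % 4], lines[k]
        mat = np.column_stack([d1, -d2])
        if abs(np.linalg.det(mat)) < 1e-9:
            corners.append(rough[k])
            continue
        t1, _ = np.linalg.solve(mat, p2 - p1)
        corners.append(p1 + t1 * d1)
    return np.array(corners)


def _luminance(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64).mean(axis=2)


def _closed_contours(gray: np.ndarray, level: float) -> list[np.ndarray]:
    out = []
    for c in measure.find_contours(gray, level):
        if len(c) >= 8 and np.hypot(*(c[0] - c[-1])) < 2.0:
            out.append(c)
    return out


def _contour_stats(c: np.ndarray) -> tuple[np.ndarray, float]:
    poly = Polygon(c[:, ::-1])
    if not poly.is_valid or poly.area <= 0:
        return c.mean(axis=0), 0.0
    cx, cy = poly.centroid.x, poly.centroid.y
    return np.array([cy, cx]), poly.area


def _find_finder_patterns(gray: np.ndarray, level: float) -> list[dict]:
    """Nested-contour signature: outer ring, inner ring boundary, core.

    Returns one record per detected finder pattern with the outer contour,
    its centroid and its area.  Area ratios of a 7-5-3 nested square are
    49 : 25 : 9; generous bands tolerate blur and resampling.
    """
    contours = _closed_contours(gray, level)
    stats = [(_contour_stats(c), c) for c in contours]
    stats = [(cen, area, c) for (cen, area), c in stats if area > 10]
    stats.sort(key=lambda t: -t[1])
    patterns = []
    used: set[int] = set()
    for i, (cen_i, area_i, c_i) in enumerate(stats):
        if i in used:
            continue
        tol = 0.25 * np.sqrt(area_i)
        nested = []
        for j, (cen_j, area_j, c_j) in enumerate(stats):
            if j == i or j in used:
                continue
            if area_j < area_i and np.hypot(*(cen_i - cen_j)) < tol:
                nested.append((area_j, j))
        if len(nested) < 2:
            continue
        nested.sort(reverse=True)
        (a_mid, j_mid), (a_core, j_core) = nested[0], nested[-1]
        # ratios for ideal 7:5:3 squares: mid/outer = 25/49 ~ 0.51, core/outer = 9/49 ~ 0.18
        if not (0.25 < a_mid / area_i < 0.8 and 0.04 < a_core / area_i < 0.45):
            continue
        patterns.append(
            {
                "contour": c_i,
                "mid_contour": stats[j_mid][2],
                "core_contour": stats[j_core][2],
                "centroid": cen_i,
                "area": area_i,
            }
        )
        used.update({i, j_mid, j_core})
    return patterns


def _refine_ring_contour(gray: np.ndarray, contour: np.ndarray, otsu_level: float) -> np.ndarray:
    """Re-extract a ring's outer contour at the local ink/paper midpoint level.

    A threshold away from the half-intensity point shifts the marching-squares
    crossing off the physical edge, dilating or eroding the ring by a fraction
    of a pixel per side — enough to bias the projective fit's scale.  The
    midpoint of the local dark and light means puts the crossing back on the
    edge.  Falls back to the input contour if refinement fails.
    """
    r0 = max(0, int(contour[:, 0].min()) - 4)
    r1 = min(gray.shape[0], int(contour[:, 0].max()) + 5)
    c0 = max(0, int(contour[:, 1].min()) - 4)
    c1 = min(gray.shape[1], int(contour[:, 1].max()) + 5)
    local = gray[r0:r1, c0:c1]
    dark = local[local < otsu_level]
    light = local[local >= otsu_level]
    if dark.size == 0 or light.size == 0:
        return contour
    mid = 0.5 * (float(dark.mean()) + float(light.mean()))
    candidates = _closed_contours(local, mid)
    if not candidates:
        return contour
    outer = max(candidates, key=lambda c: _contour_stats(c)[1])
    return outer + [r0, c0]


def _order_finder_patterns(patterns: list[dict]) -> dict[str, dict] | None:
    """Identify the TL / TR / BL roles of three finder patterns.

    The corner pattern (TL) is the one whose vectors to the other two are
    closest to perpendicular; of the remaining two, TR is the one displaced
    mostly horizontally from TL.
    """
    if len(patterns) != 3:
        return None
    cents = [p["centroid"] for p in patterns]
    best, best_dev = None, np.inf
    for k in range(3):
        others = [cents[i] for i in range(3) if i != k]
        v1, v2 = others[0] - cents[k], others[1] - cents[k]
        cosang = abs(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        if cosang < best_dev:
            best, best_dev = k, cosang
    if best_dev > 0.5:  # not remotely perpendicular: not a finder triangle
        return None
    tl = patterns[best]
    rest = [patterns[i] for i in range(3) if i != best]
    d0 = rest[0]["centroid"] - tl["centroid"]
    d1 = rest[1]["centroid"] - tl["centroid"]
    if abs(d0[1]) >= abs(d1[1]):
        tr, bl = rest[0], rest[1]
    else:
        tr, bl = rest[1], rest[0]
    if abs(d0[1]) < abs(d0[0]) and abs(d1[1]) < abs(d1[0]):
        return None  # both displacements mostly vertical: geometry inconsistent
    return {"tl": tl, "tr": tr, "bl": bl}


def detect_fiducial(
    img: np.ndarray,
    blur_sigma: float = 1.2,
    canny_thresholds: tuple[float, float] = (0.05, 0.2),
    layout: Layout = DEFAULT_LAYOUT,
) -> Quad | ProcessingFailure:
    """Locate the fiducial block's outer quadrilateral.

    On success returns the block corner Quad estimated from a projective fit
    to all twelve detected finder-ring corners; on any content problem
    returns ``ProcessingFailure(stage='fiducial')`` — never raises.
    """
    try:
        gray = _luminance(img) / 255.0
        if min(gray.shape) < 32:
            return ProcessingFailure("fiducial", "image too small")
        blurred = gaussian(gray, sigma=blur_sigma, preserve_range=True)
        edges = canny(blurred, sigma=0, low_threshold=canny_thresholds[0], high_threshold=canny_thresholds[1])
        if not edges.any():
            return ProcessingFailure("fiducial", "no edges detected")
        level = threshold_otsu(blurred)
        patterns = _find_finder_patterns(blurred, level)
        if len(patterns) != 3:
            return ProcessingFailure(
                "fiducial", f"expected 3 finder patterns, found {len(patterns)}"
            )
        roles = _order_finder_patterns(patterns)
        if roles is None:
            return ProcessingFailure("fiducial", "finder patterns not in QR arrangement")
        # reference finder outer corners in block-local coordinates
        origins = layout.finder_origins()
        f = layout.finder_size
        u = f / 7.0
        src, dst = [], []
        for name in ("tl", "tr", "bl"):
            r0, c0 = origins[name]
            # outer ring edge, ring inner edge and core edge give 12 corner
            # correspondences per pattern; averaging over all 36 keeps the
            # projective fit stable far from the block
            for key, inset in (("contour", 0.0), ("mid_contour", u), ("core_contour", 2 * u)):
                ra, ca = r0 + inset, c0 + inset
                side = f - 2 * inset
                ref = np.array(
                    [[ra, ca], [ra, ca + side], [ra + side, ca + side], [ra + side, ca]]
                )
                det = _corner_points(_refine_ring_contour(blurred, roles[name][key], level))
                src.extend(ref[:, ::-1])  # (x, y)
                dst.extend(det[:, ::-1])
        tf = ProjectiveTransform.from_estimate(np.array(src), np.array(dst))
        if not tf:
            return ProcessingFailure("fiducial", "projective fit failed")
        s = layout.block_size
        block_ref_xy = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float)
        block_xy = tf(block_ref_xy)
        return Quad.from_points(block_xy[:, ::-1])
    except Exception as exc:  # content failures must not raise
        return ProcessingFailure("fiducial", f"{type(exc).__name__}: {exc}")


def align_photo(
    img: np.ndarray,
    fiducial: Quad,
    layout: Layout = DEFAULT_LAYOUT,
    return_transform: bool = False,
):
    """Rectify the photo so the fiducial sits at its canonical design position.

    Estimates the projective transform sending the detected block corners to
    the layout's block corners and warps the image onto the design canvas.
    Raises :class:`GeometryError` on degenerate (near-collinear) corners.
    """
    dst_rc = layout.block_corners()
    src = np.asarray(fiducial.corners, dtype=float)[:, ::-1]
    if fiducial.area() < 1e-3:
        raise GeometryError("fiducial corners are degenerate")
    tf = ProjectiveTransform.from_estimate(src, dst_rc[:, ::-1])
    if not tf:
        raise GeometryError("could not estimate alignment transform")
    aligned = warp(
        np.asarray(img, dtype=np.float64),
        tf.inverse,
        output_shape=layout.canvas_shape,
        order=1,
        cval=layout.background_value,
        mode="constant",
        preserve_range=True,
    )
    if return_transform:
        return aligned, tf
    return aligned


def detect_black_rectangle(
    img: np.ndarray,
    layout: Layout = DEFAULT_LAYOUT,
    min_area: float = 20000.0,
    aspect_bounds: tuple[float, float] = (1.5, 5.0),
    max_mean_luminance: float = 90.0,
) -> Quad | ProcessingFailure:
    """Find the black rectangle in an aligned image.

    Candidates are hole-filled connected dark components (Otsu threshold);
    they must pass area, tall-aspect and darkness gates.  The largest passing
    candidate wins.
    """
    try:
        gray = _luminance(img)
        level = threshold_otsu(gray)
        dark = gray < level
        labels, n = ndi.label(dark)
        if n == 0:
            return ProcessingFailure("rectangle", "no dark pixels")
        sizes = ndi.sum_labels(np.ones_like(gray), labels, index=np.arange(1, n + 1))
        slices = ndi.find_objects(labels)
        best: tuple[float, Quad] | None = None
        # pixel noise fragments the threshold mask; only bbox-plausible
        # components are examined, and each only within its own slice
        for lab in np.nonzero(sizes >= 0.25 * min_area)[0] + 1:
            sl = slices[lab - 1]
            comp = labels[sl] == lab
            filled = ndi.binary_fill_holes(comp)
            area = float(filled.sum())
            if area < min_area:
                continue
            rows, cols = np.nonzero(filled)
            h = rows.max() - rows.min() + 1
            w = cols.max() - cols.min() + 1
            aspect = h / w
            if not aspect_bounds[0] <= aspect <= aspect_bounds[1]:
                continue
            if gray[sl][comp].mean() > max_mean_luminance:
                continue
            # subpixel outline: marching-squares contour of the padded slice
            pad = 3
            r_lo = max(0, sl[0].start - pad)
            c_lo = max(0, sl[1].start - pad)
            sub = gray[r_lo : sl[0].stop + pad, c_lo : sl[1].stop + pad]
            contours = _closed_contours(sub, level)
            if not contours:
                continue
            outline = max(contours, key=lambda c: _contour_stats(c)[1])
            pts = _corner_points(outline) + [r_lo, c_lo]
            quad = Quad.from_points(pts)
            if best is None or area > best[0]:
                best = (area, quad)
        if best is None:
            return ProcessingFailure("rectangle", "no dark rectangle candidate passed the gates")
        return best[1]
    except Exception as exc:
        return ProcessingFailure("rectangle", f"{type(exc).__name__}: {exc}")


@dataclass
class StripCrop:
    """A cropped strip region plus its placement in the parent image."""

    image: np.ndarray
    origin: tuple[int, int]                  # (row, col) of crop in parent
    bbox: tuple[float, float, float, float]  # parent-frame (row0, col0, row1, col1)

    def to_parent(self, point_rc: tuple[float, float]) -> tuple[float, float]:
        return point_rc[0] + self.origin[0], point_rc[1] + self.origin[1]


def crop_strip(
    img: np.ndarray,
    rect: Quad,
    aspect_bounds: tuple[float, float] = (4.0, 12.0),
    margin: int = 2,
) -> StripCrop | ProcessingFailure:
    """Isolate the bright strip inside the detected rectangle.

    Masks the rectangle interior, thresholds bright pixels against the dark
    surround, keeps the largest hole-filled bright component, and checks that
    its bounding box is strip-shaped (long-to-short aspect within bounds).
    """
    try:
        gray = _luminance(img)
        rr, cc = np.mgrid[0 : gray.shape[0], 0 : gray.shape[1]]
        poly = Polygon(rect.corners[:, ::-1]).buffer(-margin)
        r0, c0, r1, c1 = (
            int(max(0, rect.corners[:, 0].min())),
            int(max(0, rect.corners[:, 1].min())),
            int(min(gray.shape[0], rect.corners[:, 0].max() + 1)),
            int(min(gray.shape[1], rect.corners[:, 1].max() + 1)),
        )
        inside = np.zeros_like(gray, dtype=bool)
        sub = np.column_stack([cc[r0:r1, c0:c1].ravel(), rr[r0:r1, c0:c1].ravel()])
        from shapely import contains_xy

        inside[r0:r1, c0:c1] = contains_xy(poly, sub[:, 0], sub[:, 1]).reshape(r1 - r0, c1 - c0)
        region = gray[inside]
        if region.size == 0:
            return ProcessingFailure("strip", "empty rectangle interior")
        level = threshold_otsu(region)
        bright = inside & (gray > level)
        if not bright.any():
            return ProcessingFailure("strip", "no bright region inside rectangle")
        labels, n = ndi.label(bright)
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        lab = int(np.argmax(sizes)) + 1
        comp = ndi.binary_fill_holes(labels == lab)
        rows, cols = np.nonzero(comp)
        h = rows.max() - rows.min() + 1
        w = cols.max() - cols.min() + 1
        aspect = max(h, w) / min(h, w)
        if not aspect_bounds[0] <= aspect <= aspect_bounds[1]:
            return ProcessingFailure("strip", f"bright region aspect {aspect:.2f} not strip-like")
        sr0, sc0, sr1, sc1 = rows.min(), cols.min(), rows.max() + 1, cols.max() + 1
        crop = np.asarray(img, dtype=np.float64)[sr0:sr1, sc0:sc1].copy()
        return StripCrop(
            image=crop,
            origin=(int(sr0), int(sc0)),
            bbox=(float(sr0), float(sc0), float(sr1), float(sc1)),
        )
    except Exception as exc:
        return ProcessingFailure("strip", f"{type(exc).__name__}: {exc}")


@dataclass
class PadRegion:
    """One colorimetric pad: bounding polygon, center, inscribed circle."""

    identity: str                    # "free" | "total"
    polygon: np.ndarray              # (N, 2) (row, col) vertices
    center: tuple[float, float]
    circle_center: tuple[float, float]
    radius: float


@dataclass
class PadSample:
    """Mean pad color over the inscribed circle."""

    mean_r: float
    mean_g: float
    mean_b: float
    pixel_count: int
    source: str = ""
    identity: str = ""

    @property
    def rgb(self) -> tuple[float, float, float]:
        return (self.mean_r, self.mean_g, self.mean_b)


def inscribe_circle(polygon: np.ndarray, center: tuple[float, float] | None = None) -> tuple[tuple[float, float], float]:
    """Largest circle centered at the pad's center point inside its polygon.

    The radius is the minimum distance from the center to the polygon
    boundary, so the circle is inscribed by construction.  The center
    defaults to the polygon centroid.
    """
    poly = Polygon(np.asarray(polygon, dtype=float)[:, ::-1])
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("zero-area or invalid pad polygon")
    if center is None:
        center = (poly.centroid.y, poly.centroid.x)
    radius = float(poly.exterior.distance(Point(center[1], center[0])))
    if radius <= 0:
        raise GeometryError("pad center lies on or outside the polygon boundary")
    return (float(center[0]), float(center[1])), radius


def locate_pads(
    strip: StripCrop,
    total_frac: float = DEFAULT_LAYOUT.total_pad_frac,
    free_frac: float = DEFAULT_LAYOUT.free_pad_frac,
    pad_side_frac: float = 0.64,
    min_length_px: int = 40,
    orientation: str = "up",
) -> tuple[PadRegion, PadRegion] | ProcessingFailure:
    """Place the free and total pad regions at fractions of the strip length.

    The fiducial fixes the image orientation, so with ``orientation='up'``
    the total pad sits near the strip's top end and the free pad mid-strip;
    ``orientation='down'`` measures the fractions from the bottom instead,
    swapping the pad positions consistently with a flipped strip.
    """
    try:
        h, w = strip.image.shape[:2]
        length, width = (h, w) if h >= w else (w, h)
        if length < min_length_px:
            return ProcessingFailure("pad", f"strip too short ({length} px)")
        side = pad_side_frac * width
        regions = []
        for identity, frac in (("free", free_frac), ("total", total_frac)):
            if orientation == "up":
                axis_pos = frac * length
            elif orientation == "down":
                axis_pos = length - frac * length
            else:
                raise GeometryError(f"unknown orientation {orientation!r}")
            if h >= w:
                center = (axis_pos, w / 2.0)
            else:
                center = (h / 2.0, axis_pos)
            half = side / 2.0
            polygon = np.array(
                [
                    [center[0] - half, center[1] - half],
                    [center[0] - half, center[1] + half],
                    [center[0] + half, center[1] + half],
                    [center[0] + half, center[1] - half],
                ]
            )
            circle_center, radius = inscribe_circle(polygon, center)
            regions.append(
                PadRegion(
                    identity=identity,
                    polygon=polygon,
                    center=center,
                    circle_center=circle_center,
                    radius=radius,
                )
            )
        free, total = regions
        return free, total
    except Exception as exc:
        return ProcessingFailure("pad", f"{type(exc).__name__}: {exc}")


def extract_mean_rgb(
    img: np.ndarray,
    circle_center: tuple[float, float],
    radius: float,
    min_pixels: int = 20,
    source: str = "",
    identity: str = "",
) -> PadSample:
    """Mean RGB over pixels whose centers lie strictly inside the circle.

    Pixel (i, j) has its center at coordinates (i, j); boundary ties are
    excluded so the membership rule is reproducible in integer geometry.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape[:2]
    cr, cc = circle_center
    r0 = max(0, int(np.floor(cr - radius)))
    r1 = min(h, int(np.ceil(cr + radius)) + 1)
    c0 = max(0, int(np.floor(cc - radius)))
    c1 = min(w, int(np.ceil(cc + radius)) + 1)
    if r1 <= r0 or c1 <= c0:
        raise GeometryError("circle outside image")
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    mask = (rr - cr) ** 2 + (cc_grid - cc) ** 2 < radius**2
    count = int(mask.sum())
    if count < min_pixels:
        raise GeometryError(f"only {count} pixels inside pad circle (min {min_pixels})")
    sel = img[r0:r1, c0:c1][mask]
    return PadSample(
        mean_r=float(sel[:, 0].mean()),
        mean_g=float(sel[:, 1].mean()),
        mean_b=float(sel[:, 2].mean()),
        pixel_count=count,
        source=source,
        identity=identity,
    )
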