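"""Fiducial, rectangle, strip and pad localization against rendered truth."""

import numpy as np
import pytest

from stripsense import geometry as geo
from stripsense import whitebalance as wb
from stripsense.layout import DEFAULT_LAYOUT
from stripsense.scene import SceneSpec, render_scene


def _chain_to_strip(img):
    fid = geo.detect_fiducial(img)
    assert isinstance(fid, geo.Quad), getattr(fid, "message", None)
    aligned = geo.align_photo(img, fid)
    rect = geo.detect_black_rectangle(aligned)
    assert isinstance(rect, geo.Quad), getattr(rect, "message", None)
    strip = geo.crop_strip(aligned, rect)
    assert isinstance(strip, geo.StripCrop), getattr(strip, "message", None)
    return fid, aligned, rect, strip


def test_fiducial_high_res_within_3px(noisy_scene):
    img, truth = noisy_scene
    fid = geo.detect_fiducial(img)
    assert isinstance(fid, geo.Quad)
    assert np.abs(fid.corners - truth.fiducial_corners).max() <= 3.0


def test_fiducial_blank_image_fails_gracefully():
    blank = np.full((400, 600, 3), 128.0)
    out = geo.detect_fiducial(blank)
    assert isinstance(out, geo.ProcessingFailure)
    assert out.stage == "fiducial"


def test_alignment_zero_tilt_is_similarity(clean_scene):
    """On an untilted scene the alignment transform has no shear/perspective.

    For a similarity the linear part has orthogonal columns of equal norm and
    the projective row is zero; scale should be within a percent of unity.
    """
    img, truth = clean_scene
    fid = geo.detect_fiducial(img)
    _, tf = geo.align_photo(img, fid, return_transform=True)
    m = tf.params / tf.params[2, 2]
    assert abs(m[2, 0]) < 1e-4 and abs(m[2, 1]) < 1e-4  # no perspective
    col0, col1 = m[:2, 0], m[:2, 1]
    assert abs(np.dot(col0, col1)) < 0.02               # no shear
    for col in (col0, col1):
        assert np.linalg.norm(col) == pytest.approx(1.0, abs=0.02)


def test_tilted_scene_aligns_to_untilted_frame():
    """After alignment an 8-degree-tilt scene lands on the zero-tilt geometry."""
    base = dict(concentration=0.4, seed=21, noise_sd=1.0)
    img0, truth0 = render_scene(SceneSpec(tilt_deg=0.0, **base))
    img8, _ = render_scene(SceneSpec(tilt_deg=8.0, **base))
    _, _, rect0, _ = _chain_to_strip(img0)
    _, _, rect8, _ = _chain_to_strip(img8)
    assert np.abs(rect8.corners - rect0.corners).max() <= 3.0


def test_align_rejects_degenerate_corners():
    with pytest.raises(geo.GeometryError):
        geo.Quad(np.array([[0.0, 0.0], [0.0, 10.0], [0.0, 20.0], [0.0, 30.0]]))


def test_rectangle_within_3px_and_absence_fails(noisy_scene):
    img, truth = noisy_scene
    _, aligned, rect, _ = _chain_to_strip(img)
    assert np.abs(rect.corners - truth.design_rectangle_corners).max() <= 3.0
    no_rect = np.full((500, 700, 3), 200.0)
    out = geo.detect_black_rectangle(no_rect)
    assert isinstance(out, geo.ProcessingFailure) and out.stage == "rectangle"


def test_rectangle_larger_candidate_wins():
    img = np.full((700, 900, 3), 190.0)
    img[50:200, 60:120] = 15.0     # small dark quad, aspect 2.5
    img[250:650, 500:660] = 15.0   # 4x larger dark quad, aspect 2.5
    quad = geo.detect_black_rectangle(img, min_area=5000)
    assert isinstance(quad, geo.Quad)
    assert abs(quad.corners[0][0] - 250) < 3 and abs(quad.corners[0][1] - 500) < 3


def test_strip_crop_iou_and_missing_strip(noisy_scene):
    img, truth = noisy_scene
    _, _, _, strip = _chain_to_strip(img)
    r0, c0, r1, c1 = strip.bbox
    t0, tc0, t1, tc1 = truth.design_strip_bbox
    inter = max(0, min(r1, t1) - max(r0, t0)) * max(0, min(c1, tc1) - max(c0, tc0))
    union = (r1 - r0) * (c1 - c0) + (t1 - t0) * (tc1 - tc0) - inter
    assert inter / union >= 0.9
    # rectangle with no strip inside
    img2 = np.full((700, 900, 3), 190.0)
    img2[100:620, 350:550] = 15.0
    rect = geo.detect_black_rectangle(img2)
    out = geo.crop_strip(img2, rect)
    assert isinstance(out, geo.ProcessingFailure) and out.stage == "strip"


def test_strip_recovered_when_laterally_offset():
    """The 3x-width rectangle tolerates off-center strip placement."""
    spec = SceneSpec(concentration=0.4, seed=33, noise_sd=1.0, lateral_offset_px=40.0)
    img, truth = render_scene(spec)
    _, _, _, strip = _chain_to_strip(img)
    r0, c0, r1, c1 = strip.bbox
    t0, tc0, t1, tc1 = truth.design_strip_bbox
    assert abs(c0 - tc0) <= 3 and abs(c1 - tc1) <= 3


def test_locate_pads_centers_within_3px(noisy_scene):
    img, truth = noisy_scene
    _, _, _, strip = _chain_to_strip(img)
    free, total = geo.locate_pads(strip)
    for region, name in ((free, "free"), (total, "total")):
        got = strip.to_parent(region.center)
        want = truth.design_pad_centers[name]
        assert np.hypot(got[0] - want[0], got[1] - want[1]) <= 3.0


def test_locate_pads_orientation_flip_swaps_identities(noisy_scene):
    img, _ = noisy_scene
    _, _, _, strip = _chain_to_strip(img)
    free_up, total_up = geo.locate_pads(strip, orientation="up")
    free_dn, total_dn = geo.locate_pads(strip, orientation="down")
    length = strip.image.shape[0]
    assert free_dn.center[0] == pytest.approx(length - free_up.center[0])
    assert total_dn.center[0] == pytest.approx(length - total_up.center[0])


def test_locate_pads_short_strip_fails():
    tiny = geo.StripCrop(image=np.full((20, 8, 3), 220.0), origin=(0, 0), bbox=(0, 0, 20, 8))
    out = geo.locate_pads(tiny)
    assert isinstance(out, geo.ProcessingFailure) and out.stage == "pad"


def test_inscribe_circle_square_and_rectangle():
    square = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
    center, radius = geo.inscribe_circle(square)
    assert center == pytest.approx((5.0, 5.0))
    assert radius == pytest.approx(5.0)
    rect = np.array([[0.0, 0.0], [0.0, 20.0], [10.0, 20.0], [10.0, 0.0]])
    _, r2 = geo.inscribe_circle(rect)
    assert r2 == pytest.approx(5.0)


def test_inscribe_circle_matches_brute_force_on_convex_polygons(rng):
    """Oracle: minimum point-to-segment distance over all edges."""

    def brute_force(poly, center):
        best = np.inf
        n = len(poly)
        for k in range(n):
            a, b = poly[k], poly[(k + 1) % n]
            ab = b - a
            t = np.clip(np.dot(center - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            best = min(best, float(np.linalg.norm(center - (a + t * ab))))
        return best

    from scipy.spatial import ConvexHull

    for _ in range(20):
        pts = rng.uniform(0, 40, size=(int(rng.integers(6, 15)), 2))
        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
        center, radius = geo.inscribe_circle(poly)
        assert radius == pytest.approx(brute_force(poly, np.array(center)), abs=1e-9)


def test_inscribe_circle_zero_area_polygon():
    with pytest.raises(geo.GeometryError):
        geo.inscribe_circle(np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]))


def test_extract_mean_rgb_uniform_and_split():
    img = np.empty((40, 40, 3))
    img[:] = (150.0, 60.0, 120.0)
    s = geo.extract_mean_rgb(img, (20.0, 20.0), 10.0)
    assert s.rgb == pytest.approx((150.0, 60.0, 120.0))
    # half/half split through the circle center: counting oracle
    img2 = np.full((41, 41, 3), 100.0)
    img2[:, 20:] = 200.0
    cr, cc, r = 20.0, 19.5, 12.0
    s2 = geo.extract_mean_rgb(img2, (cr, cc), r)
    rr, ccg = np.mgrid[0:41, 0:41]
    inside = (rr - cr) ** 2 + (ccg - cc) ** 2 < r**2
    oracle = img2[inside].mean(axis=0)
    assert s2.rgb == pytest.approx(tuple(oracle))
    assert abs(s2.mean_r - 150.0) <= 3.0  # near-even split within discretization


def test_extract_mean_rgb_min_pixels():
    img = np.full((30, 30, 3), 90.0)
    with pytest.raises(geo.GeometryError):
        geo.extract_mean_rgb(img, (15.0, 15.0), 1.5, min_pixels=20)


def test_extract_zero_noise_scene_matches_truth(clean_scene):
    """Ground-truth geometry recovers the exact pad color on a clean scene."""
    img, truth = clean_scene
    r, c = truth.pad_centers["free"]
    s = geo.extract_mean_rgb(img, (r, c), 12.0)
    assert np.abs(np.array(s.rgb) - np.array(truth.pad_rgb_free)).max() <= 2.0


def test_geometry_invariant_to_brightness_scaling(noisy_scene):
    """Uniform brightness scaling (within clipping) moves corners < 1 px."""
    img, _ = noisy_scene
    fid1 = geo.detect_fiducial(img)
    fid2 = geo.detect_fiducial(np.clip(img * 0.85, 0, 255))
    assert isinstance(fid1, geo.Quad) and isinstance(fid2, geo.Quad)
    assert np.abs(fid1.corners - fid2.corners).max() <= 1.0


def test_low_resolution_fails_more_than_high():
    rng = np.random.default_rng(5)
    fails = {"low": 0, "high": 0}
    n = 6
    for level in fails:
        for _ in range(n):
            spec = SceneSpec(
                concentration=float(rng.uniform(0.1, 3.0)),
                seed=int(rng.integers(2**31)),
                noise_sd=2.0,
                tilt_deg=float(rng.uniform(-8, 8)),
                resolution_level=level,
            )
            img, _ = render_scene(spec)
            if isinstance(geo.detect_fiducial(img), geo.ProcessingFailure):
                fails[level] += 1
    assert fails["low"] > fails["high"]
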