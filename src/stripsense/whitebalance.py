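"""Two-stage white balancing for test-strip photographs.

Stage one is a whole-photo gray-world normalization: assuming the average
color of the scene is achromatic, each channel is rescaled by
``(Gray / 3) / channel_mean`` where ``Gray`` is the sum of the three channel
means, which equalizes the channel means.  Stage two, applied to the cropped
strip region, is a white-patch correction: the strip body is made of white
plastic, so the mean color of its white pixels is mapped to the theoretical
maximum (255, 255, 255) by per-channel gains ``255 / white_mean``.

Images are (H, W, 3) arrays in RGB channel order, 0-based (row, col)
coordinates.  Balancing arithmetic is done in floating point and clipped to
[0, 255]; quantization to integers happens only when an image is written out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image


class BalanceError(ValueError):
    """Raised when an image cannot be balanced (degenerate channel / no whites)."""


def load_image(path) -> np.ndarray:
    """Decode a PNG/JPEG into a float (H, W, 3) RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64)


def save_image(img: np.ndarray, path) -> None:
    """Quantize to uint8 (round half to even via np.rint) and encode."""
    arr = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    return img


@dataclass(frozen=True)
class GrayWorldStats:
    """Channel means and their sum for one image."""

    r_avg: float
    g_avg: float
    b_avg: float

    @property
    def gray(self) -> float:
        return self.r_avg + self.g_avg + self.b_avg


def gray_world_stats(img: np.ndarray) -> GrayWorldStats:
    img = _as_float(img)
    r, g, b = (float(img[..., c].mean()) for c in range(3))
    return GrayWorldStats(r, g, b)


def gray_world_balance(img: np.ndarray) -> np.ndarray:
    """Gray-world normalization: gain (Gray/3)/channel_mean per channel.

    After balancing the three channel means are equal (within clipping
    effects).  A channel whose mean is zero cannot be balanced.
    """
    img = _as_float(img)
    stats = gray_world_stats(img)
    means = np.array([stats.r_avg, stats.g_avg, stats.b_avg])
    if (means == 0).any():
        raise BalanceError("a channel mean is 0; gray-world balance undefined")
    gains = (stats.gray / 3.0) / means
    return np.clip(img * gains, 0.0, 255.0)


def select_white_pixels(img: np.ndarray, luminance_threshold: float = 200.0) -> np.ndarray:
    """Boolean mask of pixels whose *minimum* channel is >= the threshold.

    Requiring the minimum channel to be bright selects near-neutral bright
    pixels (the white strip body) while rejecting colored pads, whose weakest
    channel is well below white.
    """
    img = _as_float(img)
    if not 0.0 < luminance_threshold < 255.0:
        raise ValueError("threshold must be in (0, 255)")
    return img.min(axis=2) >= luminance_threshold


@dataclass(frozen=True)
class WhiteReference:
    """Mean color of the selected white pixels."""

    r_w: float
    g_w: float
    b_w: float
    count: int


def white_reference_from_mask(img: np.ndarray, mask: np.ndarray) -> WhiteReference:
    img = _as_float(img)
    if not mask.any():
        raise BalanceError("no white pixels selected; white reference unavailable")
    sel = img[mask]
    r, g, b = (float(sel[:, c].mean()) for c in range(3))
    return WhiteReference(r, g, b, int(mask.sum()))


def white_reference_balance(
    img: np.ndarray, ref: WhiteReference, variant: str = "gain"
) -> np.ndarray:
    """White-patch correction against a measured white reference.

    ``variant='gain'`` (default) applies 255 / white_mean per channel, sending
    the reference region to (255, 255, 255).  ``variant='reciprocal'`` applies
    white_mean / 255 instead — the literal inverse scaling, kept available as
    a switch because both conventions circulate; it darkens rather than
    normalizes and is not used by the default pipeline.
    """
    img = _as_float(img)
    means = np.array([ref.r_w, ref.g_w, ref.b_w])
    if (means <= 0).any():
        raise BalanceError("white reference has a zero channel mean")
    if variant == "gain":
        gains = 255.0 / means
    elif variant == "reciprocal":
        gains = means / 255.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return np.clip(img * gains, 0.0, 255.0)
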