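"""Dataset preparation for the two generative models.

Tassel side: centre crop → blue-chroma (Cb) Otsu segmentation → resize →
[-1, 1] normalisation.  Sky side: HSV saturation/luminance augmentation and
removal of dark patches.  Coordinates are 0-based and intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

from .color import rgb_to_ycbcr, to_uint8
from .errors import DegenerateInputError, ParameterError

__all__ = [
    "PreprocessConfig",
    "otsu_threshold",
    "segment_tassel",
    "crop_center",
    "resize_image",
    "normalize",
    "denormalize",
    "augment_sky",
    "filter_dark_sky",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preparation pipeline.

    ``crop_height``/``crop_width`` are the centre-crop extent in source
    pixels; ``target_resolution`` the square output size; ``sat_scale`` and
    ``lum_scale`` the sky-augmentation multipliers; and
    ``dark_mean_value_threshold`` the minimum mean HSV-value (fraction of
    full brightness) a sky patch must have to be kept.
    """

    crop_height: int = 2512
    crop_width: int = 3408
    target_resolution: int = 128
    sat_scale: float = 0.6
    lum_scale: float | None = 1.3
    dark_mean_value_threshold: float = 0.35


def otsu_threshold(channel: np.ndarray) -> int:
    """Otsu's histogram threshold on an 8-bit single-channel image.

    Returns the integer t in [0, 255] maximising the between-class variance
    of the 256-bin histogram, with pixels ≤ t forming class 0.  Ties are
    broken toward the smallest t.

    Raises :class:`DegenerateInputError` when the channel is constant (a
    single grey level admits no two-class split).
    """
    ch = np.asarray(channel)
    if ch.size == 0:
        raise ParameterError("empty channel")
    ch = np.clip(np.rint(ch), 0, 255).astype(np.uint8)
    hist = np.bincount(ch.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("constant channel: Otsu threshold undefined")
    p = hist / hist.sum()
    omega = np.cumsum(p)                      # P(class 0) for t = 0..255
    mu = np.cumsum(p * np.arange(256))        # first moment up to t
    mu_t = mu[-1]
    # between-class variance for t = 0..254 (t = 255 puts everything in class 0)
    w0 = omega[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(255, -np.inf)
    num = (mu_t * w0[valid] - mu[:-1][valid]) ** 2
    sigma_b[valid] = num / (w0[valid] * w1[valid])
    return int(np.argmax(sigma_b))  # argmax returns the smallest maximiser


def segment_tassel(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Segment a plant object from a chromatically distinct backdrop.

    The image is converted to YCbCr and the blue-difference (Cb) channel is
    Otsu-thresholded.  Of the two classes, the tassel is the one whose mean
    Cb lies farther from the backdrop's modal Cb value (ties go to the
    smaller class, since the plant occupies a minority of the frame).
    Returns ``(segmented, mask)`` where ``segmented`` is the input with
    background pixels forced to exact black.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError("expected an H×W×3 RGB image")
    cb = np.clip(np.rint(rgb_to_ycbcr(img)[..., 1]), 0, 255).astype(np.uint8)
    t = otsu_threshold(cb)
    low = cb <= t
    high = ~low
    mode_cb = np.argmax(np.bincount(cb.ravel(), minlength=256))
    d_low = abs(cb[low].mean() - mode_cb)
    d_high = abs(cb[high].mean() - mode_cb)
    if d_low > d_high:
        mask = low
    elif d_high > d_low:
        mask = high
    else:
        mask = low if low.sum() < high.sum() else high
    segmented = np.where(mask[..., None], img, 0).astype(np.uint8)
    return segmented, mask.astype(np.uint8)


def crop_center(img: np.ndarray, h: int, w: int) -> np.ndarray:
    """Centre crop to h×w: rows [⌊(H−h)/2⌋, ⌊(H−h)/2⌋+h), same for columns."""
    img = np.asarray(img)
    H, W = img.shape[:2]
    if h > H or w > W:
        raise ParameterError(f"crop {h}×{w} exceeds image {H}×{W}")
    r0 = (H - h) // 2
    c0 = (W - w) // 2
    return img[r0 : r0 + h, c0 : c0 + w]


def resize_image(img: np.ndarray, resolution: int) -> np.ndarray:
    """Bicubic resize to resolution×resolution, clipped back to 8-bit."""
    if resolution < 1:
        raise ParameterError("resolution must be >= 1")
    img = np.asarray(img)
    pil = Image.fromarray(img.astype(np.uint8))
    out = pil.resize((resolution, resolution), Image.Resampling.BICUBIC)
    return np.asarray(out, dtype=np.uint8)


def normalize(img: np.ndarray) -> np.ndarray:
    """Map 8-bit values to [-1, 1] via x/127.5 − 1 (float64)."""
    return np.asarray(img, dtype=np.float64) / 127.5 - 1.0


def denormalize(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`: back to rounded, clipped uint8."""
    return to_uint8((np.asarray(x, dtype=np.float64) + 1.0) * 127.5)


def augment_sky(img: np.ndarray, sat_scale: float, lum_scale: float | None = None) -> np.ndarray:
    """Sky augmentation: scale HSV saturation (and optionally value),
    leaving hue untouched."""
    if sat_scale <= 0 or (lum_scale is not None and lum_scale <= 0):
        raise ParameterError("scales must be > 0")
    hsv = rgb2hsv(np.asarray(img, dtype=np.uint8))
    hsv[..., 1] = np.clip(hsv[..., 1] * sat_scale, 0.0, 1.0)
    if lum_scale is not None:
        hsv[..., 2] = np.clip(hsv[..., 2] * lum_scale, 0.0, 1.0)
    return to_uint8(hsv2rgb(hsv) * 255.0)


def filter_dark_sky(images: list[np.ndarray], threshold: float = 0.35) -> list[np.ndarray]:
    """Drop overly dark sky patches: keep an image iff its mean HSV value
    (fraction of full brightness) is ≥ ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must be in (0, 1)")
    kept = []
    for img in images:
        v = rgb2hsv(np.asarray(img, dtype=np.uint8))[..., 2]
        if v.mean() >= threshold:
            kept.append(img)
    return kept
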