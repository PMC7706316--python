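"""Compositing generated tassels onto generated skies.

Pipeline: luminance correction of the (over-bright) generated tassel →
Y-channel Otsu mask → ×2 bicubic upscale of tassel, sky and mask → seeded
integer shift of the tassel+mask → per-pixel merge

    I_m = mask · I_f + (1 − mask) · I_b

→ horizontal edge blending (weighted 0.5/0.75/0.25 averages of each edge
pixel's row neighbours) → ×2 downscale back to the input resolution, with
the mask re-binarised at 0.5.  Each output is a (merged image, mask) pair,
so the synthetic field images arrive pre-labelled for segmentation work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .color import rgb_to_ycbcr, to_uint8, ycbcr_to_rgb
from .errors import DegenerateInputError, ParameterError, ShapeError
from .preprocess import otsu_threshold, resize_image

__all__ = [
    "ComposeConfig",
    "reduce_luminance",
    "extract_tassel_mask",
    "merge_images",
    "blend_edges",
    "compose_field_image",
]


@dataclass(frozen=True)
class ComposeConfig:
    """Compositing knobs: luminance correction factor in (0, 1], maximum
    |dx|,|dy| of the seeded tassel shift (pixels, at the upscaled ×2 grid),
    and whether edge blending runs."""

    luminance_factor: float = 0.85
    shift_range: int = 16
    seed: int = 0
    blend_enabled: bool = True
    upscale_factor: int = 2

    def __post_init__(self):
        if not (0.0 < self.luminance_factor <= 1.0):
            raise ParameterError("luminance_factor must be in (0, 1]")
        if self.shift_range < 0:
            raise ParameterError("shift_range must be >= 0")
        if self.upscale_factor != 2:
            raise ParameterError("only the ×2 up/downscale protocol is supported")


def reduce_luminance(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale the luma (Y) channel by ``factor``, leaving chroma untouched."""
    if factor <= 0:
        raise ParameterError("factor must be > 0")
    ycc = rgb_to_ycbcr(img)
    ycc[..., 0] = np.clip(ycc[..., 0] * factor, 0, 255)
    return to_uint8(ycbcr_to_rgb(ycc))


def extract_tassel_mask(img: np.ndarray) -> np.ndarray:
    """Binary mask of a bright object on a dark background: Otsu on the Y
    channel, foreground = the brighter class (Y > t)."""
    y = np.clip(np.rint(rgb_to_ycbcr(img)[..., 0]), 0, 255).astype(np.uint8)
    t = otsu_threshold(y)  # raises DegenerateInputError on constant Y
    return (y > t).astype(np.uint8)


def merge_images(fg: np.ndarray, bg: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel selection: mask=1 → foreground value, mask=0 → background."""
    fg, bg, mask = np.asarray(fg), np.asarray(bg), np.asarray(mask)
    if fg.shape != bg.shape or mask.shape != fg.shape[:2]:
        raise ShapeError(f"shape mismatch: fg {fg.shape}, bg {bg.shape}, mask {mask.shape}")
    return np.where(mask[..., None].astype(bool), fg, bg)


def blend_edges(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Soften horizontal mask transitions by weighted averaging.

    For each row, the first and last foreground pixel of every maximal
    mask=1 run is an edge pixel; with L and R its left/right row neighbours
    (pre-blend values), the triple is rewritten per channel as

        edge ← 0.5·L + 0.5·R,  left ← 0.75·L + 0.25·R,  right ← 0.25·L + 0.75·R.

    All updates are computed from the pre-blend image simultaneously.  Edge
    pixels sitting at an image border (missing a neighbour) are skipped.
    A transition-free mask returns the image unchanged.
    """
    img = np.asarray(img)
    mask = np.asarray(mask)
    if mask.shape != img.shape[:2]:
        raise ShapeError(f"mask {mask.shape} does not match image {img.shape[:2]}")
    src = img.astype(np.float64)
    out = src.copy()
    m = mask.astype(bool)
    H, W = m.shape
    for r in range(H):
        row = m[r]
        if not row.any():
            continue
        padded = np.concatenate(([False], row, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        edges = sorted(set(starts) | set(ends))
        for c in edges:
            if c - 1 < 0 or c + 1 >= W:
                continue
            L = src[r, c - 1]
            R = src[r, c + 1]
            out[r, c] = 0.5 * L + 0.5 * R
            out[r, c - 1] = 0.75 * L + 0.25 * R
            out[r, c + 1] = 0.25 * L + 0.75 * R
    if img.dtype == np.uint8:
        return to_uint8(out)
    return out


def _shift(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift padding with zeros (content leaving the frame is lost,
    but shifts are pre-clipped so the tassel bounding box stays inside)."""
    out = np.zeros_like(arr)
    H, W = arr.shape[:2]
    ys_src = slice(max(0, -dy), min(H, H - dy))
    xs_src = slice(max(0, -dx), min(W, W - dx))
    ys_dst = slice(max(0, dy), min(H, H + dy))
    xs_dst = slice(max(0, dx), min(W, W + dx))
    out[ys_dst, xs_dst] = arr[ys_src, xs_src]
    return out


def compose_field_image(
    tassel: np.ndarray,
    sky: np.ndarray,
    config: ComposeConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full compositing pipeline; returns the field-like image and its
    paired binary mask, both at the input resolution."""
    config = config or ComposeConfig()
    tassel = np.asarray(tassel)
    sky = np.asarray(sky)
    if tassel.shape != sky.shape:
        raise ShapeError(f"tassel {tassel.shape} and sky {sky.shape} must match")
    res = tassel.shape[0]

    fg = reduce_luminance(tassel, config.luminance_factor)
    mask = extract_tassel_mask(fg)
    if mask.sum() == 0:
        raise DegenerateInputError("tassel mask is empty after thresholding")

    up = res * config.upscale_factor
    fg2 = resize_image(fg, up)
    bg2 = resize_image(sky, up)
    mask2 = (np.asarray(resize_image(mask * 255, up), dtype=np.float64) / 255.0 > 0.5).astype(np.uint8)

    rng = np.random.default_rng(config.seed)
    dy = int(rng.integers(-config.shift_range, config.shift_range + 1))
    dx = int(rng.integers(-config.shift_range, config.shift_range + 1))
    rows = np.flatnonzero(mask2.any(axis=1))
    cols = np.flatnonzero(mask2.any(axis=0))
    dy_c = int(np.clip(dy, -rows[0], up - 1 - rows[-1]))
    dx_c = int(np.clip(dx, -cols[0], up - 1 - cols[-1]))
    if (dy_c, dx_c) != (dy, dx):
        warnings.warn("shift clipped to keep the tassel bounding box in frame", stacklevel=2)
    fg2 = _shift(fg2, dy_c, dx_c)
    mask2 = _shift(mask2, dy_c, dx_c)

    merged = merge_images(fg2, bg2, mask2)
    if config.blend_enabled:
        merged = blend_edges(merged, mask2)

    merged_out = resize_image(merged, res)
    mask_out = (np.asarray(resize_image(mask2 * 255, res), dtype=np.float64) / 255.0 > 0.5).astype(np.uint8)
    return merged_out, mask_out
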