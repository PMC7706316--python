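"""Procedural stand-ins for the three kinds of imagery the pipeline consumes.

The real training corpora (indoor lab maize-tassel photographs and the
SWIMSEG / HYTA sky-patch databases) are not redistributable, so every
generator here is *synthetic*: it reproduces only the statistical structure
each downstream stage relies on —

* tassel patches: a connected central spike plus lateral branches in brownish
  tones on an exactly-black background, with a pixel-exact ground-truth mask;
* sky patches: a blue-dominant vertical gradient with smooth cloud texture;
* lab scenes: the same tassel geometry over a uniform bluish backdrop, i.e.
  a bimodal blue-chroma histogram for segmentation tests;
* annotation matrices: N items × K annotators with a controlled
  disagreement rate, for the inter-annotator error bound.

All generators are deterministic for a fixed seed.  Strokes are drawn with
hard (non-anti-aliased) pixels so masks are binary-exact: the mask is the
exact set of painted foreground pixels and the background is exact (0,0,0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import line as _draw_line

from .errors import ParameterError

__all__ = [
    "TasselParams",
    "SkyParams",
    "make_tassel_image",
    "make_tassel_mask",
    "make_sky_image",
    "make_lab_scene",
    "make_lab_scene_mask",
    "make_annotation_matrix",
    "make_tassel_set",
    "make_sky_set",
]


@dataclass(frozen=True)
class TasselParams:
    """Geometry and palette of a synthetic tassel patch.

    resolution
        Pixels per side of the square patch (≥ 16).
    n_branches
        Number of lateral branches attached to the central spike (≥ 0).
    spike_height_frac
        Height of the central spike as a fraction of image height, in (0, 1].
    branch_angle_range
        (low, high) branch inclination from vertical, degrees.
    color_base
        Base RGB of the foreground, brownish by default.
    jitter
        Per-pixel multiplicative brightness jitter amplitude in [0, 1).
    """

    resolution: int = 128
    n_branches: int = 8
    spike_height_frac: float = 0.75
    branch_angle_range: tuple[float, float] = (25.0, 65.0)
    color_base: tuple[int, int, int] = (139, 92, 44)
    jitter: float = 0.15

    def validate(self) -> None:
        if self.resolution < 16:
            raise ParameterError(f"resolution must be >= 16, got {self.resolution}")
        if self.n_branches < 0:
            raise ParameterError("n_branches must be >= 0")
        if not (0.0 < self.spike_height_frac <= 1.0):
            raise ParameterError("spike_height_frac must be in (0, 1]")
        if not (0.0 <= self.jitter < 1.0):
            raise ParameterError("jitter must be in [0, 1)")
        if any(not (0 <= c <= 255) for c in self.color_base):
            raise ParameterError("color_base channels must be in [0, 255]")


@dataclass(frozen=True)
class SkyParams:
    """Palette and texture of a synthetic sky patch."""

    resolution: int = 128
    gradient_top: tuple[int, int, int] = (105, 160, 235)
    gradient_bottom: tuple[int, int, int] = (185, 212, 248)
    cloud_density: float = 0.5
    cloud_scale: int = 24

    def validate(self) -> None:
        if self.resolution < 16:
            raise ParameterError(f"resolution must be >= 16, got {self.resolution}")
        if not (0.0 <= self.cloud_density <= 1.0):
            raise ParameterError("cloud_density must be in [0, 1]")
        if self.cloud_scale < 1:
            raise ParameterError("cloud_scale must be >= 1")
        for name, c in (("gradient_top", self.gradient_top), ("gradient_bottom", self.gradient_bottom)):
            if any(not (0 <= v <= 255) for v in c):
                raise ParameterError(f"{name} channels must be in [0, 255]")
            if c[2] < c[0]:
                raise ParameterError(f"{name} must be blue-dominant (blue >= red)")


def _render_geometry(params: TasselParams, rng: np.random.Generator) -> np.ndarray:
    """Draw the binary tassel silhouette. Consumes rng draws in a fixed order
    so that the image and mask entry points stay in lockstep."""
    res = params.resolution
    mask = np.zeros((res, res), dtype=bool)

    half_w = max(1, res // 86)          # spike half-width
    amp = max(1, res // 64)             # spike waviness amplitude
    bottom = res - 1 - res // 16
    top = max(0, int(round(bottom - params.spike_height_frac * res)) + 1)
    rows = np.arange(top, bottom + 1)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = np.rint(amp * np.sin(2 * np.pi * rows / max(res / 2.5, 1) + phase)).astype(int)
    centers = res // 2 + wobble
    for r, c in zip(rows, centers):
        lo = max(0, c - half_w)
        hi = min(res - 1, c + half_w)
        mask[r, lo : hi + 1] = True

    spike_len = bottom - top + 1
    lo_a, hi_a = params.branch_angle_range
    branch_skeleton = np.zeros_like(mask)
    for b in range(params.n_branches):
        # attachment spaced along the upper 70% of the spike, alternating sides
        frac = rng.uniform(0.05, 0.70)
        r0 = top + int(round(frac * spike_len))
        r0 = min(r0, bottom)
        c0 = res // 2 + int(np.rint(amp * np.sin(2 * np.pi * r0 / max(res / 2.5, 1) + phase)))
        side = 1 if b % 2 == 0 else -1
        angle = np.deg2rad(rng.uniform(lo_a, hi_a))
        # branches near the top are shorter (tassel tapers)
        length = rng.uniform(0.18, 0.42) * spike_len * (0.5 + 0.5 * frac)
        r1 = int(round(r0 - length * np.cos(angle)))
        c1 = int(round(c0 + side * length * np.sin(angle)))
        r1 = int(np.clip(r1, 0, res - 1))
        c1 = int(np.clip(c1, 0, res - 1))
        rr, cc = _draw_line(r0, c0, r1, c1)
        branch_skeleton[rr, cc] = True
    if params.n_branches and res >= 64:
        branch_skeleton = binary_dilation(branch_skeleton, np.ones((2, 2), dtype=bool))
    return mask | branch_skeleton


def _render(params: TasselParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    params.validate()
    rng = np.random.default_rng(seed)
    mask = _render_geometry(params, rng)
    n_fg = int(mask.sum())
    base = np.array(params.color_base, dtype=np.float64)
    bright = 1.0 + params.jitter * rng.uniform(-1.0, 1.0, size=(n_fg, 1))
    chroma = params.jitter * 20.0 * rng.uniform(-1.0, 1.0, size=(n_fg, 3))
    colors = np.clip(np.rint(base * bright + chroma), 1, 255).astype(np.uint8)
    img = np.zeros((params.resolution, params.resolution, 3), dtype=np.uint8)
    img[mask] = colors
    return img, mask.astype(np.uint8)


def make_tassel_image(params: TasselParams, seed: int) -> np.ndarray:
    """Render a tassel patch on an exactly-black background (uint8 H×W×3)."""
    return _render(params, seed)[0]


def make_tassel_mask(params: TasselParams, seed: int) -> np.ndarray:
    """Ground-truth binary mask paired with :func:`make_tassel_image`
    for the same ``(params, seed)``: exactly the painted pixels."""
    return _render(params, seed)[1]


def make_sky_image(params: SkyParams, seed: int) -> np.ndarray:
    """Render a blue-dominant sky patch: vertical gradient plus smooth,
    seeded cloud texture blended toward white (uint8 H×W×3)."""
    params.validate()
    rng = np.random.default_rng(seed)
    res = params.resolution
    t = np.linspace(0.0, 1.0, res)[:, None, None]
    top = np.asarray(params.gradient_top, dtype=np.float64)
    bot = np.asarray(params.gradient_bottom, dtype=np.float64)
    img = (1 - t) * top + t * bot  # each row constant
    if params.cloud_density > 0:
        field = np.zeros((res, res))
        for octave in range(3):
            sigma = max(params.cloud_scale / (2.0 ** octave) / 2.0, 0.5)
            field += gaussian_filter(rng.standard_normal((res, res)), sigma) / (2.0 ** octave)
        lo, hi = field.min(), field.max()
        if hi > lo:
            field = (field - lo) / (hi - lo)
        alpha = (params.cloud_density * field ** 1.5)[:, :, None]
        img = (1 - alpha) * img + alpha * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_lab_scene(
    params: TasselParams,
    backdrop: tuple[int, int, int] = (150, 172, 216),
    seed: int = 0,
) -> np.ndarray:
    """Tassel rendered over a uniform backdrop, emulating a raw indoor-lab
    capture with a bluish (high-Cb) screen behind the plant.  The paired
    ground-truth mask is :func:`make_lab_scene_mask` with the same arguments.
    """
    img, mask = _render(params, seed)
    out = np.empty_like(img)
    out[:] = np.asarray(backdrop, dtype=np.uint8)
    out[mask.astype(bool)] = img[mask.astype(bool)]
    return out


def make_lab_scene_mask(params: TasselParams, seed: int = 0) -> np.ndarray:
    """Ground-truth mask of :func:`make_lab_scene` (backdrop-independent)."""
    return _render(params, seed)[1]


def make_annotation_matrix(
    n_items: int,
    k_annotators: int,
    disagreement_rate: float,
    seed: int,
    n_labels: int = 2,
) -> np.ndarray:
    """N×K categorical label matrix: each item has a latent true label and
    each annotator independently reports a different label with probability
    ``disagreement_rate``."""
    if n_items < 1:
        raise ParameterError("n_items must be >= 1")
    if k_annotators < 2:
        raise ParameterError("k_annotators must be >= 2")
    if not (0.0 <= disagreement_rate <= 1.0):
        raise ParameterError("disagreement_rate must be in [0, 1]")
    if n_labels < 2:
        raise ParameterError("n_labels must be >= 2")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, n_labels, size=n_items)
    labels = np.repeat(truth[:, None], k_annotators, axis=1)
    flip = rng.random((n_items, k_annotators)) < disagreement_rate
    offset = rng.integers(1, n_labels, size=(n_items, k_annotators))
    labels = np.where(flip, (labels + offset) % n_labels, labels)
    return labels.astype(np.int64)


def make_tassel_set(
    n: int, params: TasselParams | None = None, seed: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Convenience: n tassel images + paired masks, seeds ``seed .. seed+n-1``."""
    p = params or TasselParams()
    pairs = [_render(p, seed + i) for i in range(n)]
    return [im for im, _ in pairs], [m for _, m in pairs]


def make_sky_set(n: int, params: SkyParams | None = None, seed: int = 0) -> list[np.ndarray]:
    """Convenience: n sky patches, seeds ``seed .. seed+n-1``."""
    p = params or SkyParams()
    return [make_sky_image(p, seed + i) for i in range(n)]
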