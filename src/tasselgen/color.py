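"""Color-space conversions used throughout the pipeline.

YCbCr here is the ITU-R BT.601 *full-range* (JPEG) convention: Y, Cb, Cr all
span [0, 255] for 8-bit input, with the chroma channels centred at 128.
(scikit-image's ``rgb2ycbcr`` is the studio-swing variant, which is why the
transform is spelled out here.)
"""

from __future__ import annotations

import numpy as np

# BT.601 full-range forward matrix, rows = (Y, Cb, Cr).
_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_OFFSET = np.array([0.0, 128.0, 128.0])
_INV = np.linalg.inv(_FWD)


def rgb_to_ycbcr(img: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 RGB array (any float/uint8 scale in [0, 255]) to
    float YCbCr on the same scale."""
    rgb = np.asarray(img, dtype=np.float64)
    return rgb @ _FWD.T + _OFFSET


def ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_ycbcr`; returns float RGB, unclipped."""
    ycc = np.asarray(ycc, dtype=np.float64)
    return (ycc - _OFFSET) @ _INV.T


def luma(img: np.ndarray) -> np.ndarray:
    """Full-range BT.601 luma channel of an RGB image, float in [0, 255]."""
    rgb = np.asarray(img, dtype=np.float64)
    return rgb @ _FWD[0]


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Round and clip a float image to 8-bit."""
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
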