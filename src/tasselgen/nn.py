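"""Minimal NumPy neural-network layers with hand-written backpropagation.

Implements exactly what the DC-GAN variant needs — strided convolution,
transposed convolution, 1×1 projection, batch normalisation, the usual
activations, nearest/bilinear ×2 upsampling and an Adam optimiser — on
NCHW float64 arrays.  Everything is deterministic: initialisation draws from
an injected ``numpy.random.Generator`` and no layer keeps hidden global
state, so fixed-seed training runs are bit-reproducible on one machine.

Each layer exposes ``forward(x, train)`` (caching what backward needs) and
``backward(dy)`` (returning dx and accumulating parameter gradients in
``Param.grad``).
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "UpsampleNearest2x",
    "UpsampleBilinear2x",
    "Adam",
    "INIT_STD",
]

INIT_STD = 0.02  # zero-mean Gaussian weight init, DC-GAN convention


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    N, C, H, W = x.shape
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    if oh < 1 or ow < 1:
        raise ShapeError(f"kernel {k} does not fit input {H}×{W} (pad {pad})")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, k, k, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    return np.ascontiguousarray(cols).reshape(N, C * k * k, oh * ow), oh, ow


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    N, C, H, W = xshape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
    d6 = dcols.reshape(N, C, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[:, :, i, j]
    return dxp[:, :, pad : pad + H, pad : pad + W]


class Conv2d:
    """Strided 2-D convolution (cross-correlation), weight (cout, cin, k, k)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.w = Param(rng.normal(0.0, INIT_STD, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} channels, got {x.shape[1]}")
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        wm = self.w.value.reshape(self.cout, -1)
        y = np.matmul(wm, cols) + self.b.value[None, :, None]
        self._cache = (x.shape, cols, oh, ow)
        return y.reshape(x.shape[0], self.cout, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, cols, oh, ow = self._cache
        N = xshape[0]
        dym = dy.reshape(N, self.cout, oh * ow)
        self.w.grad += np.einsum("nol,nkl->ok", dym, cols).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        wm = self.w.value.reshape(self.cout, -1)
        dcols = np.matmul(wm.T, dym)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad, oh, ow)


class ConvTranspose2d:
    """Transposed (fractionally-strided) convolution, weight (cin, cout, k, k).

    Output spatial size = (in − 1)·stride − 2·pad + k, matching the usual
    deep-learning convention; the forward pass is the adjoint of
    :class:`Conv2d`'s forward.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self.w = Param(rng.normal(0.0, INIT_STD, size=(cin, cout, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} channels, got {x.shape[1]}")
        N, _, H, W = x.shape
        oh, ow = self.out_size(H), self.out_size(W)
        if oh < 1 or ow < 1:
            raise ShapeError("transposed conv output would be empty")
        wm = self.w.value.reshape(self.cin, -1)           # (cin, cout*k*k)
        xf = x.reshape(N, self.cin, H * W)
        tmp = np.matmul(wm.T[None], xf)                   # (N, cout*k*k, H*W)
        y = _col2im(tmp, (N, self.cout, oh, ow), self.k, self.stride, self.pad, H, W)
        y += self.b.value[None, :, None, None]
        self._cache = (x, (N, self.cout, oh, ow), H, W)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, yshape, H, W = self._cache
        N = x.shape[0]
        dcols, oh2, ow2 = _im2col(dy, self.k, self.stride, self.pad)   # (N, cout*k*k, H*W)
        assert (oh2, ow2) == (H, W)
        xf = x.reshape(N, self.cin, H * W)
        self.w.grad += np.einsum("ncl,nkl->ck", xf, dcols).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        wm = self.w.value.reshape(self.cin, -1)
        dx = np.matmul(wm[None], dcols)
        return dx.reshape(x.shape)


class BatchNorm2d:
    """Per-channel batch normalisation over (N, H, W) with learned affine."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std[None, :, None, None]


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Tanh:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Sigmoid:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class UpsampleNearest2x:
    """×2 nearest-neighbour upsampling (each pixel becomes a 2×2 block)."""

    def params(self):
        return []

    def forward(self, x, train=True):
        self._inshape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        N, C, H, W = self._inshape
        return dy.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))


class UpsampleBilinear2x:
    """×2 bilinear upsampling (align_corners=False convention), expressed as
    a fixed linear map so the backward pass is its transpose."""

    def params(self):
        return []

    @staticmethod
    def _axis_weights(n: int) -> np.ndarray:
        # row-stochastic (2n × n) interpolation matrix along one axis
        m = np.zeros((2 * n, n))
        src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, n - 1)
        hi = np.clip(lo + 1, 0, n - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        m[np.arange(2 * n), lo] += 1.0 - frac
        m[np.arange(2 * n), hi] += frac
        return m

    def forward(self, x, train=True):
        N, C, H, W = x.shape
        self._mh = self._axis_weights(H)
        self._mw = self._axis_weights(W)
        y = np.einsum("ih,nchw->nciw", self._mh, x)
        return np.einsum("jw,nciw->ncij", self._mw, y)

    def backward(self, dy):
        y = np.einsum("jw,ncij->nciw", self._mw, dy)
        return np.einsum("ih,nciw->nchw", self._mh, y)


class Adam:
    """Adam over a list of :class:`Param`, DC-GAN betas (0.5, 0.999)."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
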