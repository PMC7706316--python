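"""Architectures of the DC-GAN variant used for tassel and sky synthesis.

The generator maps a latent vector to an image through a chain of
transposed-convolution ("Deconv") stages that double spatial resolution from
4×4 up to the target, each followed by ReLU except the last, which uses tanh
so outputs live in [-1, 1].  Two departures from stock DC-GAN define the
variant:

* batch normalisation can be removed entirely (``use_batchnorm=False``, the
  default here) — with the tassel data's overwhelmingly black background,
  batch-norm makes the discriminator converge almost immediately and the
  generator never learns;
* residual paths can be attached to chosen stages: the previous stage's
  activated feature maps are upsampled ×2 by interpolation, projected to the
  next stage's channel count by a learned 1×1 convolution (zero padding,
  stride 1), and added to that stage's pre-activation output.  This
  counteracts the degradation seen when growing the generator from 64×64
  (5 stages) to 128×128 (6 stages).

The discriminator mirrors the generator with strided convolutions,
leaky-ReLU (slope 0.2), and a final 4×4 convolution + sigmoid producing one
probability per sample.  Kernels are 4×4, stride 2, padding 1; weights are
initialised from a zero-mean Gaussian with σ = 0.02.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .errors import ParameterError, ShapeError

__all__ = [
    "GanSpec",
    "DEFAULT_RESIDUAL_STAGES",
    "build_generator_spec",
    "build_discriminator_spec",
    "Generator",
    "Discriminator",
    "compute_residual",
    "generator_forward",
    "discriminator_forward",
    "sample_latents",
    "save_checkpoint",
    "load_checkpoint",
]

#: Stage output resolutions that receive a residual path in the tassel model.
DEFAULT_RESIDUAL_STAGES = frozenset({16, 32, 64, 128})


def _is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class GanSpec:
    """Layer-by-layer description of one network.

    ``stages`` is the ordered list of (output spatial resolution, output
    channels).  For a generator, resolutions run 4, 8, …, R and the last
    stage has 3 channels; for a discriminator they run R/2, …, 4, 1 with the
    final scalar stage having 1 channel.  ``residual_stages`` lists the
    generator stage resolutions that receive a residual path (always empty
    for discriminators).
    """

    kind: str                                  # "generator" | "discriminator"
    latent_dim: int
    stages: tuple[tuple[int, int], ...]
    use_batchnorm: bool
    residual_stages: frozenset[int] = field(default_factory=frozenset)
    residual_interp: str = "nearest"           # "nearest" | "bilinear"
    final_activation: str = "tanh"

    def __post_init__(self):
        if self.kind not in ("generator", "discriminator"):
            raise ParameterError(f"unknown kind {self.kind!r}")
        if self.kind == "generator":
            res = [r for r, _ in self.stages]
            if res[0] != 4 or any(b != 2 * a for a, b in zip(res, res[1:])):
                raise ParameterError("generator stages must double from 4×4")
            if self.stages[-1][1] != 3:
                raise ParameterError("generator's last stage must emit 3 channels")
            if not self.residual_stages <= set(res):
                raise ParameterError("residual_stages must be a subset of stage resolutions")
        if self.residual_interp not in ("nearest", "bilinear"):
            raise ParameterError("residual_interp must be 'nearest' or 'bilinear'")

    @property
    def resolution(self) -> int:
        return self.stages[-1][0] if self.kind == "generator" else self.stages[0][0] * 2

    def to_yaml(self) -> str:
        d = {
            "kind": self.kind,
            "latent_dim": self.latent_dim,
            "stages": [list(s) for s in self.stages],
            "use_batchnorm": self.use_batchnorm,
            "residual_stages": sorted(self.residual_stages),
            "residual_interp": self.residual_interp,
            "final_activation": self.final_activation,
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GanSpec":
        d = yaml.safe_load(text)
        return cls(
            kind=d["kind"],
            latent_dim=int(d["latent_dim"]),
            stages=tuple((int(r), int(c)) for r, c in d["stages"]),
            use_batchnorm=bool(d["use_batchnorm"]),
            residual_stages=frozenset(int(r) for r in d["residual_stages"]),
            residual_interp=d.get("residual_interp", "nearest"),
            final_activation=d.get("final_activation", "tanh"),
        )

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _check_resolution(resolution: int) -> int:
    if not _is_pow2(resolution) or resolution < 8:
        raise ParameterError(f"resolution must be a power of two >= 8, got {resolution}")
    return int(np.log2(resolution // 4)) + 1  # stage count


def build_generator_spec(
    resolution: int,
    use_batchnorm: bool = False,
    residual_stages: frozenset[int] | set[int] | None = None,
    base_channels: int = 64,
    latent_dim: int = 100,
    residual_interp: str = "nearest",
) -> GanSpec:
    """Generator spec for a given output resolution.

    Stage resolutions are 4, 8, …, ``resolution`` (so 6 stages at 128×128,
    5 at 64×64).  Channel widths follow the DC-GAN doubling scheme ending at
    ``base_channels`` before the 3-channel output (1024→…→64→3 at 128 with
    the default base).  ``residual_stages=None`` selects the tassel-model
    default {16, 32, 64, 128} (intersected with the available stages); pass
    an empty set for a residual-free (sky) generator.
    """
    n = _check_resolution(resolution)
    res = [4 * 2 ** i for i in range(n)]
    chans = [base_channels * 2 ** (n - 2 - i) for i in range(n - 1)] + [3]
    if residual_stages is None:
        residual_stages = DEFAULT_RESIDUAL_STAGES & set(res)
    return GanSpec(
        kind="generator",
        latent_dim=latent_dim,
        stages=tuple(zip(res, chans)),
        use_batchnorm=use_batchnorm,
        residual_stages=frozenset(residual_stages),
        residual_interp=residual_interp,
        final_activation="tanh",
    )


def build_discriminator_spec(
    resolution: int,
    use_batchnorm: bool = False,
    base_channels: int = 64,
) -> GanSpec:
    """Discriminator spec mirroring the generator: strided 4×4 convolutions
    halving resolution down to 4×4, then a final 4×4 convolution + sigmoid
    yielding one probability.  Stage count equals the generator's."""
    n = _check_resolution(resolution)
    res = [resolution // 2 ** (i + 1) for i in range(n - 1)] + [1]
    chans = [base_channels * 2 ** i for i in range(n - 1)] + [1]
    return GanSpec(
        kind="discriminator",
        latent_dim=0,
        stages=tuple(zip(res, chans)),
        use_batchnorm=use_batchnorm,
        residual_stages=frozenset(),
        final_activation="sigmoid",
    )


def compute_residual(
    features: np.ndarray,
    target_channels: int,
    projection: np.ndarray,
    interp: str = "nearest",
) -> np.ndarray:
    """Residual path as a standalone computation: upsample ``features``
    (N×C×s×s) by ×2 interpolation, then apply the 1×1 ``projection`` kernel
    (target_channels × C × 1 × 1, zero padding, stride 1).  The result has
    shape N × target_channels × 2s × 2s and is meant to be added to the next
    stage's pre-activation output."""
    features = np.asarray(features, dtype=np.float64)
    projection = np.asarray(projection, dtype=np.float64)
    if features.ndim != 4:
        raise ShapeError("features must be N×C×H×W")
    if projection.shape != (target_channels, features.shape[1], 1, 1):
        raise ShapeError(
            f"projection kernel must be ({target_channels}, {features.shape[1]}, 1, 1), "
            f"got {projection.shape}"
        )
    up = (nn.UpsampleNearest2x() if interp == "nearest" else nn.UpsampleBilinear2x()).forward(features)
    return np.einsum("oc,nchw->nohw", projection[:, :, 0, 0], up)


class Generator:
    """Materialised generator network for a :class:`GanSpec`."""

    def __init__(self, spec: GanSpec, seed: int | np.random.Generator = 0):
        if spec.kind != "generator":
            raise ParameterError("spec.kind must be 'generator'")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.spec = spec
        self.convs: list[nn.ConvTranspose2d] = []
        self.bns: list[nn.BatchNorm2d | None] = []
        self.acts: list = []
        self.projs: dict[int, nn.Conv2d] = {}     # stage index -> 1×1 projection
        self.ups: dict[int, object] = {}
        n = len(spec.stages)
        cin = spec.latent_dim
        for i, (res, ch) in enumerate(spec.stages):
            if i == 0:
                self.convs.append(nn.ConvTranspose2d(cin, ch, 4, 1, 0, rng))
            else:
                self.convs.append(nn.ConvTranspose2d(cin, ch, 4, 2, 1, rng))
            last = i == n - 1
            self.bns.append(nn.BatchNorm2d(ch) if (spec.use_batchnorm and not last) else None)
            self.acts.append(nn.Tanh() if last else nn.ReLU())
            cin = ch
        # projections are initialised after the main path, so specs differing
        # only in residual_stages share main-path weights under one seed
        for i, (res, ch) in enumerate(spec.stages):
            if i > 0 and res in spec.residual_stages:
                self.projs[i] = nn.Conv2d(spec.stages[i - 1][1], ch, 1, 1, 0, rng)
                self.ups[i] = (
                    nn.UpsampleNearest2x() if spec.residual_interp == "nearest" else nn.UpsampleBilinear2x()
                )

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for conv, bn in zip(self.convs, self.bns):
            ps.extend(conv.params())
            if bn is not None:
                ps.extend(bn.params())
        for i in sorted(self.projs):
            ps.extend(self.projs[i].params())
        return ps

    def forward(self, z: np.ndarray, residual_enabled: bool = True, train: bool = True) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if z.ndim == 1:
            z = z[None]
        if z.shape[1] != self.spec.latent_dim:
            raise ShapeError(f"latent dim {z.shape[1]} != spec {self.spec.latent_dim}")
        x = z.reshape(z.shape[0], self.spec.latent_dim, 1, 1)
        self._res_active: dict[int, bool] = {}
        prev = None
        for i, conv in enumerate(self.convs):
            pre = conv.forward(x, train)
            if self.bns[i] is not None:
                pre = self.bns[i].forward(pre, train)
            use_res = residual_enabled and i in self.projs
            self._res_active[i] = use_res
            if use_res:
                pre = pre + self.projs[i].forward(self.ups[i].forward(prev, train), train)
            x = self.acts[i].forward(pre, train)
            prev = x
        return x

    def backward(self, dimg: np.ndarray) -> np.ndarray:
        dx = dimg
        dprev_extra = None
        for i in range(len(self.convs) - 1, -1, -1):
            if dprev_extra is not None:
                dx = dx + dprev_extra
                dprev_extra = None
            dpre = self.acts[i].backward(dx)
            if self._res_active.get(i, False):
                dres = self.projs[i].backward(dpre)
                dprev_extra = self.ups[i].backward(dres)
            if self.bns[i] is not None:
                dpre = self.bns[i].backward(dpre)
            dx = self.convs[i].backward(dpre)
        return dx

    # -- parameter state ---------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            state[f"conv{i}.w"] = conv.w.value
            state[f"conv{i}.b"] = conv.b.value
            if bn is not None:
                state[f"bn{i}.gamma"] = bn.gamma.value
                state[f"bn{i}.beta"] = bn.beta.value
                state[f"bn{i}.running_mean"] = bn.running_mean
                state[f"bn{i}.running_var"] = bn.running_var
        for i, proj in self.projs.items():
            state[f"proj{i}.w"] = proj.w.value
            state[f"proj{i}.b"] = proj.b.value
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            conv.w.value = np.asarray(state[f"conv{i}.w"], dtype=np.float64)
            conv.b.value = np.asarray(state[f"conv{i}.b"], dtype=np.float64)
            if bn is not None:
                bn.gamma.value = np.asarray(state[f"bn{i}.gamma"], dtype=np.float64)
                bn.beta.value = np.asarray(state[f"bn{i}.beta"], dtype=np.float64)
                bn.running_mean = np.asarray(state[f"bn{i}.running_mean"], dtype=np.float64)
                bn.running_var = np.asarray(state[f"bn{i}.running_var"], dtype=np.float64)
        for i, proj in self.projs.items():
            proj.w.value = np.asarray(state[f"proj{i}.w"], dtype=np.float64)
            proj.b.value = np.asarray(state[f"proj{i}.b"], dtype=np.float64)


class Discriminator:
    """Materialised discriminator network for a :class:`GanSpec`."""

    def __init__(self, spec: GanSpec, seed: int | np.random.Generator = 0):
        if spec.kind != "discriminator":
            raise ParameterError("spec.kind must be 'discriminator'")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.spec = spec
        self.convs: list[nn.Conv2d] = []
        self.bns: list[nn.BatchNorm2d | None] = []
        self.acts: list = []
        n = len(spec.stages)
        cin = 3
        for i, (res, ch) in enumerate(spec.stages):
            last = i == n - 1
            if last:
                self.convs.append(nn.Conv2d(cin, ch, 4, 1, 0, rng))
                self.bns.append(None)
                self.acts.append(nn.Sigmoid())
            else:
                self.convs.append(nn.Conv2d(cin, ch, 4, 2, 1, rng))
                # DC-GAN convention: no normalisation on the first conv layer
                self.bns.append(nn.BatchNorm2d(ch) if (spec.use_batchnorm and i > 0) else None)
                self.acts.append(nn.LeakyReLU(0.2))
            cin = ch

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for conv, bn in zip(self.convs, self.bns):
            ps.extend(conv.params())
            if bn is not None:
                ps.extend(bn.params())
        return ps

    def forward(self, img: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(img, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        expected = self.spec.stages[0][0] * 2
        if x.shape[2] != expected or x.shape[3] != expected:
            raise ShapeError(f"expected {expected}×{expected} input, got {x.shape[2]}×{x.shape[3]}")
        for i, conv in enumerate(self.convs):
            x = conv.forward(x, train)
            if self.bns[i] is not None:
                x = self.bns[i].forward(x, train)
            x = self.acts[i].forward(x, train)
        return x.reshape(x.shape[0])

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        dx = np.asarray(dprob, dtype=np.float64).reshape(-1, 1, 1, 1)
        for i in range(len(self.convs) - 1, -1, -1):
            dx = self.acts[i].backward(dx)
            if self.bns[i] is not None:
                dx = self.bns[i].backward(dx)
            dx = self.convs[i].backward(dx)
        return dx

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            state[f"conv{i}.w"] = conv.w.value
            state[f"conv{i}.b"] = conv.b.value
            if bn is not None:
                state[f"bn{i}.gamma"] = bn.gamma.value
                state[f"bn{i}.beta"] = bn.beta.value
                state[f"bn{i}.running_mean"] = bn.running_mean
                state[f"bn{i}.running_var"] = bn.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            conv.w.value = np.asarray(state[f"conv{i}.w"], dtype=np.float64)
            conv.b.value = np.asarray(state[f"conv{i}.b"], dtype=np.float64)
            if bn is not None:
                bn.gamma.value = np.asarray(state[f"bn{i}.gamma"], dtype=np.float64)
                bn.beta.value = np.asarray(state[f"bn{i}.beta"], dtype=np.float64)
                bn.running_mean = np.asarray(state[f"bn{i}.running_mean"], dtype=np.float64)
                bn.running_var = np.asarray(state[f"bn{i}.running_var"], dtype=np.float64)


def generator_forward(
    z: np.ndarray,
    params: dict[str, np.ndarray],
    spec: GanSpec,
    residual_enabled: bool = True,
) -> np.ndarray:
    """Functional forward pass: build the network from ``spec``, load
    ``params``, and map latents to images in [-1, 1] (eval mode)."""
    gen = Generator(spec, seed=0)
    gen.set_state(params)
    return gen.forward(z, residual_enabled=residual_enabled, train=False)


def discriminator_forward(img: np.ndarray, params: dict[str, np.ndarray], spec: GanSpec) -> np.ndarray:
    """Functional forward pass: probability (one per sample) that each input
    image is real (eval mode)."""
    disc = Discriminator(spec, seed=0)
    disc.set_state(params)
    return disc.forward(img, train=False)


def sample_latents(n: int, latent_dim: int, rng: np.random.Generator) -> np.ndarray:
    """n standard-normal latent vectors."""
    return rng.standard_normal((n, latent_dim))


def save_checkpoint(path, spec: GanSpec, state: dict[str, np.ndarray]) -> None:
    """Single-file checkpoint: parameter arrays plus the YAML spec and its
    hash, so a checkpoint can be rebuilt without external context."""
    np.savez(
        path,
        __spec_yaml__=np.array(spec.to_yaml()),
        __spec_hash__=np.array(spec.hash()),
        **state,
    )


def load_checkpoint(path) -> tuple[GanSpec, dict[str, np.ndarray]]:
    with np.load(path, allow_pickle=False) as data:
        spec = GanSpec.from_yaml(str(data["__spec_yaml__"]))
        if str(data["__spec_hash__"]) != spec.hash():
            raise ParameterError("checkpoint spec hash mismatch")
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    return spec, state
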