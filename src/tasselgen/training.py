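"""Adversarial training of the tassel/sky generators.

The loop follows the classic recipe: per batch, the discriminator is updated
first on one real and one generated batch (cross-entropy loss), then the
generator is updated through the frozen discriminator using the
non-saturating loss −ln D(G(z)).  Both networks are optimised with Adam
(betas 0.5/0.999).  The residual paths in the tassel generator follow a
schedule: enabled for the first ``residual_disable_epoch`` epochs and
switched off afterwards — kept on for the whole run they start injecting
noise into late-training samples.

Every source of randomness (weight init, data shuffling, latent draws) is
derived from ``TrainConfig.seed``, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, TrainingError
from .gan_core import (
    Discriminator,
    GanSpec,
    Generator,
    build_discriminator_spec,
    build_generator_spec,
    sample_latents,
)
from .nn import Adam
from .preprocess import denormalize, normalize

__all__ = [
    "TrainConfig",
    "LossTrace",
    "TrainResult",
    "AblationResult",
    "gan_losses",
    "residual_schedule",
    "train_gan",
    "detect_discriminator_collapse",
    "run_ablation",
]

_EPS = 1e-7  # probability clamp before taking logs


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``residual_disable_epoch`` is the epoch index from which residual
    addition is switched off (None = keep enabled throughout);
    ``g_steps_per_d_step`` gives the generator extra updates per
    discriminator update (default 1:1).
    """

    learning_rate: float
    epochs: int
    batch_size: int = 64
    residual_disable_epoch: int | None = None
    use_batchnorm: bool = False
    seed: int = 0
    resolution: int = 128
    base_channels: int = 64
    latent_dim: int = 100
    g_steps_per_d_step: int = 1

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.epochs < 1 or self.batch_size < 1 or self.g_steps_per_d_step < 1:
            raise ParameterError("epochs, batch_size and g_steps_per_d_step must be >= 1")
        if self.residual_disable_epoch is not None and self.residual_disable_epoch > self.epochs:
            raise ParameterError("residual_disable_epoch must be <= epochs")


@dataclass
class LossTrace:
    """Per-epoch mean discriminator and generator losses."""

    d_loss: np.ndarray
    g_loss: np.ndarray

    def __post_init__(self):
        self.d_loss = np.asarray(self.d_loss, dtype=np.float64)
        self.g_loss = np.asarray(self.g_loss, dtype=np.float64)
        if self.d_loss.shape != self.g_loss.shape:
            raise ParameterError("d_loss and g_loss must have equal length")

    def __len__(self) -> int:
        return len(self.d_loss)


@dataclass
class TrainResult:
    gen_params: dict[str, np.ndarray]
    disc_params: dict[str, np.ndarray]
    trace: LossTrace


def gan_losses(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """Cross-entropy GAN losses from discriminator probabilities.

    d_loss = −mean ln D(x) − mean ln(1 − D(G(z)));
    g_loss = −mean ln D(G(z))  (non-saturating form).
    Probabilities are clamped to [1e−7, 1−1e−7] before the logs.
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1.0 - _EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1.0 - _EPS)
    d_loss = float(-np.mean(np.log(dr)) - np.mean(np.log(1.0 - df)))
    g_loss = float(-np.mean(np.log(df)))
    return d_loss, g_loss


def residual_schedule(epoch: int, disable_epoch: int | None) -> bool:
    """Residual addition is enabled for epochs 0 .. disable_epoch−1 and off
    from ``disable_epoch`` onward; None keeps it always on."""
    if epoch < 0:
        raise ParameterError("epoch must be >= 0")
    return disable_epoch is None or epoch < disable_epoch


def detect_discriminator_collapse(trace: LossTrace, tol: float = 0.01, window: int = 10) -> bool:
    """True iff the per-epoch discriminator loss stays below ``tol`` for
    ``window`` consecutive epochs (early discriminator convergence: the
    generator stops receiving useful gradients)."""
    return collapse_epoch(trace, tol, window) is not None


def collapse_epoch(trace: LossTrace, tol: float = 0.01, window: int = 10) -> int | None:
    """Epoch index at which a collapse window completes, or None."""
    if window < 1:
        raise ParameterError("window must be >= 1")
    run = 0
    for i, v in enumerate(trace.d_loss):
        run = run + 1 if v < tol else 0
        if run >= window:
            return i
    return None


def _to_batch_tensor(images: list[np.ndarray]) -> np.ndarray:
    """uint8 H×W×3 list → float N×3×H×W in [-1, 1]."""
    arr = np.stack([normalize(im) for im in images])
    return arr.transpose(0, 3, 1, 2)


def train_gan(
    dataset: list[np.ndarray],
    gen_spec: GanSpec,
    disc_spec: GanSpec,
    config: TrainConfig,
) -> TrainResult:
    """Run the adversarial loop and return final parameters plus the loss
    trace.  Raises :class:`TrainingError` if any epoch-mean loss becomes
    non-finite."""
    if not dataset:
        raise ParameterError("dataset must be non-empty")
    res = config.resolution
    for im in dataset:
        if im.shape[0] != res or im.shape[1] != res:
            raise ParameterError(f"all images must be {res}×{res}")

    master = np.random.default_rng(config.seed)
    init_rng = np.random.default_rng(master.integers(2 ** 31))
    shuffle_rng = np.random.default_rng(master.integers(2 ** 31))
    latent_rng = np.random.default_rng(master.integers(2 ** 31))

    gen = Generator(gen_spec, seed=init_rng)
    disc = Discriminator(disc_spec, seed=init_rng)
    g_opt = Adam(gen.params(), config.learning_rate)
    d_opt = Adam(disc.params(), config.learning_rate)

    data = _to_batch_tensor(dataset)
    n = len(data)
    bs = min(config.batch_size, n)

    d_trace, g_trace = [], []
    for epoch in range(config.epochs):
        res_on = residual_schedule(epoch, config.residual_disable_epoch)
        order = shuffle_rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - bs + 1, bs):
            real = data[order[start : start + bs]]
            nb = len(real)

            # --- discriminator step (trained first) ---
            z = sample_latents(nb, gen_spec.latent_dim, latent_rng)
            fake = gen.forward(z, residual_enabled=res_on, train=True)
            d_real = disc.forward(real, train=True)
            dr = np.clip(d_real, _EPS, 1.0 - _EPS)
            disc.backward(-1.0 / (nb * dr))
            d_fake = disc.forward(fake, train=True)
            df = np.clip(d_fake, _EPS, 1.0 - _EPS)
            disc.backward(1.0 / (nb * (1.0 - df)))
            d_opt.step()
            d_opt.zero_grad()
            d_loss, _ = gan_losses(d_real, d_fake)

            # --- generator step(s) ---
            g_loss = np.nan
            for _ in range(config.g_steps_per_d_step):
                z = sample_latents(nb, gen_spec.latent_dim, latent_rng)
                fake = gen.forward(z, residual_enabled=res_on, train=True)
                d_fake = disc.forward(fake, train=True)
                df = np.clip(d_fake, _EPS, 1.0 - _EPS)
                _, g_loss = gan_losses(np.array([0.5]), d_fake)
                dimg = disc.backward(-1.0 / (nb * df))
                d_opt.zero_grad()  # discriminator is frozen during the G step
                gen.backward(dimg)
                g_opt.step()
                g_opt.zero_grad()

            d_losses.append(d_loss)
            g_losses.append(g_loss)

        d_mean, g_mean = float(np.mean(d_losses)), float(np.mean(g_losses))
        if not (np.isfinite(d_mean) and np.isfinite(g_mean)):
            raise TrainingError(
                f"non-finite loss at epoch {epoch}: d={d_mean}, g={g_mean} "
                f"(lr={config.learning_rate}, batch={bs})"
            )
        d_trace.append(d_mean)
        g_trace.append(g_mean)

    return TrainResult(gen.get_state(), disc.get_state(), LossTrace(np.array(d_trace), np.array(g_trace)))


@dataclass
class AblationResult:
    """Outcome of one ablation variant."""

    use_batchnorm: bool
    use_residual: bool
    trace: LossTrace
    collapsed: bool
    collapse_epoch: int | None
    min_d_loss: float
    argmin_epoch: int
    samples: list[np.ndarray] = field(default_factory=list)


def run_ablation(
    dataset: list[np.ndarray],
    resolution: int,
    variants: set[tuple[bool, bool]],
    config: TrainConfig,
    n_samples: int = 8,
    collapse_tol: float = 0.01,
    collapse_window: int = 10,
) -> dict[tuple[bool, bool], AblationResult]:
    """Train one run per (use_batchnorm, use_residual) variant under a common
    seed and summarise each: loss trace, collapse diagnosis, minimum
    discriminator loss (and when it is reached), and generated samples."""
    if not variants:
        raise ParameterError("variants must be non-empty")
    report: dict[tuple[bool, bool], AblationResult] = {}
    for use_bn, use_res in sorted(variants):
        gspec = build_generator_spec(
            resolution,
            use_batchnorm=use_bn,
            residual_stages=None if use_res else frozenset(),
            base_channels=config.base_channels,
            latent_dim=config.latent_dim,
        )
        dspec = build_discriminator_spec(resolution, use_batchnorm=use_bn, base_channels=config.base_channels)
        cfg = TrainConfig(
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            batch_size=config.batch_size,
            residual_disable_epoch=config.residual_disable_epoch if use_res else None,
            use_batchnorm=use_bn,
            seed=config.seed,
            resolution=resolution,
            base_channels=config.base_channels,
            latent_dim=config.latent_dim,
            g_steps_per_d_step=config.g_steps_per_d_step,
        )
        result = train_gan(dataset, gspec, dspec, cfg)
        gen = Generator(gspec, seed=0)
        gen.set_state(result.gen_params)
        z = sample_latents(n_samples, config.latent_dim, np.random.default_rng(config.seed))
        imgs = gen.forward(z, residual_enabled=False, train=False)
        samples = [denormalize(im.transpose(1, 2, 0)) for im in imgs]
        ce = collapse_epoch(result.trace, collapse_tol, collapse_window)
        report[(use_bn, use_res)] = AblationResult(
            use_batchnorm=use_bn,
            use_residual=use_res,
            trace=result.trace,
            collapsed=ce is not None,
            collapse_epoch=ce,
            min_d_loss=float(result.trace.d_loss.min()),
            argmin_epoch=int(result.trace.d_loss.argmin()),
            samples=samples,
        )
    return report
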