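"""Architecture specs, forward-pass contracts and the residual path."""

import numpy as np
import pytest

from tasselgen import nn
from tasselgen.errors import ParameterError, ShapeError
from tasselgen.gan_core import (
    DEFAULT_RESIDUAL_STAGES,
    Discriminator,
    GanSpec,
    Generator,
    build_discriminator_spec,
    build_generator_spec,
    compute_residual,
    discriminator_forward,
    generator_forward,
    sample_latents,
)


class TestSpecs:
    @pytest.mark.parametrize("resolution,n_stages", [(128, 6), (64, 5), (32, 4), (8, 2)])
    def test_generator_stage_count(self, resolution, n_stages):
        spec = build_generator_spec(resolution)
        assert len(spec.stages) == n_stages
        assert spec.stages[0][0] == 4
        assert spec.stages[-1] == (resolution, 3)

    def test_stage_count_matches_log_formula(self):
        for r in (8, 16, 32, 64, 128, 256):
            expected = int(np.log2(r / 4)) + 1
            assert len(build_generator_spec(r).stages) == expected
            assert len(build_discriminator_spec(r).stages) == expected

    def test_default_residual_stages_for_tassel_model(self):
        assert build_generator_spec(128).residual_stages == frozenset({16, 32, 64, 128})
        assert build_generator_spec(64).residual_stages == frozenset({16, 32, 64})

    def test_channel_widths_follow_dcgan_doubling(self):
        chans = [c for _, c in build_generator_spec(128).stages]
        assert chans == [1024, 512, 256, 128, 64, 3]
        assert [c for _, c in build_generator_spec(64).stages] == [512, 256, 128, 64, 3]

    def test_discriminator_gains_a_stage_at_128(self):
        assert len(build_discriminator_spec(128).stages) == len(build_discriminator_spec(64).stages) + 1

    @pytest.mark.parametrize("resolution", [7, 12, 0, 96])
    def test_non_power_of_two_rejected(self, resolution):
        with pytest.raises(ParameterError):
            build_generator_spec(resolution)

    def test_residual_stages_must_be_stage_resolutions(self):
        with pytest.raises(ParameterError):
            build_generator_spec(32, residual_stages={64})

    def test_yaml_roundtrip(self):
        spec = build_generator_spec(64, use_batchnorm=True, base_channels=8)
        assert GanSpec.from_yaml(spec.to_yaml()) == spec


class TestResidual:
    def test_shape_contract(self):
        feat = np.random.default_rng(0).standard_normal((2, 256, 8, 8))
        proj = np.random.default_rng(1).standard_normal((128, 256, 1, 1))
        out = compute_residual(feat, 128, proj)
        assert out.shape == (2, 128, 16, 16)

    def test_zero_projection_contributes_nothing(self):
        feat = np.random.default_rng(0).standard_normal((1, 16, 8, 8))
        out = compute_residual(feat, 8, np.zeros((8, 16, 1, 1)))
        assert (out == 0).all()

    def test_constant_features_stay_constant(self):
        feat = np.full((1, 4, 8, 8), 2.5)
        proj = np.zeros((3, 4, 1, 1))
        proj[:, 0, 0, 0] = 1.0  # pick out channel 0
        out = compute_residual(feat, 3, proj, interp="bilinear")
        assert np.allclose(out, 2.5)

    @pytest.mark.parametrize("resolution", [64, 128])
    def test_shapes_for_every_consecutive_stage_pair(self, resolution):
        spec = build_generator_spec(resolution, base_channels=4)
        rng = np.random.default_rng(0)
        for (r0, c0), (r1, c1) in zip(spec.stages, spec.stages[1:]):
            feat = rng.standard_normal((1, c0, r0, r0))
            proj = rng.standard_normal((c1, c0, 1, 1))
            assert compute_residual(feat, c1, proj).shape == (1, c1, r1, r1)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            compute_residual(np.zeros((1, 16, 8, 8)), 8, np.zeros((8, 4, 1, 1)))


@pytest.fixture(scope="module")
def small_nets():
    gs = build_generator_spec(32, base_channels=8, latent_dim=16)
    ds = build_discriminator_spec(32, base_channels=8)
    return Generator(gs, seed=1), Discriminator(ds, seed=2), gs, ds


class TestForward:

    def test_generator_output_shape_and_range(self, small_nets):
        gen, _, gs, _ = small_nets
        z = sample_latents(4, gs.latent_dim, np.random.default_rng(0))
        img = gen.forward(z)
        assert img.shape == (4, 3, 32, 32)
        assert img.min() >= -1.0 and img.max() <= 1.0

    def test_generator_deterministic(self, small_nets):
        gen, _, gs, _ = small_nets
        z = sample_latents(2, gs.latent_dim, np.random.default_rng(3))
        assert np.array_equal(gen.forward(z), gen.forward(z))

    def test_residual_disabled_equals_empty_residual_set(self):
        gs = build_generator_spec(32, base_channels=8, latent_dim=16)
        gs_empty = build_generator_spec(32, residual_stages=frozenset(), base_channels=8, latent_dim=16)
        z = sample_latents(2, 16, np.random.default_rng(4))
        assert np.array_equal(
            Generator(gs, seed=9).forward(z, residual_enabled=False),
            Generator(gs_empty, seed=9).forward(z),
        )

    def test_discriminator_probability_range(self, small_nets):
        gen, disc, gs, _ = small_nets
        z = sample_latents(3, gs.latent_dim, np.random.default_rng(5))
        p = disc.forward(gen.forward(z))
        assert p.shape == (3,)
        assert ((p > 0) & (p < 1)).all()

    def test_batch_order_invariance_without_batchnorm(self, small_nets):
        gen, disc, gs, _ = small_nets
        z = sample_latents(4, gs.latent_dim, np.random.default_rng(6))
        imgs = gen.forward(z)
        batched = disc.forward(imgs)
        single = np.array([disc.forward(imgs[i : i + 1])[0] for i in range(4)])
        assert np.array_equal(batched, single)

    def test_no_batchnorm_spec_has_no_normalisation_layers(self, small_nets):
        gen, disc, _, _ = small_nets
        assert all(bn is None for bn in gen.bns)
        assert all(bn is None for bn in disc.bns)

    def test_latent_dim_mismatch_rejected(self, small_nets):
        gen, _, _, _ = small_nets
        with pytest.raises(ShapeError):
            gen.forward(np.zeros((1, 7)))

    def test_functional_wrappers_match_state(self, small_nets):
        gen, disc, gs, ds = small_nets
        z = sample_latents(2, gs.latent_dim, np.random.default_rng(7))
        img = gen.forward(z, train=False)
        assert np.array_equal(generator_forward(z, gen.get_state(), gs), img)
        assert np.array_equal(discriminator_forward(img, disc.get_state(), ds), disc.forward(img, train=False))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """End-to-end gradient check through generator (with residual and
        batch-norm) and discriminator against central differences."""
        gs = build_generator_spec(16, use_batchnorm=True, base_channels=4, latent_dim=8, residual_stages={8, 16})
        ds = build_discriminator_spec(16, use_batchnorm=True, base_channels=4)
        gen, disc = Generator(gs, seed=3), Discriminator(ds, seed=4)
        z = np.random.default_rng(1).standard_normal((2, 8))

        def loss():
            p = disc.forward(gen.forward(z))
            return float(-np.log(np.clip(p, 1e-7, 1 - 1e-7)).mean())

        p = disc.forward(gen.forward(z))
        dimg = disc.backward(-1.0 / (len(p) * np.clip(p, 1e-7, 1 - 1e-7)))
        gen.backward(dimg)

        rng = np.random.default_rng(5)
        params = [gen.convs[1].w, gen.projs[1].w, gen.bns[0].gamma, disc.convs[0].w, disc.bns[1].beta]
        for param in params:
            idx = tuple(rng.integers(0, s) for s in param.value.shape)
            eps, orig = 1e-6, param.value[idx]
            param.value[idx] = orig + eps
            lp = loss()
            param.value[idx] = orig - eps
            lm = loss()
            param.value[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = param.grad[idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), (num, ana)

    def test_upsample_bilinear_backward_is_transpose(self):
        up = nn.UpsampleBilinear2x()
        x = np.random.default_rng(0).standard_normal((1, 2, 5, 5))
        y = up.forward(x)
        dy = np.random.default_rng(1).standard_normal(y.shape)
        dx = up.backward(dy)
        # <Ax, dy> == <x, A^T dy> for a linear map
        assert np.allclose((y * dy).sum(), (x * dx).sum())
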