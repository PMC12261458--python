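import numpy as np
import pytest

from genodiff._nn import Adam, Tensor
from genodiff.denoisers import UNetMLP
from genodiff.diffusion_core import (
    DiffusionConfig,
    NoiseSchedule,
    build_schedule,
    draw_noise,
    embedding_clip_bound,
    forward_noise,
    one_shot_reconstruct,
    sample,
    train_denoiser,
    training_step,
)
from genodiff.gene_embedding import GeneEmbedding, apply_clamp


class OracleEpsilon:
    """Recovers the exact injected noise from (x_t, t) given the clean x0."""

    def __init__(self, x0, schedule):
        self.x0 = x0
        self.schedule = schedule

    def forward(self, x_t, t_norm, y):
        t = np.rint(np.asarray(t_norm) * self.schedule.T).astype(int)
        abar = self.schedule.abar(t).reshape(-1, 1, 1)
        eps = (x_t - np.sqrt(abar) * self.x0) / np.sqrt(1.0 - abar)
        return Tensor(eps)

    def parameters(self):
        return []


class ConstantModel:
    def __init__(self, value):
        self.value = value

    def forward(self, x_t, t_norm, y):
        return Tensor(np.broadcast_to(self.value, np.shape(x_t)).copy())

    def parameters(self):
        return []


@pytest.fixture
def mask():
    m = np.ones((8, 8))
    m[6:] = 0.0
    m[:, 5:] = 0.0
    return m


class TestSchedule:
    def test_single_step(self):
        s = build_schedule(1, 0.5, 0.5)
        np.testing.assert_allclose(s.alpha_bar, [0.5])

    def test_alpha_bar_strictly_decreasing(self):
        s = build_schedule(1000, 1e-4, 0.02)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert s.alpha_bar[0] >= 1 - 2 * s.beta[0]

    def test_constant_beta_closed_form(self):
        s = build_schedule(10, 0.1, 0.1)
        np.testing.assert_allclose(s.alpha_bar[-1], 0.9 ** 10, rtol=1e-12)

    @pytest.mark.parametrize("args", [(0, 1e-4, 0.02), (10, 0.0, 0.02), (10, 0.5, 0.1),
                                      (10, 0.1, 1.0)])
    def test_invalid_ranges_rejected(self, args):
        with pytest.raises(ValueError):
            build_schedule(*args)


class TestForwardNoise:
    def test_single_step_algebra(self, mask):
        s = build_schedule(1, 0.5, 0.5)
        rng = np.random.default_rng(0)
        x0 = apply_clamp(rng.standard_normal((3, 8, 8)), mask)
        eps = draw_noise(x0.shape, mask, rng)
        x_t = forward_noise(x0, 1, eps, s, mask)
        np.testing.assert_allclose(x_t, apply_clamp(np.sqrt(0.5) * x0 + np.sqrt(0.5) * eps, mask))

    def test_shape_mismatch_rejected(self, mask):
        s = build_schedule(10)
        with pytest.raises(ValueError, match="shape"):
            forward_noise(np.zeros((2, 8, 8)), 1, np.zeros((3, 8, 8)), s, mask)

    def test_marginal_variance_matches_closed_form(self, mask):
        """Monte-Carlo at 10^4 draws: per-live-slot variance is 1 - alpha_bar."""
        s = build_schedule(50)
        t = 30
        x0 = apply_clamp(np.full((1, 8, 8), 0.7), mask)
        rng = np.random.default_rng(1)
        draws = np.stack([
            forward_noise(x0, t, draw_noise(x0.shape, mask, rng), s, mask)[0]
            for _ in range(10_000)
        ])
        var = draws.var(axis=0)
        expected = 1.0 - s.abar(t)
        live = mask > 0
        np.testing.assert_allclose(var[live], expected, rtol=0.05)
        assert np.all(var[~live] == 0.0)
        np.testing.assert_allclose(draws.mean(axis=0)[live], np.sqrt(s.abar(t)) * 0.7,
                                   atol=0.02)


class TestTrainingStep:
    def test_oracle_epsilon_gives_zero_loss(self, mask):
        s = build_schedule(20)
        rng = np.random.default_rng(2)
        x0 = apply_clamp(rng.standard_normal((16, 8, 8)), mask)
        model = OracleEpsilon(x0, s)
        loss = training_step(model, Adam([]), x0, None, s, mask, np.random.default_rng(3))
        assert loss < 1e-18

    def test_zero_predictor_loss_near_unity(self, mask):
        s = build_schedule(20)
        rng = np.random.default_rng(4)
        x0 = apply_clamp(rng.standard_normal((256, 8, 8)), mask)
        loss = training_step(ConstantModel(0.0), Adam([]), x0, None, s, mask,
                             np.random.default_rng(5))
        assert abs(loss - 1.0) < 0.1  # mean of ~7680 squared unit normals

    def test_loss_decreases_on_two_gene_toy(self, mask):
        """Recorded training curve: early-loss mean exceeds late-loss mean."""
        s = build_schedule(50)
        rng = np.random.default_rng(6)
        base = apply_clamp(rng.standard_normal((1, 8, 8)), mask)
        x0 = np.repeat(base, 64, axis=0) + 0.1 * draw_noise((64, 8, 8), mask, rng)
        model = UNetMLP(8, 1, 2, seed=0)
        opt = Adam(model.parameters(), lr=1e-3)
        losses = [
            training_step(model, opt, x0, np.zeros(64, dtype=int), s, mask,
                          np.random.default_rng(100 + i))
            for i in range(200)
        ]
        assert np.mean(losses[-20:]) < np.mean(losses[:20])


class TestSampling:
    def test_padded_slots_exactly_zero(self, mask):
        s = build_schedule(5)
        out = sample(ConstantModel(0.1), 4, 1, s, mask, np.random.default_rng(0))
        assert out.shape == (4, 8, 8)
        assert np.all(out[:, mask == 0] == 0.0)

    def test_single_step_posterior_mean_by_hand(self, mask):
        s = build_schedule(1, 0.3, 0.3)
        eps0 = 0.25
        seed = 9
        out = sample(ConstantModel(eps0), 2, None, s, mask, np.random.default_rng(seed))
        rng = np.random.default_rng(seed)
        x1 = draw_noise((2, 8, 8), mask, rng)
        expected = apply_clamp((x1 - 0.3 / np.sqrt(1 - 0.7) * eps0) / np.sqrt(0.7), mask)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_same_seed_identical_tensors(self, mask):
        s = build_schedule(10)
        a = sample(ConstantModel(0.2), 3, 0, s, mask, np.random.default_rng(7))
        b = sample(ConstantModel(0.2), 3, 0, s, mask, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_n_rejected(self, mask):
        with pytest.raises(ValueError):
            sample(ConstantModel(0.0), 0, None, build_schedule(5), mask,
                   np.random.default_rng(0))


class TestOneShotReconstruct:
    def test_oracle_predictor_inverts_exactly(self, mask):
        s = build_schedule(40)
        rng = np.random.default_rng(8)
        x0 = apply_clamp(rng.standard_normal((5, 8, 8)), mask)
        x_p, err = one_shot_reconstruct(OracleEpsilon(x0, s), x0, 25, s, mask,
                                        np.random.default_rng(9))
        np.testing.assert_allclose(x_p, x0, atol=1e-10)
        assert err < 1e-10

    def test_zero_predictor_error_algebra(self, mask):
        """x_p = x_t / sqrt(abar), so the error is sqrt((1-abar)/abar)*||eps||
        plus the (sqrt(abar)-1)/sqrt(abar) shrinkage of x0 itself."""
        s = build_schedule(40)
        rng = np.random.default_rng(10)
        x0 = apply_clamp(rng.standard_normal((3, 8, 8)), mask)
        t, seed = 2, 11
        x_p, err = one_shot_reconstruct(ConstantModel(0.0), x0, t, s, mask,
                                        np.random.default_rng(seed))
        eps = draw_noise(x0.shape, mask, np.random.default_rng(seed))
        abar = s.abar(t)
        expected = np.linalg.norm(x0 - (np.sqrt(abar) * x0 + np.sqrt(1 - abar) * eps)
                                  / np.sqrt(abar))
        np.testing.assert_allclose(err, expected, rtol=1e-10)

    def test_padded_slots_contribute_nothing(self, mask):
        s = build_schedule(10)
        rng = np.random.default_rng(12)
        x0 = apply_clamp(rng.standard_normal((2, 8, 8)), mask)
        x_p, _ = one_shot_reconstruct(ConstantModel(0.5), x0, 5, s, mask,
                                      np.random.default_rng(13))
        assert np.all(x_p[:, mask == 0] == 0.0)

    def test_out_of_range_t_rejected(self, mask):
        s = build_schedule(10)
        with pytest.raises(ValueError):
            one_shot_reconstruct(ConstantModel(0.0), np.zeros((1, 8, 8)), 11, s, mask,
                                 np.random.default_rng(0))

    def test_degenerate_alpha_bar_rejected(self, mask):
        s = NoiseSchedule(T=1, beta=np.array([1.0]), alpha=np.array([0.0]),
                          alpha_bar=np.array([0.0]))
        with pytest.raises(ValueError, match="alpha_bar"):
            one_shot_reconstruct(ConstantModel(0.0), np.zeros((1, 8, 8)), 1, s, mask,
                                 np.random.default_rng(0))


class TestTrainDenoiser:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            DiffusionConfig(T=0)
        with pytest.raises(ValueError):
            DiffusionConfig(learning_rate=-1.0)

    def test_class_conditional_means_learned(self, mask):
        """On a two-class toy, generated class means move toward the data
        class means as training proceeds."""
        rng = np.random.default_rng(14)
        centers = {0: -1.5, 1: 1.5}
        n = 128
        labels = np.repeat([0, 1], n // 2)
        x = np.stack([
            apply_clamp(centers[l] + 0.3 * rng.standard_normal((8, 8)), mask) for l in labels
        ])
        emb = GeneEmbedding(x, mask, labels, depth=1, n_genes=6)
        model = UNetMLP(8, 1, 2, seed=1)
        cfg = DiffusionConfig(T=200, beta_start=1e-4, beta_end=0.1, epochs=100,
                              batch_size=32, learning_rate=2e-3, seed=1)
        history = train_denoiser(model, emb, cfg, rng=np.random.default_rng(15))
        assert np.mean(history.loss[-10:]) < np.mean(history.loss[:10])
        assert history.recon_error[-1] < history.recon_error[0]
        live = mask > 0
        sch = cfg.schedule()
        clip = embedding_clip_bound(emb)
        for l in (0, 1):
            gen = sample(model, 32, l, sch, mask, np.random.default_rng(16), x0_clip=clip)
            gen_mean = gen[:, live].mean()
            assert abs(gen_mean - centers[l]) < 0.75, (l, gen_mean)
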