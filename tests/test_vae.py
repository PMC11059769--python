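"""Attention VAE: softmax contracts, ELBO terms, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from mbdetect.vae import (
    AttentionVAE,
    AttentionWeights,
    DivergenceError,
    LatentDistribution,
    TrainingConfig,
    apply_attention,
    attention,
    decode,
    elbo_loss,
    encode,
    gaussian_kl,
    init_params,
    reparameterize,
    train,
)

TINY = TrainingConfig(
    hidden_size=16, latent_dim=4, epochs=3, batch_size=8, dropout=0.0, weight_decay=0.0, seed=3
)


@pytest.fixture(scope="module")
def tiny_params():
    return init_params(12, TINY)


class TestTrainingConfig:
    def test_published_defaults(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.epochs == 100
        assert cfg.batch_size == 32
        assert (cfg.encoder_layers, cfg.decoder_layers, cfg.attention_layers) == (3, 3, 2)
        assert cfg.hidden_size == 256
        assert cfg.latent_dim == 50
        assert cfg.dropout == 0.2
        assert cfg.weight_decay == 0.001
        assert cfg.kl_weight == 0.5 and cfg.recon_weight == 0.5

    def test_round_trip(self):
        cfg = TrainingConfig(epochs=7)
        assert TrainingConfig.from_dict(cfg.to_dict()) == cfg


class TestAttention:
    def test_constant_scores_give_uniform_weights(self, tiny_params):
        # zero-initialised score head: any input yields uniform weights
        w = attention(np.ones(12, dtype=np.float32), tiny_params)
        np.testing.assert_allclose(w.weights, np.full(12, 1 / 12), atol=1e-9)

    def test_weights_sum_to_one_and_shift_invariance(self, rng):
        from scipy.special import softmax as scipy_softmax

        params = init_params(20, TINY)
        # give the head non-trivial weights
        params["att_W2"] = rng.normal(size=params["att_W2"].shape).astype(np.float32)
        for _ in range(100):
            x = rng.normal(size=20).astype(np.float32)
            w = attention(x, params)
            assert abs(w.weights.sum() - 1.0) < 1e-9
            assert np.all((w.weights > 0) & (w.weights < 1))
            # cross-check against an independent softmax
            np.testing.assert_allclose(
                w.weights, scipy_softmax(w.raw_scores.astype(np.float64)), atol=1e-6
            )
            shifted = AttentionWeights(
                weights=np.exp(w.raw_scores + 100.0 - np.max(w.raw_scores + 100.0)),
                raw_scores=w.raw_scores + 100.0,
            )
            shifted_w = shifted.weights / shifted.weights.sum()
            np.testing.assert_allclose(w.weights, shifted_w, atol=1e-6)

    def test_non_finite_input_raises(self, tiny_params):
        with pytest.raises(FloatingPointError):
            attention(np.array([np.nan] * 12), tiny_params)


class TestGating:
    def test_uniform_attention_is_identity(self, rng):
        x = rng.normal(size=10)
        w = AttentionWeights(weights=np.full(10, 0.1), raw_scores=np.zeros(10))
        np.testing.assert_allclose(apply_attention(x, w), x, atol=1e-7)

    def test_matches_elementwise_product(self, rng):
        x = rng.normal(size=9)
        raw = rng.normal(size=9)
        e = np.exp(raw - raw.max())
        w = AttentionWeights(weights=e / e.sum(), raw_scores=raw)
        expected = np.array([x[i] * 9 * w.weights[i] for i in range(9)])
        np.testing.assert_allclose(apply_attention(x, w), expected, atol=1e-6)

    def test_dominant_weight_concentrates_mass(self):
        x = np.ones(5)
        w = np.array([0.96, 0.01, 0.01, 0.01, 0.01])
        g = apply_attention(x, AttentionWeights(weights=w, raw_scores=np.zeros(5)))
        assert g[0] > 0.9 * g.sum()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            apply_attention(np.ones(4), AttentionWeights(np.full(5, 0.2), np.zeros(5)))


class TestEncodeDecode:
    def test_eval_mode_is_deterministic(self, tiny_params, rng):
        x = rng.normal(size=12).astype(np.float32)
        a = encode(x, tiny_params)
        b = encode(x, tiny_params)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.log_var, b.log_var)
        np.testing.assert_array_equal(decode(a.mu, tiny_params), decode(b.mu, tiny_params))

    def test_latent_and_output_dimensions(self):
        cfg = TrainingConfig(hidden_size=32, latent_dim=50, seed=0)
        params = init_params(30, cfg)
        dist = encode(np.ones(30, dtype=np.float32), params)
        assert dist.mu.shape == (50,) and dist.log_var.shape == (50,)
        assert decode(dist.mu, params).shape == (30,)

    def test_fresh_network_outputs_are_bounded(self):
        params = init_params(40, TrainingConfig(seed=0))
        dist = encode(np.ones(40, dtype=np.float32), params)
        assert np.all(np.isfinite(dist.mu))
        assert np.max(np.abs(dist.mu)) < 10

    def test_dimension_mismatch(self, tiny_params):
        with pytest.raises(ValueError):
            encode(np.ones(13), tiny_params)
        with pytest.raises(ValueError):
            decode(np.ones(5), tiny_params)


class TestReparameterize:
    def test_zero_noise_returns_mean(self, rng):
        dist = LatentDistribution(mu=rng.normal(size=6), log_var=rng.normal(size=6))
        np.testing.assert_allclose(reparameterize(dist, np.zeros(6)), dist.mu)

    def test_degenerate_sigma(self):
        dist = LatentDistribution(mu=np.arange(4.0), log_var=np.full(4, -80.0))
        np.testing.assert_allclose(reparameterize(dist, np.ones(4)), dist.mu, atol=1e-15)

    def test_monte_carlo_mean(self, rng):
        n = 100_000
        dist = LatentDistribution(mu=np.array([1.5, -2.0]), log_var=np.array([0.3, -1.0]))
        eps = rng.standard_normal((n, 2))
        samples = reparameterize(dist, eps)
        tol = 3 * dist.sigma / np.sqrt(n)
        assert np.all(np.abs(samples.mean(axis=0) - dist.mu) < tol)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            reparameterize(LatentDistribution(np.zeros(3), np.zeros(3)), np.zeros(4))


class TestElbo:
    def test_prior_posterior_match_gives_zero_kl(self):
        loss = elbo_loss(
            np.ones(5),
            np.zeros(5),
            LatentDistribution(np.zeros(3), np.zeros(3)),
        )
        assert loss.kl == 0.0

    def test_perfect_reconstruction_gives_zero_recon(self, rng):
        x = rng.normal(size=8)
        loss = elbo_loss(x, x, LatentDistribution(np.ones(3), np.zeros(3)))
        assert loss.reconstruction == 0.0
        assert loss.total == 0.5 * loss.kl

    def test_kl_closed_form_matches_monte_carlo(self, rng):
        # E_q[log q(z) - log p(z)] estimated with 10^6 samples
        for _ in range(20):
            d = 4
            mu = rng.normal(scale=1.5, size=d)
            lv = rng.uniform(-1.5, 1.0, size=d)
            sigma = np.exp(lv / 2)
            z = mu + sigma * rng.standard_normal((1_000_000, d))
            log_q = -0.5 * np.sum(((z - mu) / sigma) ** 2 + lv + np.log(2 * np.pi), axis=1)
            log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
            mc = np.mean(log_q - log_p)
            closed = gaussian_kl(mu, lv)
            assert abs(closed - mc) / abs(closed) < 0.01

    @given(
        mu=arrays(np.float64, 5, elements=st.floats(-5, 5)),
        lv=arrays(np.float64, 5, elements=st.floats(-4, 4)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kl_nonnegative(self, mu, lv):
        assert gaussian_kl(mu, lv) >= 0.0

    def test_kl_zero_iff_standard_normal(self, rng):
        assert gaussian_kl(np.zeros(7), np.zeros(7)) == 0.0
        mu = rng.normal(size=7)
        assert gaussian_kl(mu, np.zeros(7)) > 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            elbo_loss(np.ones(3), np.ones(4), LatentDistribution(np.zeros(2), np.zeros(2)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        from mbdetect.vae import _forward_backward

        cfg = TrainingConfig(
            hidden_size=7, latent_dim=3, batch_size=4, dropout=0.0, weight_decay=0.0, seed=3
        )
        F = 11
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(4, F))
        params = {k: v.astype(np.float64) for k, v in init_params(F, cfg).items()}
        params[f"att_W{cfg.attention_layers}"] = 0.1 * rng.normal(
            size=params[f"att_W{cfg.attention_layers}"].shape
        )
        eps = np.random.default_rng(1).standard_normal((4, cfg.latent_dim))

        class FixedNoise:
            def standard_normal(self, size=None):
                return eps

        def loss_of(p):
            r, k, _ = _forward_backward(X, p, cfg, FixedNoise())
            return cfg.recon_weight * r + cfg.kl_weight * k

        _, _, grads = _forward_backward(X, params, cfg, FixedNoise())
        h = 1e-6
        for key, g in grads.items():
            num = np.zeros_like(params[key])
            it = np.nditer(params[key], flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                p2 = {k: v.copy() for k, v in params.items()}
                p2[key][i] += h
                lp = loss_of(p2)
                p2[key][i] -= 2 * h
                lm = loss_of(p2)
                num[i] = (lp - lm) / (2 * h)
            scale = max(np.max(np.abs(num)), 1e-8)
            assert np.max(np.abs(num - g)) / scale < 1e-5, key


class TestTraining:
    def test_seeded_runs_are_bit_identical(self, rng):
        X = rng.uniform(0, 1, size=(8, 12)).astype(np.float32)
        _, h1 = train(X, TINY)
        _, h2 = train(X, TINY)
        assert [b.total for b in h1] == [b.total for b in h2]
        assert [b.reconstruction for b in h1] == [b.reconstruction for b in h2]

    def test_history_length_and_decomposition_identity(self, rng):
        X = rng.uniform(0, 1, size=(16, 12)).astype(np.float32)
        cfg = TrainingConfig(hidden_size=16, latent_dim=4, epochs=5, batch_size=8, seed=2)
        _, hist = train(X, cfg)
        assert len(hist) == 5
        for row in hist:
            assert abs(row.total - (0.5 * row.reconstruction + 0.5 * row.kl)) < 1e-9
            assert row.kl >= 0

    def test_loss_decreases_on_tiny_problem(self, rng):
        X = rng.uniform(0, 1, size=(32, 12)).astype(np.float32)
        cfg = TrainingConfig(hidden_size=16, latent_dim=4, epochs=30, batch_size=8, seed=1)
        _, hist = train(X, cfg)
        assert hist[-1].total < hist[0].total

    def test_trained_model_beats_untrained(self, rng):
        X = rng.uniform(0, 1, size=(32, 12)).astype(np.float32)
        cfg = TrainingConfig(hidden_size=16, latent_dim=4, epochs=30, batch_size=8, seed=1)
        fresh = init_params(12, cfg)
        trained, _ = train(X, cfg)

        def recon_mse(params):
            from mbdetect.vae import apply_attention as gate, attention as att

            g = gate(X, att(X, params))
            dist = encode(g, params)
            return float(np.mean((decode(dist.mu, params) - g) ** 2))

        assert recon_mse(trained) < recon_mse(fresh)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(np.empty((0, 5), dtype=np.float32), TINY)

    def test_divergence_is_reported_with_epoch(self, rng):
        X = (1e3 * rng.uniform(1, 2, size=(16, 8))).astype(np.float32)
        cfg = TrainingConfig(
            hidden_size=8, latent_dim=2, epochs=5, batch_size=4, learning_rate=1e12, seed=0
        )
        with np.errstate(all="ignore"), pytest.raises(DivergenceError, match="epoch"):
            train(X, cfg)


class TestEstimator:
    def test_fit_sets_artifacts_and_saves(self, rng, tmp_path):
        X = rng.uniform(0, 1, size=(12, 10)).astype(np.float32)
        model = AttentionVAE(hidden_size=8, latent_dim=3, epochs=2, batch_size=4, seed=0)
        model.fit(X)
        assert model.n_features_in_ == 10
        assert len(model.history_) == 2
        g, xhat = model.reconstruct(X)
        assert g.shape == xhat.shape == X.shape
        model.save(tmp_path / "ckpt")
        loaded = AttentionVAE.load(tmp_path / "ckpt")
        g2, xhat2 = loaded.reconstruct(X)
        np.testing.assert_array_equal(xhat, xhat2)

    def test_get_set_params(self):
        model = AttentionVAE()
        assert model.get_params()["epochs"] == 100
        model.set_params(epochs=5)
        assert model.config.epochs == 5
        with pytest.raises(ValueError):
            model.set_params(nonsense=1)
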