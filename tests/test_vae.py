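import numpy as np
import pytest

from brainuad.vae import (
    VAE,
    LatentCode,
    NetworkConfig,
    kl_term,
    load_checkpoint,
    recon_l1,
    reparameterize,
    save_checkpoint,
    vae_loss,
)
from brainuad.vae import nn


def small_cfg(rank, **kw):
    base = dict(rank=rank, input_extent=16, latent_dim=16, stage_channels=(8, 16),
                seed=0)
    base.update(kw)
    return NetworkConfig(**base)


class TestArchitecture:
    def test_default_latent_sizes_by_rank(self):
        assert NetworkConfig(rank=2).latent_dim == 128
        assert NetworkConfig(rank=3).latent_dim == 512

    @pytest.mark.parametrize("rank", [2, 3])
    def test_encode_decode_shapes(self, rank, rng):
        cfg = small_cfg(rank)
        model = VAE(cfg)
        x = rng.random((2,) + (16,) * rank).astype(np.float32)
        code = model.encode(x)
        assert code.mu.shape == (2, 16) and code.logvar.shape == (2, 16)
        x_hat = model.decode(code.mu)
        assert x_hat.shape == x.shape

    def test_first_stage_halves_the_spatial_extent(self, rng):
        cfg = small_cfg(3)
        model = VAE(cfg)
        x = rng.random((1, 1, 16, 16, 16)).astype(np.float32)
        first = model.encoder.layers[0].forward(x)
        assert first.shape[2:] == (8, 8, 8)

    def test_decoder_output_bounded_to_unit_interval(self, rng):
        model = VAE(small_cfg(3))
        z = 100.0 * rng.standard_normal((4, 16)).astype(np.float32)
        out = model.decode(z)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_2d_and_3d_share_the_same_structure(self):
        """Same layer count and channel progression, only operator rank differs."""
        m2, m3 = VAE(small_cfg(2)), VAE(small_cfg(3))
        assert len(m2.encoder.layers) == len(m3.encoder.layers)
        assert len(m2.decoder.layers) == len(m3.decoder.layers)
        for l2, l3 in zip(m2.encoder.layers, m3.encoder.layers):
            assert type(l2) is type(l3)
            if isinstance(l2, nn.Conv):
                assert (l2.c_in, l2.c_out) == (l3.c_in, l3.c_out)
                assert (l2.rank, l3.rank) == (2, 3)

    def test_parameter_count_stable_under_fixed_config(self):
        assert VAE(small_cfg(3)).n_parameters() == VAE(small_cfg(3)).n_parameters()

    @pytest.mark.parametrize("kwargs", [
        {"rank": 4},
        {"latent_dim": 0},
        {"input_extent": 20, "stage_channels": (8, 16, 32)},
        {"kernel_size": 3},
        {"output_activation": "tanh"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_cfg(kwargs.pop("rank", 3), **kwargs)

    def test_shape_mismatch_rejected(self, rng):
        model = VAE(small_cfg(3))
        with pytest.raises(ValueError):
            model.encode(rng.random((1, 8, 8, 8)))
        with pytest.raises(ValueError):
            model.decode(rng.random((1, 7)))


class TestReparameterize:
    def test_zero_variance_limit_returns_mu(self):
        code = LatentCode(np.ones((1, 4)), np.full((1, 4), -80.0))
        z = reparameterize(code, np.random.default_rng(0))
        assert np.allclose(z, 1.0, atol=1e-12)

    def test_fixed_seed_reproducible(self):
        code = LatentCode(np.zeros((2, 8)), np.zeros((2, 8)))
        z1 = reparameterize(code, np.random.default_rng(5))
        z2 = reparameterize(code, np.random.default_rng(5))
        assert np.array_equal(z1, z2)

    def test_sample_mean_matches_mu_by_clt(self):
        code = LatentCode(np.zeros((10_000, 3)), np.zeros((10_000, 3)))
        z = reparameterize(code, np.random.default_rng(7))
        assert np.all(np.abs(z.mean(axis=0)) <= 3.0 / np.sqrt(10_000))


class TestLosses:
    def test_recon_l1_perfect_and_extreme(self, rng):
        x = rng.random((2, 8, 8))
        assert recon_l1(x, x) == 0.0
        assert recon_l1(np.zeros((4, 4)), np.ones((4, 4))) == 1.0

    def test_recon_l1_matches_elementwise_loop(self, rng):
        a, b = rng.random((3, 5, 5)), rng.random((3, 5, 5))
        brute = sum(abs(float(x) - float(y))
                    for x, y in zip(a.ravel(), b.ravel())) / a.size
        assert recon_l1(a, b) == pytest.approx(brute, abs=1e-7)

    def test_kl_closed_form_values(self):
        assert kl_term(LatentCode(np.zeros((1, 4)), np.zeros((1, 4)))) == 0.0
        assert kl_term(LatentCode(np.array([[1.0]]), np.array([[0.0]]))) == 0.5

    def test_kl_matches_monte_carlo_estimate(self):
        """Closed form vs sampling estimate of E_q[log q - log p]."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            mu = rng.normal(0, 1, (1, 4))
            lv = rng.uniform(-1.5, 1.0, (1, 4))
            sd = np.exp(lv / 2)
            n = 100_000
            z = mu + sd * rng.standard_normal((n, 4))
            log_q = -0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi) + lv).sum(axis=1)
            log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
            samples = log_q - log_p
            mc, se = samples.mean(), samples.std(ddof=1) / np.sqrt(n)
            assert abs(kl_term(LatentCode(mu, lv)) - mc) <= 3 * se

    def test_loss_composition(self, rng):
        x = rng.random((2, 8, 8))
        x_hat = rng.random((2, 8, 8))
        code = LatentCode(rng.normal(0, 1, (2, 6)), rng.normal(0, 0.3, (2, 6)))
        total, recon, kl = vae_loss(x, x_hat, code, kl_weight=0.7)
        assert total == pytest.approx(recon + 0.7 * kl, abs=1e-7)
        total0, recon0, _ = vae_loss(x, x_hat, code, kl_weight=0.0)
        assert total0 == recon0
        t_perfect, _, _ = vae_loss(x, x, LatentCode(np.zeros((2, 6)),
                                                    np.zeros((2, 6))), 1.0)
        assert t_perfect == 0.0

    def test_latent_code_must_be_finite_and_aligned(self):
        with pytest.raises(ValueError):
            LatentCode(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            LatentCode(np.array([np.inf]), np.array([0.0]))


class TestGradients:
    def _fd_model_grad(self, rank=2):
        """Full-model finite-difference check on a tiny float64 instance."""
        cfg = NetworkConfig(rank=rank, input_extent=8, latent_dim=4,
                            stage_channels=(3,), seed=1)
        model = VAE(cfg)
        # promote to float64 for finite differences
        for _, p, _, n in model.parameters():
            p[n] = p[n].astype(np.float64)
        x = np.random.default_rng(0).random((2,) + (8,) * rank)

        def loss():
            out = model.forward_train(
                x.astype(np.float32), x.astype(np.float32),
                np.random.default_rng(99), kl_weight=0.01)
            return out["loss"]

        base = loss()
        model.backward()
        grads = {k: g[n].copy() for k, p, g, n in model.parameters()}
        rng = np.random.default_rng(5)
        checked = 0
        for key, p, g, n in model.parameters():
            flat = p[n].reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                eps = 1e-4
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[key].reshape(-1)[idx]
                assert an == pytest.approx(fd, abs=2e-4), (key, idx)
                checked += 1
        assert checked > 10

    def test_backprop_matches_finite_differences(self):
        self._fd_model_grad(rank=2)

    def test_one_adam_step_decreases_the_loss(self, rng):
        cfg = NetworkConfig(rank=2, input_extent=16, latent_dim=8,
                            stage_channels=(4, 8), seed=2)
        model = VAE(cfg)
        x = rng.random((4, 16, 16)).astype(np.float32)
        opt = nn.Adam(model.parameters(), lr=1e-3)
        srng = np.random.default_rng(0)
        before = model.forward_train(x, x, np.random.default_rng(1), 1e-4)["loss"]
        model.backward()
        opt.step()
        after = model.forward_train(x, x, np.random.default_rng(1), 1e-4)["loss"]
        assert after < before


class TestCheckpoint:
    def test_round_trip_preserves_config_and_outputs(self, tmp_path, rng):
        model = VAE(small_cfg(3))
        x = rng.random((1, 16, 16, 16)).astype(np.float32)
        want = model.reconstruct(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, {"note": "test"})
        back, meta = load_checkpoint(path)
        assert meta == {"note": "test"}
        assert back.cfg == model.cfg
        assert np.array_equal(back.reconstruct(x), want)
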