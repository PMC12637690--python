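"""Tests for the NumPy VAE: shape contracts, closed-form loss terms,
finite-difference gradient checks, and desk-scale convergence."""

import numpy as np
import pytest

from scresample import vae
from scresample.containers import CellMatrix

LOG2PI = np.log(2 * np.pi)


def _flatten(params):
    return np.concatenate([v.ravel() for v in sorted(params)])


class TestInit:
    def test_deterministic_given_seed(self):
        a = vae.init_model(D=100, K=8, H=32, likelihood_mode="nb", seed=1)
        b = vae.init_model(D=100, K=8, H=32, likelihood_mode="nb", seed=1)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_encoder_output_width_is_two_k(self):
        m = vae.init_model(D=100, K=64, H=128, likelihood_mode="gaussian", seed=1)
        assert m.params["enc_W_out"].shape == (128, 2 * 64)

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError):
            vae.init_model(D=0, K=4, H=8, likelihood_mode="nb")

    def test_k_exceeding_d_warns(self):
        with pytest.warns(UserWarning):
            vae.init_model(D=4, K=8, H=16, likelihood_mode="gaussian")


class TestEncodeDecode:
    def test_mean_mode_deterministic(self):
        m = vae.init_model(D=20, K=4, H=16, likelihood_mode="gaussian", seed=0)
        X = np.random.default_rng(0).normal(size=(10, 20))
        np.testing.assert_array_equal(
            vae.encode(m, X, mode="mean").values, vae.encode(m, X, mode="mean").values)

    def test_sample_mode_seeded_determinism(self):
        m = vae.init_model(D=20, K=4, H=16, likelihood_mode="gaussian", seed=0)
        X = np.random.default_rng(0).normal(size=(10, 20))
        a = vae.encode(m, X, mode="sample", rng_seed=5).values
        b = vae.encode(m, X, mode="sample", rng_seed=5).values
        np.testing.assert_array_equal(a, b)
        c = vae.encode(m, X, mode="sample", rng_seed=6).values
        assert not np.array_equal(a, c)

    def test_zero_variance_sample_equals_mean(self):
        # drive logvar to a huge negative value: sigma -> 0
        m = vae.init_model(D=6, K=3, H=None, likelihood_mode="gaussian", seed=0)
        m.params["enc_W_out"][:, 3:] = 0.0
        m.params["enc_b_out"][3:] = -80.0
        X = np.random.default_rng(1).normal(size=(5, 6))
        np.testing.assert_allclose(
            vae.encode(m, X, mode="sample", rng_seed=0).values,
            vae.encode(m, X, mode="mean").values, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        m = vae.init_model(D=20, K=4, H=16, likelihood_mode="gaussian", seed=0)
        with pytest.raises(ValueError):
            vae.encode(m, np.zeros((3, 7)))
        with pytest.raises(ValueError):
            vae.decode(m, np.zeros((3, 7)))

    def test_identity_toy_decoder_returns_z(self):
        m = vae.init_model(D=5, K=5, H=None, likelihood_mode="gaussian", seed=0)
        m.params["dec_W_out"] = np.eye(5)
        m.params["dec_b_out"][:] = 0.0
        Z = np.random.default_rng(2).normal(size=(8, 5))
        np.testing.assert_allclose(vae.decode(m, Z), Z)

    def test_count_mode_rows_scale_to_library(self):
        m = vae.init_model(D=30, K=4, H=16, likelihood_mode="nb", seed=0)
        Z = np.random.default_rng(0).normal(size=(6, 4))
        out = vae.decode(m, Z, target_library=1e4)
        np.testing.assert_allclose(np.expm1(out).sum(axis=1), 1e4, rtol=1e-9)

    def test_decode_deterministic(self):
        m = vae.init_model(D=30, K=4, H=16, likelihood_mode="nb", seed=0)
        Z = np.random.default_rng(0).normal(size=(6, 4))
        np.testing.assert_array_equal(vae.decode(m, Z), vae.decode(m, Z))


class TestLoss:
    def test_kl_zero_when_posterior_is_prior(self):
        m = vae.init_model(D=4, K=2, H=None, likelihood_mode="gaussian", seed=0)
        m.params["enc_W_out"][:] = 0.0
        m.params["enc_b_out"][:] = 0.0  # mu = 0, logvar = 0
        X = np.random.default_rng(0).normal(size=(7, 4))
        _, _, kl, _ = vae.loss_and_grads(m, X, eps=np.zeros((7, 2)))
        assert kl == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_nll_at_perfect_reconstruction(self):
        # decoder reproduces X exactly -> NLL = D/2 * log(2*pi) per cell
        D = 6
        m = vae.init_model(D=D, K=D, H=None, likelihood_mode="gaussian", seed=0)
        m.params["enc_W_out"][:] = 0.0
        m.params["enc_W_out"][:, :D] = np.eye(D)  # mu = X
        m.params["enc_b_out"][:] = 0.0
        m.params["dec_W_out"] = np.eye(D)
        m.params["dec_b_out"][:] = 0.0
        X = np.random.default_rng(0).normal(size=(5, D))
        _, recon, _, _ = vae.loss_and_grads(m, X, eps=np.zeros((5, D)))
        assert recon == pytest.approx(D / 2 * LOG2PI, rel=1e-12)

    def test_kl_closed_form_for_unit_logvar(self):
        # logvar = 0, mean mu -> KL = sum(mu^2) / 2
        D, K = 3, 2
        m = vae.init_model(D=D, K=K, H=None, likelihood_mode="gaussian", seed=0)
        m.params["enc_W_out"][:] = 0.0
        m.params["enc_b_out"][:] = 0.0
        m.params["enc_b_out"][:K] = [1.0, 2.0]
        X = np.zeros((4, D))
        _, _, kl, _ = vae.loss_and_grads(m, X, eps=np.zeros((4, K)))
        assert kl == pytest.approx((1.0 + 4.0) / 2, rel=1e-12)

    def test_kl_nonnegative_random_batches(self):
        m = vae.init_model(D=12, K=5, H=8, likelihood_mode="gaussian", seed=3)
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = rng.normal(size=(9, 12))
            _, _, kl, _ = vae.loss_and_grads(m, X, eps=rng.standard_normal((9, 5)))
            assert kl >= 0

    def test_nan_guard(self):
        m = vae.init_model(D=4, K=2, H=None, likelihood_mode="gaussian", seed=0)
        m.params["enc_b_out"][2:] = 2000.0  # exp(logvar) overflows
        with pytest.raises(FloatingPointError):
            with np.errstate(over="ignore"):
                vae.elbo_loss(m, np.zeros((3, 4)), rng_seed=0)


@pytest.mark.parametrize("likelihood,H", [("gaussian", 7), ("gaussian", None),
                                          ("nb", 7), ("nb", None)])
def test_gradients_match_finite_differences(likelihood, H):
    """Closed-form backprop agrees with central finite differences."""
    rng = np.random.default_rng(0)
    D, K, B = 5, 3, 4
    m = vae.init_model(D=D, K=K, H=H, likelihood_mode=likelihood, seed=1)
    for k in m.params:  # move off the zero-bias init to exercise all paths
        m.params[k] = m.params[k] + 0.1 * rng.normal(size=m.params[k].shape)
    X = (rng.poisson(5.0, size=(B, D)).astype(float) if likelihood == "nb"
         else rng.normal(size=(B, D)))
    eps = rng.standard_normal((B, K))
    _, _, _, grads = vae.loss_and_grads(m, X, eps)
    h = 1e-6
    for name, g in grads.items():
        flat = m.params[name].ravel()
        for j in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[j]
            flat[j] = orig + h
            lp, *_ = vae.loss_and_grads(m, X, eps)
            flat[j] = orig - h
            lm, *_ = vae.loss_and_grads(m, X, eps)
            flat[j] = orig
            fd = (lp - lm) / (2 * h)
            assert g.ravel()[j] == pytest.approx(fd, rel=2e-4, abs=1e-7), name


def test_linear_toy_roundtrip_reaches_high_correlation():
    """On low-rank Gaussian data X = Z W + noise the trained VAE reconstructs
    with mean per-cell r >= 0.9."""
    from scresample.evaluation import reconstruction_r
    from scresample.training import TrainConfig, split_train_val, train

    rng = np.random.default_rng(0)
    n, d, k_true = 400, 30, 3
    Z_true = rng.normal(size=(n, k_true))
    W = rng.normal(size=(k_true, d))
    X = Z_true @ W + 0.1 * rng.normal(size=(n, d))
    cm = CellMatrix(X=X)
    X_tr, X_val = split_train_val(cm, seed=0)
    m = vae.init_model(D=d, K=4, H=32, likelihood_mode="gaussian", seed=0)
    cfg = TrainConfig(mode="standard", epochs=120, batch_size=64, learning_rate=3e-3)
    best, hist = train(m, X_tr, X_val, cfg)
    recon = vae.decode(best, vae.encode(best, X_val, mode="mean"))
    assert reconstruction_r(X_val.X, recon) >= 0.9
    # loss decreases in 10-epoch moving average
    avg = np.convolve(hist.train_loss, np.ones(10) / 10, mode="valid")
    assert avg[-1] < avg[0]


def test_checkpoint_roundtrip(tmp_path):
    m = vae.init_model(D=12, K=3, H=8, likelihood_mode="nb", seed=4)
    path = tmp_path / "model.ckpt"
    vae.save_checkpoint(m, path)
    loaded = vae.load_checkpoint(path)
    assert loaded.config() == m.config()
    for k in m.params:
        np.testing.assert_array_equal(loaded.params[k], m.params[k])
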