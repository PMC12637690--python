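"""A compact variational autoencoder for expression matrices, in NumPy.

The model is deliberately small: dense encoder ``D -> H -> 2K`` (posterior
mean and log-variance per latent dimension), mirrored dense decoder
``K -> H -> D``, tanh hidden activation, and one of two observation models:

``gaussian``
    Unit-variance Gaussian likelihood on log-normalized expression
    (scGen-style).  The decoder output is the reconstruction directly.
``nb``
    Negative-binomial likelihood on raw counts (scVI-style).  The decoder
    emits per-gene proportions through a softmax; the NB mean is the
    observed per-cell library size times those proportions, with a free
    gene-wise inverse-dispersion parameter.

Training maximizes the evidence lower bound (ELBO): the reparameterized
reconstruction log-likelihood minus the KL divergence of the diagonal
Gaussian posterior from a standard-normal prior.  Gradients are derived in
closed form and checked against finite differences in the test suite;
optimization uses Adam.  ``H=None`` (or 0) gives purely linear encoder and
decoder, which is handy for closed-form toy checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln

from .containers import CellMatrix, LatentMatrix

LOG2PI = float(np.log(2.0 * np.pi))
_MU_EPS = 1e-10  # guards y/mu in the NB likelihood


@dataclass
class VAEState:
    """Parameters plus architecture description of the VAE."""

    params: dict
    D: int
    K: int
    H: int | None
    likelihood_mode: str  # "gaussian" | "nb"
    seed: int

    def copy(self) -> "VAEState":
        return VAEState(
            params={k: v.copy() for k, v in self.params.items()},
            D=self.D, K=self.K, H=self.H,
            likelihood_mode=self.likelihood_mode, seed=self.seed,
        )

    def config(self) -> dict:
        return {"D": self.D, "K": self.K, "H": self.H,
                "likelihood_mode": self.likelihood_mode, "seed": self.seed}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(
    D: int,
    K: int = 64,
    H: int | None = 128,
    likelihood_mode: str = "nb",
    seed: int = 0,
) -> VAEState:
    """Deterministically initialize a VAE; identical arguments give
    byte-identical parameters."""
    if D < 1 or K < 1:
        raise ValueError(f"D and K must be positive, got D={D}, K={K}")
    if H is not None and H == 0:
        H = None
    if H is not None and H < 1:
        raise ValueError(f"H must be positive or None, got {H}")
    if likelihood_mode not in ("gaussian", "nb"):
        raise ValueError(f"unknown likelihood_mode {likelihood_mode!r}")
    if K > D:
        warnings.warn(f"latent dimension K={K} exceeds feature dimension D={D}")
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    if H is None:
        p["enc_W_out"] = _glorot(rng, D, 2 * K)
        p["enc_b_out"] = np.zeros(2 * K)
        p["dec_W_out"] = _glorot(rng, K, D)
        p["dec_b_out"] = np.zeros(D)
    else:
        p["enc_W_h"] = _glorot(rng, D, H)
        p["enc_b_h"] = np.zeros(H)
        p["enc_W_out"] = _glorot(rng, H, 2 * K)
        p["enc_b_out"] = np.zeros(2 * K)
        p["dec_W_h"] = _glorot(rng, K, H)
        p["dec_b_h"] = np.zeros(H)
        p["dec_W_out"] = _glorot(rng, H, D)
        p["dec_b_out"] = np.zeros(D)
    if likelihood_mode == "nb":
        p["log_theta"] = np.zeros(D)  # gene-wise inverse dispersion, exp-link
    return VAEState(params=p, D=D, K=K, H=H, likelihood_mode=likelihood_mode, seed=seed)


def _as_array(X) -> np.ndarray:
    return X.X if isinstance(X, CellMatrix) else np.asarray(X, dtype=float)


def _encoder_input(model: VAEState, X: np.ndarray) -> np.ndarray:
    # count mode encodes log1p counts for numerical stability
    return np.log1p(X) if model.likelihood_mode == "nb" else X


def _encode_moments(model: VAEState, Xe: np.ndarray):
    p = model.params
    if model.H is None:
        h, h_pre = Xe, None
    else:
        h_pre = Xe @ p["enc_W_h"] + p["enc_b_h"]
        h = np.tanh(h_pre)
    out = h @ p["enc_W_out"] + p["enc_b_out"]
    mu, logvar = out[:, : model.K], out[:, model.K:]
    return mu, logvar, h, h_pre


def encode(model: VAEState, X, mode: str = "sample", rng_seed: int = 0) -> LatentMatrix:
    """Project cells to the latent space.

    ``mode="mean"`` returns the posterior mean; ``mode="sample"`` draws
    ``mu + exp(logvar/2) * eps`` with standard-normal ``eps`` under
    ``rng_seed`` (deterministic given the seed).
    """
    Xa = _as_array(X)
    if Xa.shape[1] != model.D:
        raise ValueError(f"X has {Xa.shape[1]} genes, model expects {model.D}")
    mu, logvar, _, _ = _encode_moments(model, _encoder_input(model, Xa))
    if mode == "mean":
        z = mu
    elif mode == "sample":
        eps = np.random.default_rng(rng_seed).standard_normal(mu.shape)
        z = mu + np.exp(0.5 * logvar) * eps
    else:
        raise ValueError(f"unknown encode mode {mode!r}")
    ids = X.cell_ids if isinstance(X, CellMatrix) else None
    return LatentMatrix(values=z, cell_index=ids)


def _decode_output(model: VAEState, Z: np.ndarray):
    p = model.params
    if model.H is None:
        g, g_pre = Z, None
    else:
        g_pre = Z @ p["dec_W_h"] + p["dec_b_h"]
        g = np.tanh(g_pre)
    o = g @ p["dec_W_out"] + p["dec_b_out"]
    return o, g, g_pre


def _softmax(o: np.ndarray) -> np.ndarray:
    e = np.exp(o - o.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def decode(model: VAEState, Z, target_library: float = 1e4) -> np.ndarray:
    """Decode latent coordinates to expression space.

    Gaussian mode returns the decoder output on the log-normalized scale.
    Count mode returns ``log1p`` of the expected counts scaled so every
    cell's (pre-log) expectation totals ``target_library`` — the scale used
    throughout reconstruction evaluation.
    """
    Zv = Z.values if isinstance(Z, LatentMatrix) else np.asarray(Z, dtype=float)
    if Zv.shape[1] != model.K:
        raise ValueError(f"Z has {Zv.shape[1]} dimensions, model expects {model.K}")
    o, _, _ = _decode_output(model, Zv)
    if model.likelihood_mode == "gaussian":
        return o
    rho = _softmax(o)  # rows sum to 1, so scaled rows sum to target_library
    return np.log1p(target_library * rho)


def _nb_nll(y: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Elementwise negative log-likelihood of NB with mean mu, inverse
    dispersion theta (var = mu + mu^2/theta)."""
    return -(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def loss_and_grads(model: VAEState, X, eps: np.ndarray):
    """Per-cell mean ELBO loss and closed-form parameter gradients.

    ``eps`` is the (batch x K) standard-normal draw for the
    reparameterization trick; pass zeros for a deterministic posterior-mean
    evaluation.  Returns ``(loss, recon_nll, kl, grads)`` where the first
    three are per-cell means and ``grads`` matches ``model.params``.
    """
    p = model.params
    Xa = _as_array(X)
    B = Xa.shape[0]
    Xe = _encoder_input(model, Xa)
    mu, logvar, h, h_pre = _encode_moments(model, Xe)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    o, g, g_pre = _decode_output(model, z)

    grads: dict[str, np.ndarray] = {}
    if model.likelihood_mode == "gaussian":
        resid = o - Xa
        recon = 0.5 * (resid**2).sum(axis=1) + 0.5 * model.D * LOG2PI
        d_o = resid / B
    else:
        lib = Xa.sum(axis=1, keepdims=True)
        rho = _softmax(o)
        mu_nb = lib * rho + _MU_EPS
        theta = np.exp(p["log_theta"])
        recon = _nb_nll(Xa, mu_nb, theta).sum(axis=1)
        d_mu_nb = (theta + Xa) / (theta + mu_nb) - Xa / mu_nb
        d_rho = d_mu_nb * lib / B
        d_o = rho * (d_rho - (rho * d_rho).sum(axis=1, keepdims=True))
        d_theta = -(
            digamma(Xa + theta) - digamma(theta)
            + np.log(theta / (theta + mu_nb))
            + 1.0 - (theta + Xa) / (theta + mu_nb)
        )
        grads["log_theta"] = (theta * d_theta).sum(axis=0) / B

    kl = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1)
    loss = float(recon.mean() + kl.mean())

    # decoder backprop
    grads["dec_W_out"] = g.T @ d_o
    grads["dec_b_out"] = d_o.sum(axis=0)
    if model.H is None:
        d_z = d_o @ p["dec_W_out"].T
    else:
        d_g = d_o @ p["dec_W_out"].T
        d_gpre = d_g * (1.0 - g**2)
        grads["dec_W_h"] = z.T @ d_gpre
        grads["dec_b_h"] = d_gpre.sum(axis=0)
        d_z = d_gpre @ p["dec_W_h"].T

    # through the reparameterization, plus the KL term
    d_mu = d_z + mu / B
    d_logvar = d_z * (0.5 * sigma * eps) + 0.5 * (np.exp(logvar) - 1.0) / B
    d_out = np.concatenate([d_mu, d_logvar], axis=1)

    grads["enc_W_out"] = h.T @ d_out
    grads["enc_b_out"] = d_out.sum(axis=0)
    if model.H is not None:
        d_h = d_out @ p["enc_W_out"].T
        d_hpre = d_h * (1.0 - h**2)
        grads["enc_W_h"] = Xe.T @ d_hpre
        grads["enc_b_h"] = d_hpre.sum(axis=0)

    return loss, float(recon.mean()), float(kl.mean()), grads


def elbo_loss(model: VAEState, X, rng_seed: int = 0, sample: bool = True) -> float:
    """Negative ELBO averaged over cells: reconstruction NLL + KL(q || N(0,I)).

    ``sample=False`` evaluates at the posterior mean (eps = 0), which is the
    deterministic form used for validation-based model selection.
    """
    Xa = _as_array(X)
    if Xa.shape[1] != model.D:
        raise ValueError(f"X has {Xa.shape[1]} genes, model expects {model.D}")
    if sample:
        eps = np.random.default_rng(rng_seed).standard_normal((Xa.shape[0], model.K))
    else:
        eps = np.zeros((Xa.shape[0], model.K))
    loss, _, _, _ = loss_and_grads(model, Xa, eps)
    if not np.isfinite(loss):
        raise FloatingPointError("ELBO loss is not finite")
    return loss


class Adam:
    """Plain Adam over a parameter dict, with optional L2 weight decay."""

    def __init__(self, params: dict, lr: float = 5e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.weight_decay and "_W_" in k:  # decay weights, not biases/dispersion
                g = g + self.weight_decay * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(model: VAEState, path) -> None:
    """Single-file archive: parameters plus a JSON architecture header."""
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.frombuffer(
            json.dumps(model.config()).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path) -> VAEState:
    with np.load(path) as f:
        cfg = json.loads(bytes(f["__config__"]).decode())
        params = {k: f[k].copy() for k in f.files if k != "__config__"}
    return VAEState(params=params, **cfg)
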