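"""Paired adaptive-resampling (AR) and standard VAE training loops.

The two arms share everything — initialization, optimizer, minibatching,
fixed epoch count, no early stopping, best-validation-loss selection —
except one block: in AR mode, at the start of every epoch the *original*
training set is projected to the latent space, resampling weights are
computed from the per-dimension latent densities, and the epoch's training
multiset is drawn with replacement from those weights.  In standard mode
each sample is seen exactly once per epoch.

Randomness is split into four independently seeded streams (model
initialization, latent sampling, resampling draws, minibatch shuffling) so
that an AR run and a standard run can share initialization and be compared
as a matched pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import vae
from .containers import CellMatrix
from .resampling import (DEFAULT_ALPHA, DEFAULT_N_BINS,
                         compute_resampling_weights, resample_indices)

_SEED_MOD = 2**31 - 1


@dataclass
class TrainConfig:
    """Everything a training run depends on.

    ``mode`` is ``"AR"`` or ``"standard"``; standard mode ignores the
    resampling fields (alpha, n_bins, latent_mode, latent/resample seeds).
    """

    mode: str = "standard"
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 5e-5
    weight_decay: float = 0.0
    alpha: float = DEFAULT_ALPHA
    n_bins: int = DEFAULT_N_BINS
    latent_mode: str = "mean"  # "mean" | "sample": encoding used for weighting
    seed_init: int = 0
    seed_latent: int = 1
    seed_resample: int = 2
    seed_shuffle: int = 3
    validation_fraction: float = 0.2

    def __post_init__(self):
        if self.mode not in ("AR", "standard"):
            raise ValueError(f"mode must be 'AR' or 'standard', got {self.mode!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class TrainHistory:
    mode: str
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    weights: list = field(default_factory=list)        # AR: per-epoch w* vectors
    epoch_indices: list = field(default_factory=list)  # per-epoch training multiset
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_loss)


def _derive(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(_SEED_MOD))


def train(
    model: vae.VAEState,
    X_train: CellMatrix,
    X_val: CellMatrix,
    config: TrainConfig,
    resample_hook=resample_indices,
) -> tuple[vae.VAEState, TrainHistory]:
    """Train for a fixed number of epochs; return the parameters with the
    best (posterior-mean) validation loss and the full history.

    ``resample_hook(w_star, seed) -> indices`` is the epoch-start redraw in
    AR mode; injectable so tests can verify that with an identity redraw the
    AR loop reduces to the standard one.
    """
    if X_val.n_cells == 0:
        raise ValueError("validation set is empty")
    if X_train.n_genes != model.D or X_val.n_genes != model.D:
        raise ValueError("train/validation gene dimension does not match the model")
    if set(X_train.cell_ids) & set(X_val.cell_ids):
        raise ValueError("train and validation sets overlap")

    model = model.copy()
    opt = vae.Adam(model.params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    hist = TrainHistory(mode=config.mode)
    n = X_train.n_cells
    best_val, best_params = np.inf, None

    for epoch in range(config.epochs):
        if config.mode == "AR":
            # weights come from the ORIGINAL training set, every epoch
            Z = vae.encode(model, X_train, mode=config.latent_mode,
                           rng_seed=_derive(config.seed_latent, 2 * epoch))
            rw = compute_resampling_weights(Z, alpha=config.alpha, n_bins=config.n_bins)
            hist.weights.append(rw.final)
            epoch_set = resample_hook(rw.final, _derive(config.seed_resample, epoch))
        else:
            epoch_set = np.arange(n)
        hist.epoch_indices.append(np.asarray(epoch_set))

        order = np.random.default_rng(
            _derive(config.seed_shuffle, epoch)).permutation(len(epoch_set))
        epoch_set = np.asarray(epoch_set)[order]

        eps_rng = np.random.default_rng(_derive(config.seed_latent, 2 * epoch + 1))
        losses = []
        for start in range(0, len(epoch_set), config.batch_size):
            batch = X_train.X[epoch_set[start:start + config.batch_size]]
            eps = eps_rng.standard_normal((batch.shape[0], model.K))
            loss, _, _, grads = vae.loss_and_grads(model, batch, eps)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.step(model.params, grads)
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))

        val = vae.elbo_loss(model, X_val, sample=False)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        hist.val_loss.append(val)
        if val < best_val:
            best_val, best_params = val, {k: v.copy() for k, v in model.params.items()}
            hist.best_epoch = epoch

    best = model.copy()
    best.params = best_params
    return best, hist


def split_train_val(X: CellMatrix, validation_fraction: float = 0.2,
                    seed: int = 0) -> tuple[CellMatrix, CellMatrix]:
    """Seeded random train/validation split; validation is never resampled."""
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.n_cells)
    n_val = max(1, int(round(validation_fraction * X.n_cells)))
    return X.subset(perm[n_val:]), X.subset(perm[:n_val])


def paired_run(
    X_train: CellMatrix,
    X_val: CellMatrix,
    config_base: TrainConfig,
    n_seeds: int = 5,
    model_factory=None,
) -> tuple[list, list]:
    """Train matched AR/standard pairs across replicate seeds.

    Each replicate's two arms start from byte-identical initialization and
    see the same data split; only the epoch-start resampling differs.
    Returns ``(ar_results, std_results)``, each a list of
    ``(VAEState, TrainHistory)``.
    """
    if n_seeds < 2:
        raise ValueError("need n_seeds >= 2 for downstream paired comparisons")
    if model_factory is None:
        def model_factory(seed):
            return vae.init_model(D=X_train.n_genes, K=8, H=64,
                                  likelihood_mode="nb", seed=seed)
    ar_out, std_out = [], []
    for rep in range(n_seeds):
        seeds = {name: _derive(getattr(config_base, name), 1000 + rep)
                 for name in ("seed_init", "seed_latent", "seed_resample", "seed_shuffle")}
        model0 = model_factory(seeds["seed_init"])
        cfg_ar = replace(config_base, mode="AR", **seeds)
        cfg_std = replace(config_base, mode="standard", **seeds)
        ar_out.append(train(model0, X_train, X_val, cfg_ar))
        std_out.append(train(model0, X_train, X_val, cfg_std))
    return ar_out, std_out


def weight_trajectory(history: TrainHistory, labels) -> pd.DataFrame:
    """Epoch x group table of mean final resampling weight.

    ``labels`` is the per-cell group vector of the original training set.
    Only meaningful for AR-mode histories.
    """
    if history.mode != "AR" or not history.weights:
        raise ValueError("weight_trajectory requires an AR-mode history with stored weights")
    labels = np.asarray(labels, dtype=object).astype(str)
    groups = sorted(set(labels))
    rows = []
    for epoch, w in enumerate(history.weights):
        if len(w) != len(labels):
            raise ValueError("label length does not match stored weight vectors")
        rows.append({"epoch": epoch, **{g: float(w[labels == g].mean()) for g in groups}})
    return pd.DataFrame(rows).set_index("epoch")
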