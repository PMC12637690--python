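"""Perturbation-response prediction by latent vector arithmetic.

A VAE is trained on control and perturbed cells from several cell groups,
with the perturbed cells of one group held out.  The mean latent
displacement from control to perturbed training cells — the delta vector —
is added to each held-out control cell's embedding, and the decoder maps
the shifted coordinates back to expression space as the predicted perturbed
profile:  ``z_p = z_c + delta``.

Includes the hold-one-group-out split builder with a graded
control-inclusion fraction f: 0 (fully out-of-distribution) through 1 (all
of the held-out group's control cells seen in training, perturbed cells
never).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import vae
from .containers import CellMatrix, LatentMatrix

CONTROL, PERTURBED = "control", "perturbed"


@dataclass
class PerturbationDelta:
    """Mean control-to-perturbed latent displacement (length K)."""

    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float).ravel()
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("delta contains non-finite entries")


@dataclass
class HoldoutSplit:
    train: CellMatrix
    test_control: CellMatrix
    test_perturbed: CellMatrix
    held_out_group: str
    control_inclusion_fraction: float


def estimate_delta(Z_control, Z_perturbed) -> PerturbationDelta:
    """delta = mean(perturbed embeddings) - mean(control embeddings).

    Both arguments must hold training cells only; leaking held-out
    perturbed cells here would invalidate the out-of-distribution test.
    """
    zc = Z_control.values if isinstance(Z_control, LatentMatrix) else np.asarray(Z_control, float)
    zp = Z_perturbed.values if isinstance(Z_perturbed, LatentMatrix) else np.asarray(Z_perturbed, float)
    if zc.size == 0 or zp.size == 0:
        raise ValueError("cannot estimate delta from empty latent sets")
    if zc.shape[1] != zp.shape[1]:
        raise ValueError("control and perturbed latent dimensionality differ")
    return PerturbationDelta(delta=zp.mean(axis=0) - zc.mean(axis=0))


def predict_perturbed(model: vae.VAEState, X_control: CellMatrix,
                      delta: PerturbationDelta) -> np.ndarray:
    """Encode (posterior mean), shift by delta, decode.

    Returns one predicted perturbed profile per input control cell, on the
    decoder's output scale (log-normalized for the Gaussian likelihood).
    """
    if delta.delta.shape[0] != model.K:
        raise ValueError(f"delta has {delta.delta.shape[0]} dims, model K={model.K}")
    Z = vae.encode(model, X_control, mode="mean")
    return vae.decode(model, Z.values + delta.delta[None, :])


def train_delta(model: vae.VAEState, X_train: CellMatrix) -> PerturbationDelta:
    """Delta from a labeled training set: all control vs all perturbed
    training cells pooled across groups, encoded at the posterior mean."""
    if X_train.condition is None:
        raise ValueError("training set lacks condition labels")
    Z = vae.encode(model, X_train, mode="mean")
    ctrl = X_train.condition == CONTROL
    pert = X_train.condition == PERTURBED
    return estimate_delta(Z.values[ctrl], Z.values[pert])


def build_holdout(X: CellMatrix, held_out_group: str, f: float,
                  seed: int = 0) -> HoldoutSplit:
    """Hold-one-group-out split with control-inclusion fraction ``f``.

    All cells of the other groups (both conditions) train the model.  Of
    the held-out group, perturbed cells never enter training; exactly
    ``round(f * n_group_controls)`` of its control cells (seeded-random
    choice) do.  The test inputs are ALL of the group's control cells —
    identical across f — and the test ground truth is its perturbed cells.
    """
    if X.group is None or X.condition is None:
        raise ValueError("dataset lacks group and/or condition labels")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"control inclusion fraction must be in [0,1], got {f}")
    held_out_group = str(held_out_group)
    in_group = X.group == held_out_group
    if not in_group.any():
        raise ValueError(f"group {held_out_group!r} not present")
    ctrl_idx = np.flatnonzero(in_group & (X.condition == CONTROL))
    pert_idx = np.flatnonzero(in_group & (X.condition == PERTURBED))
    if len(pert_idx) == 0:
        raise ValueError(f"group {held_out_group!r} has no perturbed cells")
    other_idx = np.flatnonzero(~in_group)

    n_include = int(round(f * len(ctrl_idx)))
    rng = np.random.default_rng(seed)
    included = rng.choice(ctrl_idx, size=n_include, replace=False) if n_include else np.array([], int)
    train_idx = np.sort(np.concatenate([other_idx, included]).astype(int))

    split = HoldoutSplit(
        train=X.subset(train_idx),
        test_control=X.subset(ctrl_idx),
        test_perturbed=X.subset(pert_idx),
        held_out_group=held_out_group,
        control_inclusion_fraction=f,
    )
    assert_no_leakage(split)
    return split


def assert_no_leakage(split: HoldoutSplit) -> None:
    """No held-out perturbed cell may appear in training; inclusion count
    must match the requested fraction exactly."""
    train_ids = set(split.train.cell_ids)
    if train_ids & set(split.test_perturbed.cell_ids):
        raise AssertionError("held-out perturbed cells leaked into training")
    n_ctrl = split.test_control.n_cells
    expected = int(round(split.control_inclusion_fraction * n_ctrl))
    got = len(train_ids & set(split.test_control.cell_ids))
    if got != expected:
        raise AssertionError(
            f"{got} held-out-group controls in training, expected {expected}")
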