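"""Adaptive-resampling weight computation.

The adaptive resampling (AR) scheme turns the learned latent coordinates of
the training set into a per-cell resampling probability.  For each latent
dimension independently:

1. estimate the density of the N projected values with a uniform-width
   histogram (``numpy.histogram`` semantics, rightmost edge inclusive);
2. smooth the per-sample density with a constant ``alpha`` and normalize
   across samples:  ``p_s*(z_kn) = (p(z_kn) + alpha) / sum_i (p(z_ki) + alpha)``;
3. invert, so cells in sparse latent regions score high:
   ``u_kn = 1 / p_s*(z_kn)``, row-normalized to ``u*``.

The final (unnormalized) weight of a cell is the maximum of its ``u*``
scores over dimensions — a cell counts as underrepresented if it is rare
along *any* latent axis — and the weights are normalized into a probability
vector ``w*`` used to redraw the training multiset with replacement.

All functions are pure NumPy and accept either a plain array or a
:class:`~scresample.containers.LatentMatrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import LatentMatrix

DEFAULT_ALPHA = 1e-4
DEFAULT_N_BINS = 50


def _latent_values(Z) -> np.ndarray:
    if isinstance(Z, LatentMatrix):
        return Z.values
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.ndim != 2 or Z.shape[0] < 1 or Z.shape[1] < 1:
        raise ValueError(f"latent matrix must be 2-D with N,K >= 1, got shape {Z.shape}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("latent values contain non-finite entries")
    return Z


@dataclass
class DensityEstimate:
    """Per-dimension histogram density of a latent matrix.

    ``bin_edges[k]`` has B+1 ascending edges, ``bin_mass[k]`` has B
    non-negative masses summing to 1 (mass = bin count / N).
    """

    bin_edges: list[np.ndarray]
    bin_mass: list[np.ndarray]

    @property
    def n_dims(self) -> int:
        return len(self.bin_edges)

    def __post_init__(self):
        for k, (edges, mass) in enumerate(zip(self.bin_edges, self.bin_mass)):
            if len(edges) != len(mass) + 1:
                raise ValueError(f"dimension {k}: {len(edges)} edges for {len(mass)} bins")
            if np.any(np.diff(edges) <= 0):
                raise ValueError(f"dimension {k}: bin edges not strictly ascending")
            if abs(mass.sum() - 1.0) > 1e-12:
                raise ValueError(f"dimension {k}: bin mass sums to {mass.sum()}, not 1")


def estimate_latent_densities(Z, n_bins: int = DEFAULT_N_BINS) -> DensityEstimate:
    """Histogram density of each latent dimension, normalized to mass 1.

    Uniform-width bins span ``[min(z_k), max(z_k)]`` per dimension with the
    rightmost edge inclusive.  A constant dimension collapses to a single
    bin of nominal width holding all samples.
    """
    Z = _latent_values(Z)
    if not isinstance(n_bins, (int, np.integer)) or n_bins < 1:
        raise ValueError(f"n_bins must be a positive integer, got {n_bins}")
    n = Z.shape[0]
    edges_all, mass_all = [], []
    for k in range(Z.shape[1]):
        col = Z[:, k]
        lo, hi = col.min(), col.max()
        if lo == hi:
            edges = np.array([lo - 0.5, lo + 0.5])
            counts = np.array([n])
        else:
            counts, edges = np.histogram(col, bins=n_bins, range=(lo, hi))
        edges_all.append(edges)
        mass_all.append(counts / n)
    return DensityEstimate(bin_edges=edges_all, bin_mass=mass_all)


def _sample_bin_mass(density: DensityEstimate, Z: np.ndarray) -> np.ndarray:
    """K x N matrix of the bin mass at each sample's position."""
    n, k_dims = Z.shape
    if density.n_dims != k_dims:
        raise ValueError(f"density has {density.n_dims} dimensions, latent has {k_dims}")
    out = np.empty((k_dims, n))
    for k in range(k_dims):
        edges, mass = density.bin_edges[k], density.bin_mass[k]
        col = Z[:, k]
        if np.any(col < edges[0]) or np.any(col > edges[-1]):
            raise ValueError(f"dimension {k}: samples fall outside the density's bin range")
        # numpy.histogram convention: half-open bins, last bin closed
        idx = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, len(mass) - 1)
        out[k] = mass[idx]
    return out


def per_sample_probability(density: DensityEstimate, Z, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Smoothed, sample-normalized probability ``p_s*`` (K x N).

    Adds ``alpha`` to each sample's raw bin mass and normalizes across the N
    samples so each dimension's row sums to 1.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    Z = _latent_values(Z)
    smoothed = _sample_bin_mass(density, Z) + alpha
    return smoothed / smoothed.sum(axis=1, keepdims=True)


def invert_per_sample(p_star: np.ndarray) -> np.ndarray:
    """Inverted, row-normalized scores ``u*`` (K x N): rare cells score high."""
    p_star = np.atleast_2d(np.asarray(p_star, dtype=float))
    if np.any(p_star <= 0):
        raise ValueError("per-sample probabilities must be strictly positive before inversion")
    u = 1.0 / p_star
    return u / u.sum(axis=1, keepdims=True)


def combine_and_normalize(u_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max over dimensions, then normalize: returns ``(w, w*)``."""
    u_star = np.atleast_2d(np.asarray(u_star, dtype=float))
    w = u_star.max(axis=0)
    return w, w / w.sum()


@dataclass
class ResamplingWeights:
    """Full intermediate ladder of one AR weight computation."""

    smoothed_prob: np.ndarray  # K x N  (p_s*)
    inverted: np.ndarray       # K x N  (u*)
    combined_raw: np.ndarray   # N      (w)
    final: np.ndarray          # N      (w*)
    alpha: float
    n_bins: int


def compute_resampling_weights(
    Z, alpha: float = DEFAULT_ALPHA, n_bins: int = DEFAULT_N_BINS
) -> ResamplingWeights:
    """Run the full ladder on a latent matrix and return every intermediate.

    This is also the frozen-mode entry point: ``Z`` may come from any
    pretrained encoder, not only the VAE trained in this package.
    """
    Zv = _latent_values(Z)
    density = estimate_latent_densities(Zv, n_bins=n_bins)
    p_star = per_sample_probability(density, Zv, alpha=alpha)
    u_star = invert_per_sample(p_star)
    w, w_star = combine_and_normalize(u_star)
    return ResamplingWeights(
        smoothed_prob=p_star,
        inverted=u_star,
        combined_raw=w,
        final=w_star,
        alpha=alpha,
        n_bins=n_bins,
    )


def resample_indices(w_star: np.ndarray, rng_seed: int) -> np.ndarray:
    """Draw N indices with replacement from the categorical ``w*``.

    Deterministic given ``rng_seed``; the returned multiset has the same
    size as the weight vector.
    """
    w_star = np.asarray(w_star, dtype=float)
    if abs(w_star.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w_star.sum()}, expected 1 within 1e-9")
    rng = np.random.default_rng(rng_seed)
    n = w_star.shape[0]
    return rng.choice(n, size=n, replace=True, p=w_star / w_star.sum())


def export_weights(
    weights: ResamplingWeights,
    path,
    cell_ids=None,
    epoch: int | None = None,
    seed: int | None = None,
) -> None:
    """Write weights as TSV (cell_id, final_weight, u* per dimension) plus a
    JSON sidecar recording alpha, n_bins, epoch and seed."""
    import pandas as pd

    path = Path(path)
    n = weights.final.shape[0]
    ids = [f"cell{i}" for i in range(n)] if cell_ids is None else list(map(str, cell_ids))
    df = pd.DataFrame({"cell_id": ids, "final_weight": weights.final})
    for k in range(weights.inverted.shape[0]):
        df[f"u_star_dim{k}"] = weights.inverted[k]
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "alpha": weights.alpha,
        "n_bins": weights.n_bins,
        "epoch": epoch,
        "seed": seed,
        "n_cells": n,
        "n_latent_dims": int(weights.inverted.shape[0]),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
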