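"""Lightweight in-memory containers shared across the package.

A :class:`CellMatrix` holds an N x D expression matrix (raw counts or
log-normalized values) together with cell/gene identifiers and optional
per-cell ``group`` and ``condition`` labels.  A :class:`LatentMatrix` holds
the N x K coordinates produced by an encoder.  Both are thin, validated
dataclasses; conversion to/from :class:`anndata.AnnData` is provided for
interoperability with the scanpy ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_string_index(ids, n: int, prefix: str) -> pd.Index:
    if ids is None:
        return pd.Index([f"{prefix}{i}" for i in range(n)])
    idx = pd.Index(np.asarray(ids, dtype=object).astype(str))
    if len(idx) != n:
        raise ValueError(f"expected {n} {prefix.rstrip('_')} identifiers, got {len(idx)}")
    return idx


@dataclass
class CellMatrix:
    """N x D expression values with identifiers and optional labels.

    Parameters
    ----------
    X
        Dense ``(n_cells, n_genes)`` float array.  Raw counts and
        log-normalized values are both accepted; which one is stored is up
        to the caller (the VAE's likelihood mode decides what it expects).
    cell_ids, gene_ids
        Ordered identifiers; generated as ``cell0..`` / ``gene0..`` when
        omitted.
    group, condition
        Optional per-cell categorical labels (cell group / perturbation
        status).
    """

    X: np.ndarray
    cell_ids: pd.Index = None
    gene_ids: pd.Index = None
    group: np.ndarray | None = None
    condition: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        n, d = self.X.shape
        self.cell_ids = _as_string_index(self.cell_ids, n, "cell")
        self.gene_ids = _as_string_index(self.gene_ids, d, "gene")
        for name in ("group", "condition"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab, dtype=object).astype(str)
                if lab.shape[0] != n:
                    raise ValueError(f"{name} labels length {lab.shape[0]} != {n} cells")
                setattr(self, name, lab)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "CellMatrix":
        """Row-subset (copy); ``idx`` is any NumPy fancy index over cells."""
        idx = np.asarray(idx)
        return CellMatrix(
            X=self.X[idx].copy(),
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            group=None if self.group is None else self.group[idx],
            condition=None if self.condition is None else self.condition[idx],
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=self.cell_ids.copy())
        if self.group is not None:
            obs["group"] = self.group
        if self.condition is not None:
            obs["condition"] = self.condition
        var = pd.DataFrame(index=self.gene_ids.copy())
        return ad.AnnData(X=self.X.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata) -> "CellMatrix":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        return cls(
            X=np.asarray(X, dtype=float),
            cell_ids=adata.obs_names,
            gene_ids=adata.var_names,
            group=adata.obs["group"].to_numpy() if "group" in adata.obs else None,
            condition=adata.obs["condition"].to_numpy() if "condition" in adata.obs else None,
        )


@dataclass
class LatentMatrix:
    """N x K latent coordinates with ordered cell identifiers."""

    values: np.ndarray
    cell_index: pd.Index = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"latent values must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("latent matrix must have N >= 1 and K >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values contain non-finite entries")
        self.cell_index = _as_string_index(self.cell_index, self.values.shape[0], "cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


def lognormalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    The standard scRNA-seq normalization used for Gaussian-likelihood
    training and for reconstruction evaluation.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_sum)
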