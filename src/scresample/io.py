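"""Readers and writers for expression matrices and label tables.

Three on-disk layouts are supported:

``mtx``
    A directory with ``matrix.mtx`` (MatrixMarket, cells x genes),
    ``genes.tsv`` (one gene id per line) and ``cells.tsv`` (columns
    ``cell_id`` and optionally ``group`` / ``condition``).
``csv``
    A dense CSV with cell ids as the index and gene ids as the header;
    labels, if any, in a sibling ``<stem>.labels.tsv``.
``h5``
    An ``.h5ad`` AnnData file with labels in ``obs``.

Round-trips are lossless for integer counts and preserve id order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CellMatrix

logger = logging.getLogger(__name__)


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    if path.suffix in (".h5ad", ".h5"):
        return "h5"
    if path.suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer matrix format from {path}")


def read_matrix(path, fmt: str | None = None) -> CellMatrix:
    """Read a :class:`CellMatrix`; ``fmt`` in {mtx, csv, h5} (inferred when
    omitted)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        X = spio.mmread(path / "matrix.mtx")
        if sparse.issparse(X):
            X = X.toarray()
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells_path = path / "cells.tsv"
        group = condition = None
        if cells_path.exists():
            cells = pd.read_csv(cells_path, sep="\t")
            if len(cells) != X.shape[0]:
                raise ValueError(
                    f"label table has {len(cells)} rows but matrix has {X.shape[0]} cells")
            cell_ids = cells["cell_id"].astype(str)
            group = cells["group"].to_numpy() if "group" in cells else None
            condition = cells["condition"].to_numpy() if "condition" in cells else None
        else:
            logger.info("no cells.tsv next to %s; generating cell ids", path)
            cell_ids = None
        return CellMatrix(X=np.asarray(X, dtype=float), cell_ids=cell_ids,
                          gene_ids=genes, group=group, condition=condition)
    if fmt == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        group = condition = None
        labels_path = path.with_suffix(".labels.tsv")
        if labels_path.exists():
            lab = pd.read_csv(labels_path, sep="\t")
            if len(lab) != len(df):
                raise ValueError(
                    f"label table has {len(lab)} rows but matrix has {len(df)} cells")
            group = lab["group"].to_numpy() if "group" in lab else None
            condition = lab["condition"].to_numpy() if "condition" in lab else None
        else:
            logger.info("no label table next to %s", path)
        return CellMatrix(X=df.to_numpy(dtype=float), cell_ids=df.index,
                          gene_ids=df.columns, group=group, condition=condition)
    if fmt == "h5":
        import anndata as ad

        return CellMatrix.from_anndata(ad.read_h5ad(path))
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(cm: CellMatrix, path, fmt: str = "mtx") -> None:
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        X = cm.X
        field = "integer" if np.all(X == np.round(X)) else "real"
        mat = sparse.csr_matrix(X.astype(int) if field == "integer" else X)
        spio.mmwrite(path / "matrix.mtx", mat, field=field)
        pd.Series(cm.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                      header=False, index=False)
        cells = pd.DataFrame({"cell_id": cm.cell_ids})
        if cm.group is not None:
            cells["group"] = cm.group
        if cm.condition is not None:
            cells["condition"] = cm.condition
        cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    elif fmt == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        pd.DataFrame(cm.X, index=cm.cell_ids, columns=cm.gene_ids).to_csv(path, sep=sep)
        if cm.group is not None or cm.condition is not None:
            lab = pd.DataFrame({"cell_id": cm.cell_ids})
            if cm.group is not None:
                lab["group"] = cm.group
            if cm.condition is not None:
                lab["condition"] = cm.condition
            lab.to_csv(path.with_suffix(".labels.tsv"), sep="\t", index=False)
    elif fmt == "h5":
        cm.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_embeddings(path) -> np.ndarray:
    """Read an N x K embedding matrix from CSV/TSV (with or without an index
    column) or HDF5 (.h5ad obsm['X_latent'] or X)."""
    path = Path(path)
    if path.suffix in (".h5ad", ".h5"):
        import anndata as ad

        adata = ad.read_h5ad(path)
        Z = adata.obsm["X_latent"] if "X_latent" in adata.obsm else adata.X
        return np.asarray(Z, dtype=float)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, header=None)
    if isinstance(df.iloc[0, 0], str):  # header and/or index present
        df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float)
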