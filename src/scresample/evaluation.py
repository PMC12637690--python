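"""Evaluation metrics for the three downstream tasks.

Reconstruction quality is the per-cell Pearson correlation between true and
reconstructed log-normalized profiles, averaged over cells.  Embedding
quality is measured by a seeded 50/50-split k-nearest-neighbour classifier
(accuracy, precision, recall, micro/macro F1) and, for two-condition data,
by the adjusted Rand index of a K-means clustering of the embeddings.
Perturbation predictions are scored on mean expression profiles — squared
Pearson R^2 and MSE over all genes and over the top differentially
expressed genes (Wilcoxon rank-sum) — plus a per-cell cosine-similarity
distribution against the true mean perturbed profile.  Arms are compared
with two-sided Welch t-tests and the usual significance stars.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import (accuracy_score, adjusted_rand_score,
                             precision_recall_fscore_support)
from sklearn.neighbors import KNeighborsClassifier

from .containers import LatentMatrix

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def _rows(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def reconstruction_r(X_true, X_pred) -> float:
    """Mean per-cell Pearson r between true and predicted profiles.

    Cells whose true or predicted profile has zero variance across genes
    have an undefined correlation; they are excluded (count logged).
    """
    Xt, Xp = _rows(X_true), _rows(X_pred)
    if Xt.shape != Xp.shape:
        raise ValueError(f"shape mismatch {Xt.shape} vs {Xp.shape}")
    tc = Xt - Xt.mean(axis=1, keepdims=True)
    pc = Xp - Xp.mean(axis=1, keepdims=True)
    st = np.sqrt((tc**2).sum(axis=1))
    sp = np.sqrt((pc**2).sum(axis=1))
    valid = (st > 0) & (sp > 0)
    if not valid.all():
        logger.info("reconstruction_r: excluded %d zero-variance cells", (~valid).sum())
    if not valid.any():
        raise ValueError("no cell has a defined correlation")
    r = (tc[valid] * pc[valid]).sum(axis=1) / (st[valid] * sp[valid])
    return float(r.mean())


def knn_classify(Z, labels, k: int = 5, split_seed: int = 0) -> dict:
    """kNN classification of embeddings after a seeded 50/50 split.

    Fits a k-nearest-neighbour (Euclidean, majority-vote) classifier on a
    random half of the cells and scores predictions on the other half.
    Macro scores average over classes unweighted; micro scores are global.
    A class absent from the training half contributes an F1 of 0 to the
    macro average (with a warning).
    """
    Zv = Z.values if isinstance(Z, LatentMatrix) else np.asarray(Z, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes")
    n = Zv.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2*k} cells for k={k}")
    perm = np.random.default_rng(split_seed).permutation(n)
    half = n // 2
    tr, te = perm[:half], perm[half:]
    if set(labels[te]) - set(labels[tr]):
        warnings.warn("classes absent from the training half score F1 = 0 in the macro average")
    clf = KNeighborsClassifier(n_neighbors=k).fit(Zv[tr], labels[tr])
    pred = clf.predict(Zv[te])
    out = {"accuracy": float(accuracy_score(labels[te], pred))}
    all_classes = sorted(set(labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division for absent classes -> 0
        for avg in ("micro", "macro"):
            p, r, f1, _ = precision_recall_fscore_support(
                labels[te], pred, average=avg, labels=all_classes, zero_division=0)
            out[f"precision_{avg}"], out[f"recall_{avg}"], out[f"f1_{avg}"] = (
                float(p), float(r), float(f1))
    return out


def select_degs(X_control, X_perturbed, n_top: int = 100) -> np.ndarray:
    """Top differentially expressed genes between conditions.

    Per-gene two-sided Wilcoxon rank-sum; genes ranked by ascending
    p-value, ties broken by descending absolute mean difference.
    """
    Xc, Xp = _rows(X_control), _rows(X_perturbed)
    if Xc.shape[0] == 0 or Xp.shape[0] == 0:
        raise ValueError("both conditions must be non-empty")
    if Xc.shape[1] != Xp.shape[1]:
        raise ValueError("gene spaces differ")
    d = Xc.shape[1]
    if n_top > d:
        warnings.warn(f"n_top={n_top} exceeds {d} genes; returning all genes")
        n_top = d
    pvals = stats.ranksums(Xc, Xp, axis=0).pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    effect = np.abs(Xp.mean(axis=0) - Xc.mean(axis=0))
    order = np.lexsort((-effect, pvals))  # p ascending, then |mean diff| descending
    return order[:n_top]


def perturbation_metrics(X_pred, X_true_perturbed, deg_idx=None) -> dict:
    """Mean-profile R^2 and MSE (all genes and DEGs) plus per-cell cosine.

    R^2 is the squared Pearson correlation between the per-gene mean of the
    predictions and the per-gene mean of the true perturbed cells; MSE is
    on the same mean profiles.  Cosine similarity is computed per predicted
    cell against the true mean profile and returned as a distribution.
    """
    Xp, Xt = _rows(X_pred), _rows(X_true_perturbed)
    if Xp.shape[1] != Xt.shape[1]:
        raise ValueError("gene spaces differ")
    mean_pred, mean_true = Xp.mean(axis=0), Xt.mean(axis=0)

    def _r2(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(stats.pearsonr(a, b).statistic ** 2)

    out = {
        "r2_all": _r2(mean_pred, mean_true),
        "mse_all": float(np.mean((mean_pred - mean_true) ** 2)),
    }
    if deg_idx is not None:
        deg_idx = np.asarray(deg_idx, dtype=int)
        out["r2_deg"] = _r2(mean_pred[deg_idx], mean_true[deg_idx])
        out["mse_deg"] = float(np.mean((mean_pred[deg_idx] - mean_true[deg_idx]) ** 2))
    norm_t = np.linalg.norm(mean_true)
    norms_p = np.linalg.norm(Xp, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (Xp @ mean_true) / (norms_p * norm_t)
    out["cosine"] = cos
    out["cosine_mean"] = float(np.nanmean(cos))
    return out


def ari_condition(Z_test, condition_labels, kmeans_seed: int = 0) -> float:
    """ARI between a 2-cluster K-means of the embeddings and the
    control/perturbed labels (10 seeded restarts, best inertia kept)."""
    Zv = Z_test.values if isinstance(Z_test, LatentMatrix) else np.asarray(Z_test, float)
    labels = np.asarray(condition_labels, dtype=object).astype(str)
    if len(set(labels)) != 2:
        raise ValueError("need exactly two condition labels")
    km = KMeans(n_clusters=2, n_init=10, random_state=kmeans_seed).fit(Zv)
    return float(adjusted_rand_score(labels, km.labels_))


def significance_stars(p: float) -> str:
    for thresh, stars in STAR_THRESHOLDS:
        if p < thresh:
            return stars
    return "ns"


def compare_arms(metric_values_a, metric_values_b) -> tuple[float, str]:
    """Two-sided Welch t-test between two arms' replicate metric values.

    Returns ``(p_value, stars)`` with stars at the 0.05 / 0.01 / 0.001 /
    0.0001 thresholds.  Degenerate equal-constant inputs give p = 1.
    """
    a = np.asarray(metric_values_a, dtype=float)
    b = np.asarray(metric_values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per arm")
    if np.std(a) == 0 and np.std(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        with np.errstate(invalid="ignore"):
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    return p, significance_stars(p)
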