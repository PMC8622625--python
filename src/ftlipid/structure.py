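"""Exploratory structure analyses: PCA, co-occurrence, subgrouping, contingency.

These operate on the normalized (optionally log2) corresponded-peak matrix
and underpin the standard exploratory views of such a study: sample PCA,
sample- and feature-level correlation heatmaps, presence/absence
co-occurrence, clustering of samples on a single lipid category, and a 2x2
chi-square test of a clinical flag against a sample partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster.hierarchy import fcluster

from .diffabund import cluster_samples
from .icikt import correlation_matrix


@dataclass
class PCAResult:
    """Principal-component scores, loadings and variance proportions."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_ratio: np.ndarray


def pca_scores(values: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """PCA of samples on a features x samples matrix with missing entries.

    Missing values are replaced by the feature's mean over observed
    samples before column-centering and singular value decomposition;
    variance-explained proportions are squared singular values over the
    total variance.  Component signs are fixed so each loading vector's
    largest-magnitude entry is positive.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = values.to_numpy(dtype=float).T  # samples x features
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    filled = np.where(np.isnan(X), col_means[None, :], X)
    centered = filled - filled.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(S))
    signs = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    U, Vt = U * signs[None, :], Vt * signs[:, None]
    total = float((S**2).sum())
    ratio = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U[:, :k] * S[:k]), index=values.columns, columns=comps)
    loadings = pd.DataFrame(Vt[:k].T, index=values.index, columns=comps)
    return PCAResult(scores, loadings, ratio)


def cooccurrence_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Jaccard co-occurrence of feature presence patterns across samples.

    Entry (i, j) is |samples where both observed| / |samples where either
    observed|; rows of never-observed features are NaN.
    """
    present = values.notna().to_numpy(dtype=float)
    inter = present @ present.T
    counts = present.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1), np.nan)
    return pd.DataFrame(jac, index=values.index, columns=values.index)


def subgroup_samples(
    values: pd.DataFrame, k: int = 2, method: str = "average"
) -> pd.Series:
    """Partition samples by clustering on 1 - ICI-Kendall-tau distance.

    ``values`` is typically the matrix restricted to one lipid category
    (e.g. only sterol features).  Returns integer cluster labels (1..k)
    per sample.  Degenerate all-equal distances collapse to one cluster
    with a warning.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least two features in the category")
    tau = correlation_matrix(values, axis="samples")
    dist = 1.0 - tau
    np.fill_diagonal(dist.values, 0.0)
    off = dist.values[~np.eye(len(dist), dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size and np.allclose(finite, finite[0]):
        warnings.warn("degenerate distances: all samples equally distant; single cluster")
        return pd.Series(1, index=values.columns, name="subgroup")
    Z, _ = cluster_samples(dist, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=values.columns, name="subgroup")


def chi_squared_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) of a 2x2 count table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = _stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), 1, float(res.pvalue)
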