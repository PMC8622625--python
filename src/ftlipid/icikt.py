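"""Missing-value-aware Kendall-tau correlation and sample quality control.

In left-censored data a missing value is informative: the analyte was most
likely below detection.  The information-content-informed (ICI) Kendall tau
used here therefore treats every missing entry as a value strictly lower
than all observed entries of its vector, with the missing entries of a
vector mutually tied, and computes ordinary tau-b over all index pairs.
With no missing values it reduces exactly to classical tau-b.

Sample QC computes, per sample, (a) its median ICI-Kendall-tau correlation
to the other samples of the same disease class and (b) the fraction of its
observed lipids that fall outside the Tukey fences of that lipid's
same-class distribution; samples extreme on *both* statistics (below /
above the per-class Tukey fences of the statistic distributions) are
removed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats


def ici_kendall_tau(x, y) -> float:
    """ICI Kendall tau-b between two equal-length vectors with missing values.

    Missing entries (NaN) are ranked below every observed entry and tied
    with one another; tau-b's tie correction then handles them exactly.
    Returns NaN when either vector is completely tied (zero denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xs = np.where(np.isnan(x), -np.inf, x)
    ys = np.where(np.isnan(y), -np.inf, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _stats.kendalltau(xs, ys, variant="b")
    return float(res.statistic)


def _pairwise_complete_tau(x, y) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _stats.kendalltau(x[mask], y[mask], variant="b")
    return float(res.statistic)


def correlation_matrix(
    values: pd.DataFrame,
    axis: str = "samples",
    observed_only: bool = False,
) -> pd.DataFrame:
    """Symmetric Kendall-tau correlation matrix over samples or features.

    ``axis="samples"`` correlates columns with the full missing-aware
    statistic.  ``axis="features"`` correlates rows; with
    ``observed_only=True`` indices missing in either vector are dropped
    first and classical tau-b computed on the pairwise-complete rest (the
    convention for feature-feature correlation), giving NaN when fewer
    than two shared observations remain.
    """
    if axis == "samples":
        mat = values.to_numpy(dtype=float).T
        labels = values.columns
        func = ici_kendall_tau if not observed_only else _pairwise_complete_tau
    elif axis == "features":
        mat = values.to_numpy(dtype=float)
        labels = values.index
        func = _pairwise_complete_tau if observed_only else ici_kendall_tau
    else:
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors")
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = func(mat[i], mat[i])
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = func(mat[i], mat[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def tukey_fences(values) -> tuple[float, float]:
    """Boxplot-style outlier fences: hinge -/+ 1.5 x (hinge spread).

    Hinges are Tukey's five-number-summary hinges (medians of the lower and
    upper halves, the median included in both halves when n is odd), the
    convention of R's ``boxplot.stats``.
    """
    arr = np.asarray(values, dtype=float)
    arr = np.sort(arr[np.isfinite(arr)])
    n = arr.size
    if n == 0:
        raise ValueError("no finite values")
    d = (math.floor((n + 1) / 2) + 1) / 2  # 1-indexed hinge position
    lo_hinge = 0.5 * (arr[math.floor(d) - 1] + arr[math.ceil(d) - 1])
    hi_hinge = 0.5 * (arr[n - math.floor(d)] + arr[n - math.ceil(d)])
    iqr = hi_hinge - lo_hinge
    return lo_hinge - 1.5 * iqr, hi_hinge + 1.5 * iqr


def sample_outlier_stats(values: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-sample QC statistics: median within-class ICI-Kt and outlier-lipid fraction.

    ``values`` is features x samples (missing allowed, log2 normalized
    intensities); ``classes`` maps sample id to disease class.  The
    outlier-lipid fraction of a sample is the share of its *observed*
    features whose value falls outside the Tukey fences of that feature's
    observed same-class distribution.
    """
    classes = classes.reindex(values.columns)
    if classes.isna().any():
        raise ValueError("class labels missing for some samples")
    for cls, count in classes.value_counts().items():
        if count < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
    median_cor = pd.Series(index=values.columns, dtype=float)
    outlier_frac = pd.Series(index=values.columns, dtype=float)
    mat = values.to_numpy(dtype=float)
    col_index = {sid: i for i, sid in enumerate(values.columns)}
    for cls in classes.unique():
        members = list(classes.index[classes == cls])
        idx = [col_index[s] for s in members]
        sub = mat[:, idx]
        k = len(idx)
        cors = np.full((k, k), np.nan)
        for a in range(k):
            for b in range(a + 1, k):
                cors[a, b] = cors[b, a] = ici_kendall_tau(sub[:, a], sub[:, b])
        for a, sid in enumerate(members):
            median_cor[sid] = float(np.nanmedian(cors[a]))
        # per-feature fences over the class's observed values
        lo = np.full(sub.shape[0], np.nan)
        hi = np.full(sub.shape[0], np.nan)
        for f in range(sub.shape[0]):
            row = sub[f][np.isfinite(sub[f])]
            if row.size:
                lo[f], hi[f] = tukey_fences(row)
        for a, sid in enumerate(members):
            col = sub[:, a]
            obs = np.isfinite(col)
            n_obs = int(obs.sum())
            if n_obs == 0:
                outlier_frac[sid] = 0.0
                continue
            out = (col < lo) | (col > hi)
            outlier_frac[sid] = float(np.sum(out & obs)) / n_obs
    return pd.DataFrame({"median_cor": median_cor, "outlier_frac": outlier_frac})


def flag_outlier_samples(
    stats: pd.DataFrame, classes: pd.Series
) -> tuple[list[str], pd.DataFrame]:
    """Flag samples extreme on both QC statistics.

    Fences are computed per class over the per-sample statistic
    distributions; a sample is removed iff its median within-class
    correlation falls below the lower correlation fence *and* its
    outlier-lipid fraction rises above the upper fraction fence.
    Returns the removal list and the stats table augmented with fences and
    the removal flag.
    """
    classes = classes.reindex(stats.index)
    out = stats.copy()
    out["cor_lower_fence"] = np.nan
    out["frac_upper_fence"] = np.nan
    for cls in classes.unique():
        members = classes.index[classes == cls]
        cor_lo, _ = tukey_fences(stats.loc[members, "median_cor"])
        _, frac_hi = tukey_fences(stats.loc[members, "outlier_frac"])
        out.loc[members, "cor_lower_fence"] = cor_lo
        out.loc[members, "frac_upper_fence"] = frac_hi
    out["removed"] = (out["median_cor"] < out["cor_lower_fence"]) & (
        out["outlier_frac"] > out["frac_upper_fence"]
    )
    return list(out.index[out["removed"]]), out
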