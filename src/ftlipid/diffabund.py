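"""Differential abundance between disease classes.

Two complementary per-feature tests are run and their significant sets
united:

* a **moderated linear model**: per-feature ordinary least squares on
  (intercept, disease indicator, instrument indicator), with the residual
  variances shrunk toward a common prior by empirical Bayes.  The prior is
  a scaled inverse chi-square (d0, s0^2) estimated by moment matching on
  log s_g^2 (digamma/trigamma equations); the posterior variance
  s~_g^2 = (d0 s0^2 + d s_g^2)/(d0 + d) yields a moderated t with d + d0
  degrees of freedom.  This consumes imputed data.

* a **two-part test** for zero-inflated abundances: a two-proportion score
  statistic on presence/absence plus a Wilcoxon rank-sum statistic on the
  observed values; the squared z's add to a chi-square whose degrees of
  freedom count the non-degenerate parts.  This consumes *pre-imputation*
  data - the missingness is its signal.

Features adjusted-significant (Benjamini-Hochberg) in either test at the
alpha cutoff form the differential set; the union is deliberate, as the two
tests are sensitive to different alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as _stats
from statsmodels.stats.multitest import multipletests


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on the trigamma function (monotone decreasing).
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-feature residual variances.

    Fits a scaled inverse chi-square prior (``d0``, ``s0^2``) to the
    observed ``s2`` (each with ``df`` residual degrees of freedom) by
    matching the mean and variance of ``log s2`` through digamma/trigamma
    moments, then returns ``(d0, s0^2, posterior variances)``.  ``d0`` is
    infinite when the observed variances are no more dispersed than
    chi-square sampling alone explains.
    """
    ok = s2 > 0
    if ok.sum() == 0:
        return np.inf, 0.0, np.zeros_like(s2)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if e.size < 2:
        return np.inf, float(np.exp(emean)), np.full_like(s2, np.exp(emean))
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
        post = np.full_like(s2, s02)
    return d0, s02, post


def fit_moderated_linear_model(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated t-test of the disease contrast.

    ``values`` is the imputed log2 matrix (features x samples); the design
    has an intercept, a cancer indicator, and a Fusion-2 instrument
    indicator (dropped if only one instrument is present).  ``prior_df``
    overrides the estimated prior degrees of freedom; 0 gives ordinary
    per-feature t-tests.
    """
    meta = metadata.set_index("sample_id").reindex(values.columns)
    if meta["class"].isna().any():
        raise ValueError("metadata does not cover every sample")
    cancer = (meta["class"] == "cancer").to_numpy(dtype=float)
    cols = [np.ones_like(cancer), cancer]
    names = ["intercept", "cancer"]
    instruments = meta["instrument"].unique()
    if len(instruments) > 1:
        cols.append((meta["instrument"] == sorted(instruments)[1]).to_numpy(dtype=float))
        names.append("instrument")
    X = np.column_stack(cols)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n < p + 1:
        raise ValueError("need at least parameters + 1 samples")
    if min((cancer == 1).sum(), (cancer == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per class")

    Y = values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("moderated model requires imputed (complete) data")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # features x p
    resid = Y - beta @ X.T
    df_resid = n - p
    s2 = (resid**2).sum(axis=1) / df_resid
    effect = beta[:, 1]
    v_contrast = xtx_inv[1, 1]

    if prior_df is None:
        d0, s02, s2_post = squeeze_variances(s2, df_resid)
    elif prior_df == 0:
        d0, s02, s2_post = 0.0, float("nan"), s2.copy()
    else:
        d0 = float(prior_df)
        _, s02, _ = squeeze_variances(s2, df_resid)
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * v_contrast)
    t = np.where(np.isfinite(t), t, 0.0)
    df_total = df_resid + d0
    p_value = 2.0 * _stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p_value": p_value,
            "s2": s2,
            "s2_post": s2_post,
            "df_resid": float(df_resid),
            "df_prior": d0,
        },
        index=values.index,
    )


def two_part_test(values: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Two-part presence/abundance test per feature.

    ``values`` is the pre-imputation log2 matrix (NaN = missing).  The
    binary part is a two-proportion score z on presence between classes
    (degenerate when combined presence is 0% or 100%); the continuous part
    is a tie-corrected Wilcoxon rank-sum z on the observed values only
    (degenerate when either class has fewer than two observed values, or
    all observed values are tied).  The statistic z_B^2 + z_C^2 is referred
    to a chi-square whose df counts the non-degenerate parts; p = 1 when
    both parts are degenerate.
    """
    classes = classes.reindex(values.columns)
    if classes.isna().any():
        raise ValueError("class labels missing for some samples")
    labels = sorted(classes.unique())
    if len(labels) != 2:
        raise ValueError("exactly two classes required")
    g1 = (classes == "cancer").to_numpy() if "cancer" in labels else (classes == labels[0]).to_numpy()
    g2 = ~g1
    mat = values.to_numpy(dtype=float)
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per class")
    records = []
    for row in mat:
        obs = np.isfinite(row)
        m1, m2 = int(obs[g1].sum()), int(obs[g2].sum())
        pooled = (m1 + m2) / (n1 + n2)
        if 0 < pooled < 1:
            z_b = (m1 / n1 - m2 / n2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            df_b = 1
        else:
            z_b, df_b = 0.0, 0
        x1 = row[g1 & obs]
        x2 = row[g2 & obs]
        z_c, df_c = 0.0, 0
        if len(x1) >= 2 and len(x2) >= 2:
            pooled_vals = np.concatenate([x1, x2])
            ranks = _stats.rankdata(pooled_vals)
            ma, mb = len(x1), len(x2)
            m = ma + mb
            _, tie_counts = np.unique(pooled_vals, return_counts=True)
            tie_term = float(((tie_counts**3 - tie_counts)).sum())
            var_w = ma * mb / 12.0 * ((m + 1) - tie_term / (m * (m - 1)))
            if var_w > 0:
                w = float(ranks[:ma].sum())
                z_c = (w - ma * (m + 1) / 2.0) / np.sqrt(var_w)
                df_c = 1
        stat = z_b**2 + z_c**2
        df = df_b + df_c
        p = float(_stats.chi2.sf(stat, df)) if df > 0 else 1.0
        records.append(
            {"statistic": stat, "df": df, "p_value": p, "z_binary": z_b, "z_continuous": z_c}
        )
    return pd.DataFrame.from_records(records, index=values.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr.copy()
    return multipletests(arr, method="fdr_bh")[1]


def differential_features(
    moderated: pd.DataFrame,
    two_part: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Union of BH-significant features from the two tests, with provenance."""
    if not moderated.index.equals(two_part.index):
        if set(moderated.index) != set(two_part.index):
            raise ValueError("the two tests cover different feature universes")
        two_part = two_part.reindex(moderated.index)
    out = pd.DataFrame(index=moderated.index)
    out["p_moderated"] = moderated["p_value"]
    out["p_two_part"] = two_part["p_value"]
    out["adj_p_moderated"] = bh_adjust(out["p_moderated"])
    out["adj_p_two_part"] = bh_adjust(out["p_two_part"])
    out["sig_moderated"] = out["adj_p_moderated"] <= alpha
    out["sig_two_part"] = out["adj_p_two_part"] <= alpha
    out["significant"] = out["sig_moderated"] | out["sig_two_part"]
    out["provenance"] = np.select(
        [
            out["sig_moderated"] & out["sig_two_part"],
            out["sig_moderated"],
            out["sig_two_part"],
        ],
        ["both", "moderated", "two-part"],
        default="",
    )
    return out


def log2_fold_changes(values: pd.DataFrame, classes: pd.Series) -> pd.Series:
    """Cancer mean minus non-cancer mean per feature, on imputed log2 data."""
    if values.isna().any().any():
        raise ValueError("fold changes require imputed (complete) data")
    classes = classes.reindex(values.columns)
    cancer_cols = classes.index[classes == "cancer"]
    other_cols = classes.index[classes != "cancer"]
    return (values[cancer_cols].mean(axis=1) - values[other_cols].mean(axis=1)).rename("log2fc")


def _subtree_weights(Z: np.ndarray, n: int) -> np.ndarray:
    # total within-subtree merge height per node (leaves weigh 0)
    weights = np.zeros(2 * n - 1)
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        weights[n + i] = Z[i, 2] + weights[a] + weights[b]
    return weights


def cluster_samples(
    distance: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns the scipy linkage matrix and the leaf labels in display order,
    reordered so that at every internal node the subtree with the smaller
    total within-cluster merge distance comes first (smallest-first
    dendrogram sorting).
    """
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    arr = distance.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    arr = np.where(np.isfinite(arr), arr, np.nanmax(np.where(np.isfinite(arr), arr, 0)) * 2 + 1)
    n = arr.shape[0]
    Z = linkage(squareform((arr + arr.T) / 2.0, checks=False), method=method)
    weights = _subtree_weights(Z, n)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        first, second = (a, b) if (weights[a], a) <= (weights[b], b) else (b, a)
        return leaves(first) + leaves(second)

    order = leaves(2 * n - 2)
    labels = list(distance.index)
    return Z, [labels[i] for i in order]


@dataclass
class DifferentialAbundanceModel:
    """Two-test differential abundance model for a corresponded-peak matrix.

    Parameters
    ----------
    imputed : DataFrame
        Imputed log2 matrix (features x samples) for the moderated linear
        model and fold changes.
    observed : DataFrame
        Pre-imputation log2 matrix with NaN for missing, for the two-part
        test.
    metadata : DataFrame
        Sample table with ``sample_id``, ``class`` and ``instrument``.
    """

    imputed: pd.DataFrame
    observed: pd.DataFrame
    metadata: pd.DataFrame
    alpha: float = 0.01

    @classmethod
    def from_matrices(cls, imputed, observed, metadata, alpha: float = 0.01):
        if not imputed.index.equals(observed.index):
            raise ValueError("imputed and observed matrices must share a feature index")
        return cls(imputed, observed, metadata, alpha)

    def fit(self, prior_df: float | None = None) -> "DifferentialAbundanceResults":
        classes = self.metadata.set_index("sample_id")["class"]
        moderated = fit_moderated_linear_model(self.imputed, self.metadata, prior_df)
        two_part = two_part_test(self.observed, classes)
        table = differential_features(moderated, two_part, self.alpha)
        table.insert(0, "effect", moderated["effect"])
        table["log2fc"] = log2_fold_changes(self.imputed, classes)
        table["direction"] = np.where(table["log2fc"] > 0, "more", "less")
        table.loc[table["log2fc"] == 0, "direction"] = ""
        return DifferentialAbundanceResults(table, moderated, two_part, self.alpha)


@dataclass
class DifferentialAbundanceResults:
    """Fitted differential-abundance results with per-feature statistics."""

    table: pd.DataFrame
    moderated: pd.DataFrame
    two_part: pd.DataFrame
    alpha: float

    @property
    def significant_features(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def summary(self) -> str:
        t = self.table
        sig = t["significant"]
        lines = [
            "Differential abundance summary",
            "==============================",
            f"features tested        {len(t)}",
            f"alpha (BH-adjusted)    {self.alpha}",
            f"significant, moderated {int(t['sig_moderated'].sum())}",
            f"significant, two-part  {int(t['sig_two_part'].sum())}",
            f"significant, union     {int(sig.sum())}",
            f"  more abundant        {int((sig & (t['direction'] == 'more')).sum())}",
            f"  less abundant        {int((sig & (t['direction'] == 'less')).sum())}",
        ]
        return "\n".join(lines)
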