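"""Lipid-category enrichment of differentially abundant features.

Every singly categorized corresponded peak forms the universe.  Each
feature carries its lipid-category annotation; sphingolipids additionally
carry a low/high-m/z annotation split at m/z 700 (inclusive on the high
side).  For each direction of change (more / less abundant in cancer) and
each of the seven annotations, over-representation of the significant
features is tested with an exact upper-tail hypergeometric probability
P(X >= k), and Benjamini-Hochberg adjustment is applied across the seven
annotations within the direction.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from .diffabund import bh_adjust

#: Annotation rows in report order.
ANNOTATION_ORDER = ("FA", "GP", "PR", "SP", "SP-low", "SP-high", "ST")

ANNOTATION_NAMES = {
    "FA": "Fatty Acyls [FA]",
    "GP": "Glycerophospholipids [GP]",
    "PR": "Prenol Lipids [PR]",
    "SP": "Sphingolipids [SP]",
    "SP-low": "Sphingolipids [SP]-Low m/z",
    "SP-high": "Sphingolipids [SP]-High m/z",
    "ST": "Sterol Lipids [ST]",
}

#: Published category-level counts of the emulated NSCLC cohort: universe
#: size, significant-feature counts per direction, and per-annotation
#: (total, observed more-abundant, observed less-abundant).
NSCLC_TABLE1 = {
    "universe": 526,
    "K_more": 131,
    "K_less": 173,
    "annotations": {
        "FA": (12, 2, 0),
        "GP": (205, 37, 88),
        "PR": (5, 0, 0),
        "SP": (281, 79, 81),
        "SP-low": (33, 3, 16),
        "SP-high": (248, 76, 65),
        "ST": (23, 13, 3),
    },
}


def annotate_categories(features: pd.DataFrame, mz_split: float = 700.0) -> pd.DataFrame:
    """Annotation table over the singly categorized universe.

    ``features`` needs ``category`` and ``mz`` columns.  Features whose
    category is one of the five lipid categories form the universe; each
    gets its category annotation, and sphingolipids additionally get
    ``SP-low`` (m/z < split) or ``SP-high`` (m/z >= split).
    """
    if features["mz"].isna().any():
        raise ValueError("every feature needs an m/z")
    universe = features[features["category"].isin(["FA", "GP", "PR", "SP", "ST"])]
    annotations = []
    for cat, mz in zip(universe["category"], universe["mz"]):
        anns = [cat]
        if cat == "SP":
            anns.append("SP-high" if mz >= mz_split else "SP-low")
        annotations.append(tuple(anns))
    return pd.DataFrame({"annotations": annotations}, index=universe.index)


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Expected overlap and exact upper-tail p of a hypergeometric draw.

    ``N`` universe size, ``K`` significant features, ``n`` annotation size,
    ``k`` observed overlap.  ``expected = n*K/N``; ``p = P(X >= k)`` summed
    exactly from the probability mass function using integer
    combinatorics.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError("inconsistent hypergeometric counts")
    expected = n * K / N
    if k <= 0:
        return expected, 1.0
    den = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return expected, num / den


def _direction_block(N: int, K: int, counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    rows = []
    for ann in ANNOTATION_ORDER:
        n, k = counts[ann]
        expected, p = hypergeometric_enrichment(N, K, n, k)
        rows.append({"annotation": ann, "total": n, "expected": expected, "observed": k, "p": p})
    block = pd.DataFrame(rows).set_index("annotation")
    block["p_adjust"] = bh_adjust(block["p"])
    return block


def enrichment_from_counts(
    N: int,
    K_more: int,
    K_less: int,
    annotations: dict[str, tuple[int, int, int]],
) -> pd.DataFrame:
    """Enrichment table from explicit counts.

    ``annotations`` maps annotation -> (total n, observed more k, observed
    less k).  Returns one row per annotation with expected / observed /
    raw p / BH-adjusted p for both directions, BH applied across the seven
    annotations within each direction.
    """
    more = _direction_block(N, K_more, {a: (v[0], v[1]) for a, v in annotations.items()})
    less = _direction_block(N, K_less, {a: (v[0], v[2]) for a, v in annotations.items()})
    out = pd.DataFrame(index=pd.Index(ANNOTATION_ORDER, name="annotation"))
    out["total"] = more["total"]
    for direction, block in (("more", more), ("less", less)):
        out[f"expected_{direction}"] = block["expected"]
        out[f"observed_{direction}"] = block["observed"]
        out[f"p_{direction}"] = block["p"]
        out[f"p_adjust_{direction}"] = block["p_adjust"]
    return out


def enrichment_table(
    diff_table: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Enrichment table from per-feature differential results.

    ``diff_table`` needs ``significant`` and ``direction`` columns (from
    :class:`~ftlipid.diffabund.DifferentialAbundanceResults`);
    ``annotations`` is the universe table from :func:`annotate_categories`.
    Only universe features are counted.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation universe")
    universe = annotations.index.intersection(diff_table.index)
    ann = annotations.loc[universe, "annotations"]
    sig = diff_table.loc[universe, "significant"]
    direction = diff_table.loc[universe, "direction"]
    N = len(universe)
    K_more = int((sig & (direction == "more")).sum())
    K_less = int((sig & (direction == "less")).sum())
    counts: dict[str, tuple[int, int, int]] = {}
    for a in ANNOTATION_ORDER:
        has = ann.map(lambda t: a in t)
        n = int(has.sum())
        k_more = int((has & sig & (direction == "more")).sum())
        k_less = int((has & sig & (direction == "less")).sum())
        counts[a] = (n, k_more, k_less)
    return enrichment_from_counts(N, K_more, K_less, counts)
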