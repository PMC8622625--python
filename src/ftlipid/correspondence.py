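"""Cross-spectrum peak correspondence by elemental-formula (EMF) voting.

Direct-infusion FT-MS spectra of the same extract type observe largely the
same ions, but untargeted formula assignment is ambiguous: each peak may
carry several candidate formulas.  Peaks are first matched across spectra by
m/z proximity (single-linkage chaining within a ppm tolerance); within each
matched group every spectrum then casts one ballot per distinct candidate
EMF it proposes, and an EMF becomes the consensus assignment only when its
ballot count exceeds a support fraction of the spectra in the group.  The
surviving consensus features ("corresponded peaks") are isotopologue-level:
one feature per consensus (EMF, isotopologue index, adduct).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._formula import peak_mz


class Candidate(NamedTuple):
    """One candidate assignment of a spectral peak."""

    emf: str
    imf: int
    adduct: str
    categories: tuple[str, ...]
    multi: bool


class Consensus(NamedTuple):
    """Winning assignment of a peak group."""

    emf: str
    imf: int
    adduct: str
    support: int
    n_spectra: int


def group_peaks_by_mz(
    spectra: Mapping[str, pd.DataFrame], tol_ppm: float = 5.0
) -> pd.DataFrame:
    """Match peaks across spectra by m/z single-linkage chaining.

    Pools all peaks, sorts by m/z, and joins consecutive peaks into one
    group when their gap is at most ``tol_ppm`` (in parts per million of the
    pair's mean m/z).  A group keeps at most one peak per spectrum: when a
    spectrum contributes several, the most intense stays and the rest are
    demoted to their own singleton groups.

    Returns a long-format frame with columns ``sample``, ``mz``,
    ``intensity``, ``candidates`` and integer ``group``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    frames = []
    for sample, peaks in spectra.items():
        if len(peaks) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "mz": np.asarray(peaks["mz"], dtype=float),
                    "intensity": np.asarray(peaks["intensity"], dtype=float),
                    "candidates": list(peaks["candidates"]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["sample", "mz", "intensity", "candidates", "group"])
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values("mz", kind="mergesort").reset_index(drop=True)
    mz = pooled["mz"].to_numpy()
    gaps = np.diff(mz)
    limits = tol_ppm * 1e-6 * 0.5 * (mz[:-1] + mz[1:])
    new_group = np.concatenate([[True], gaps > limits])
    pooled["group"] = np.cumsum(new_group) - 1

    # enforce one peak per spectrum per group
    next_group = int(pooled["group"].max()) + 1
    dup = pooled.duplicated(subset=["group", "sample"], keep=False)
    if dup.any():
        keep = (
            pooled[dup]
            .groupby(["group", "sample"])["intensity"]
            .idxmax()
            .to_numpy()
        )
        demote = pooled.index[dup].difference(pd.Index(keep))
        groups = pooled["group"].to_numpy().copy()
        groups[demote] = np.arange(next_group, next_group + len(demote))
        pooled["group"] = groups
    return pooled


def emf_vote(group: pd.DataFrame, min_support: float = 0.5) -> Consensus | None:
    """Elect a consensus EMF for one peak group.

    Each spectrum casts one ballot per distinct candidate EMF of its peak.
    The EMF with the most ballots wins iff its count strictly exceeds
    ``min_support`` times the number of spectra in the group.  Ties are
    broken by the smallest mean absolute ppm error of the candidate's
    theoretical m/z against the observed peaks, then lexicographically by
    EMF string.  The consensus isotopologue index and adduct are the modal
    (IMF, adduct) pair among the winner's supporting candidates.
    """
    n = len(group)
    if n == 0:
        raise ValueError("empty peak group")
    ballots: Counter[str] = Counter()
    observed: dict[str, list[tuple[float, list[Candidate]]]] = {}
    pairs: dict[str, Counter] = {}
    for mz_obs, cands in zip(group["mz"].to_numpy(), group["candidates"]):
        if not cands:
            raise ValueError("peak without candidate assignments")
        by_emf: dict[str, list[Candidate]] = {}
        for cand in cands:
            by_emf.setdefault(cand.emf, []).append(cand)
        for emf, group_cands in by_emf.items():
            ballots[emf] += 1
            emf_pairs = pairs.setdefault(emf, Counter())
            for cand in group_cands:
                emf_pairs[(cand.imf, cand.adduct)] += 1
            observed.setdefault(emf, []).append((mz_obs, group_cands))
    top = max(ballots.values())
    if top <= min_support * n:
        return None
    winners = [emf for emf, c in ballots.items() if c == top]
    if len(winners) == 1:
        winner = winners[0]
    else:

        def mean_abs_ppm(emf: str) -> float:
            errors = []
            for mz_obs, cands in observed[emf]:
                best = np.inf
                for cand in cands:
                    theo = peak_mz(cand.emf, cand.imf, cand.adduct)
                    best = min(best, abs(mz_obs - theo) / theo * 1e6)
                errors.append(best)
            return float(np.mean(errors))

        winner = min(winners, key=lambda e: (mean_abs_ppm(e), e))
    pair_counts = pairs[winner]
    top_pair = max(pair_counts.values())
    imf, adduct = min(p for p, c in pair_counts.items() if c == top_pair)
    return Consensus(winner, imf, adduct, top, n)


def _propagate_category(group: pd.DataFrame, emf: str) -> str:
    labels: set[str] = set()
    for cands in group["candidates"]:
        for cand in cands:
            if cand.emf == emf:
                labels.update(cand.categories)
    if labels == {"not-lipid"}:
        return "not-lipid"
    labels.discard("not-lipid")
    if len(labels) > 1:
        return "multiple"
    return labels.pop()


def build_corresponded_matrix(
    spectra: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    tol_ppm: float = 5.0,
    min_support: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the corresponded-peak intensity matrix and its annotation table.

    Returns ``(values, annotations)``: ``values`` is features x samples with
    NaN for samples where the feature's peak is absent; ``annotations`` has
    one row per corresponded peak with the consensus assignment, a
    representative m/z, the propagated lipid-category label ("multiple" when
    the winning EMF carries more than one), an ``excluded`` flag marking
    "not lipid"/multiply classified features, and per-class presence
    fractions.
    """
    missing = set(spectra) - set(metadata["sample_id"])
    if missing:
        raise ValueError(f"spectra missing from metadata: {sorted(missing)}")
    sample_ids = list(metadata["sample_id"])
    classes = metadata.set_index("sample_id")["class"]
    class_sizes = classes.value_counts()
    pooled = group_peaks_by_mz(spectra, tol_ppm)
    records = []
    intensities: dict[str, dict[str, float]] = {}
    seen: Counter[str] = Counter()
    for _, grp in pooled.groupby("group", sort=True):
        cons = emf_vote(grp, min_support)
        if cons is None:
            continue
        fid = f"{cons.emf}|M+{cons.imf}|{cons.adduct}"
        seen[fid] += 1
        if seen[fid] > 1:
            fid = f"{fid}@{grp['mz'].mean():.4f}"
        row_int = dict(zip(grp["sample"], grp["intensity"]))
        intensities[fid] = row_int
        present = pd.Index(row_int)
        pres = {
            cls: (classes.loc[present] == cls).sum() / size
            for cls, size in class_sizes.items()
        }
        records.append(
            {
                "feature_id": fid,
                "emf": cons.emf,
                "imf": cons.imf,
                "adduct": cons.adduct,
                "mz": float(grp["mz"].mean()),
                "category": _propagate_category(grp, cons.emf),
                "support": cons.support,
                "n_spectra": cons.n_spectra,
                **{f"presence_{cls.replace('-', '_')}": frac for cls, frac in pres.items()},
            }
        )
    annotations = pd.DataFrame.from_records(records).set_index("feature_id")
    annotations["excluded"] = annotations["category"].isin(["multiple", "not-lipid"])
    values = pd.DataFrame.from_dict(intensities, orient="index", columns=sample_ids)
    values = values.reindex(index=annotations.index, columns=sample_ids).astype(float)
    return values, annotations


def class_presence(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-feature fraction of samples of each class with an observed peak."""
    classes = metadata.set_index("sample_id")["class"]
    observed = values.notna()
    out = {}
    for cls, members in classes.groupby(classes).groups.items():
        cols = [c for c in values.columns if c in members]
        out[cls] = observed[cols].sum(axis=1) / len(cols)
    return pd.DataFrame(out)


def filter_by_class_presence(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    min_frac: float = 0.25,
) -> pd.DataFrame:
    """Keep features observed in at least ``min_frac`` of either class.

    The threshold is inclusive: a feature present in exactly 25% of one
    class survives the default filter.
    """
    known = set(metadata["class"])
    if not known:
        raise ValueError("metadata has no classes")
    presence = class_presence(values, metadata)
    keep = (presence >= min_frac).any(axis=1)
    return values.loc[keep]
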