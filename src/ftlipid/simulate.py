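"""Synthetic paired two-class lipidomics study generator.

Emulates the statistical structure of a paired cancer / non-cancer
direct-infusion FT-MS lipidomics cohort: two samples per patient (one per
disease class), spectra acquired on one of two instruments with a
feature-specific instrument batch effect, category-level log2 abundance
shifts in cancer (sterols up, glycerophospholipids down, high-m/z
sphingolipids up by default), missing-not-at-random left-censoring of low
abundances, isotopologue peaks with geometrically decaying intensity, and
partial assignment ambiguity via near-isobaric decoy candidate formulas.

Each generated feature is a unique elemental molecular formula (EMF) with
an adduct; the emitted peak lists carry the full candidate-assignment
structure the correspondence stage consumes, and a ground-truth table
records every feature's true annotation and planted effect for recovery
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._formula import (
    ADDUCT_MASS,
    C13_C12,
    ELEMENT_CAPS,
    MZ_LIMIT,
    hill_formula,
    parse_formula,
    peak_mz,
    within_caps,
)
from .correspondence import Candidate

LIPID_CATEGORIES = ("FA", "GP", "PR", "SP", "ST")

# Monoisotopic element masses used when sketching a formula near a target m/z.
_M = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048, "O": 15.9949146196, "P": 30.97376163}

# Category-typical m/z windows and heteroatom templates (N choices, O range, P choices).
_CATEGORY_MZ = {
    "FA": (250.0, 450.0),
    "GP": (650.0, 900.0),
    "PR": (200.0, 400.0),
    "SP": (450.0, 1050.0),
    "ST": (580.0, 760.0),
    "not-lipid": None,
}
_CATEGORY_ELEMENTS = {
    "FA": ((0,), (2, 4), (0,)),
    "GP": ((0, 1), (8, 10), (1, 2)),
    "PR": ((0,), (1, 2), (0,)),
    "SP": ((1, 2), (3, 6), (0, 1)),
    "ST": ((0,), (2, 4), (0,)),
    "not-lipid": ((0, 1, 2, 3), (0, 12), (0, 1, 2, 3)),
}

#: Minimum spacing (Da) between any two emitted peak positions, so that
#: distinct features never collide within the correspondence ppm tolerance.
_MIN_PEAK_GAP = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study.

    Defaults mirror the emulated cohort: category proportions follow the
    singly categorized universe of the real study (the remainder of the
    feature budget is "not lipid"), the instrument batch effect is larger
    than the disease effect, and the planted disease effects are the
    sterol-up / glycerophospholipid-down / high-m/z-sphingolipid-up
    phenotype.  All sigmas are log2-scale standard deviations.
    """

    n_patients: int = 20
    n_features: int = 400
    frac_category: Mapping[str, float] = field(
        default_factory=lambda: {"FA": 0.025, "GP": 0.38, "PR": 0.01, "SP": 0.47, "ST": 0.045}
    )
    mz_range: tuple[float, float] = (200.0, 1200.0)
    effect_log2fc: Mapping[str, float] = field(
        default_factory=lambda: {"ST": 2.0, "GP": -1.0, "SP-high": 1.0}
    )
    sigma_patient: float = 0.5
    sigma_instrument: float = 1.0
    sigma_noise: float = 0.5
    censor_quantile: float = 0.15
    ambiguity_rate: float = 0.2
    multi_label_rate: float = 0.05
    isotopologue_count: int = 2
    isotopologue_ratio: float = 0.3
    baseline_log2_mean: float = 14.0
    baseline_log2_sd: float = 2.0
    mz_split: float = 700.0
    statin_rate: float = 1 / 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_features <= 0:
            raise ValueError("n_patients and n_features must be positive")
        fracs = dict(self.frac_category)
        if any(f < 0 or f > 1 for f in fracs.values()) or sum(fracs.values()) > 1 + 1e-9:
            raise ValueError("category proportions must lie in [0,1] and sum to <= 1")
        if set(fracs) - set(LIPID_CATEGORIES):
            raise ValueError(f"unknown categories: {set(fracs) - set(LIPID_CATEGORIES)}")
        lo, hi = self.mz_range
        if not (150.0 < lo < hi <= MZ_LIMIT):
            raise ValueError(f"mz_range must lie within (150, {MZ_LIMIT}]")
        for name in ("sigma_patient", "sigma_instrument", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must lie in [0, 1)")
        for name in ("ambiguity_rate", "multi_label_rate", "statin_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.isotopologue_count < 1:
            raise ValueError("isotopologue_count must be >= 1")
        if not 0 < self.isotopologue_ratio < 1:
            raise ValueError("isotopologue_ratio must lie in (0, 1)")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Study:
    """A generated study: peak lists, sample metadata, and ground truth."""

    config: SimConfig
    peaklists: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    features: pd.DataFrame  # ground truth, one row per (EMF, isotopologue) feature
    latent: pd.DataFrame  # true log2 abundance of m+0 features x samples
    observed: pd.DataFrame  # boolean mask, False where censored

    def latent_matrix(self) -> pd.DataFrame:
        """Observed log2 latent abundances (NaN where censored).

        One row per (EMF, isotopologue) feature, mirroring the corresponded
        matrix the correspondence stage would produce on these peak lists;
        features censored in every sample emit no peaks and are therefore
        absent.
        """
        blocks = []
        ratio_step = float(np.log2(self.config.isotopologue_ratio))
        ever = self.observed.any(axis=1)
        base = self.latent.where(self.observed).loc[ever]
        ids0 = list(base.index)
        for k in range(self.config.isotopologue_count):
            block = base + k * ratio_step
            block.index = [fid.replace("|M+0|", f"|M+{k}|") for fid in ids0]
            blocks.append(block)
        return pd.concat(blocks)


def _decoy_emf(counts: dict[str, int]) -> dict[str, int] | None:
    """A near-isobaric decoy: swap C4 <-> N+P+H3 (delta ~0.3 mDa)."""
    if counts.get("C", 0) >= 5 and counts.get("N", 0) + 1 <= ELEMENT_CAPS["N"] and counts.get(
        "P", 0
    ) + 1 <= ELEMENT_CAPS["P"] and counts.get("H", 0) + 3 <= ELEMENT_CAPS["H"]:
        out = dict(counts)
        out["C"] -= 4
        out["N"] = out.get("N", 0) + 1
        out["P"] = out.get("P", 0) + 1
        out["H"] = out.get("H", 0) + 3
        return out
    if counts.get("N", 0) >= 1 and counts.get("P", 0) >= 1 and counts.get("H", 0) >= 4:
        out = dict(counts)
        out["C"] += 4
        out["N"] -= 1
        out["P"] -= 1
        out["H"] -= 3
        if within_caps(out):
            return out
    return None


def _sketch_formula(target_neutral: float, rng: np.random.Generator, category: str):
    """Element counts of a CHNOP formula with monoisotopic mass near target."""
    n_choices, (o_lo, o_hi), p_choices = _CATEGORY_ELEMENTS[category]
    n_n = int(rng.choice(n_choices))
    n_p = int(rng.choice(p_choices))
    n_o = int(rng.integers(o_lo, o_hi + 1))
    rem = target_neutral - n_n * _M["N"] - n_p * _M["P"] - n_o * _M["O"]
    n_c = int(rem / 13.82)  # CH1.8 repeating-unit mass
    if n_c < 1:
        return None
    n_h = int(round((rem - 12.0 * n_c) / _M["H"]))
    if n_h < 1:
        return None
    counts = {"C": n_c, "H": n_h, "N": n_n, "O": n_o, "P": n_p}
    counts = {el: n for el, n in counts.items() if n > 0}
    if not within_caps(counts):
        return None
    return counts


def generate_study(config: SimConfig) -> Study:
    """Generate peak lists, metadata, and ground truth for one study.

    Each feature's latent log2 abundance in a sample is
    ``baseline + class effect + patient effect + instrument effect + noise``;
    entries below the class-specific censoring threshold (the
    ``censor_quantile`` of the class's pooled latent distribution) are
    omitted from the peak lists.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- feature panel -------------------------------------------------
    counts_per_cat = {c: int(round(config.frac_category.get(c, 0.0) * config.n_features))
                      for c in LIPID_CATEGORIES}
    while sum(counts_per_cat.values()) > config.n_features:
        biggest = max(counts_per_cat, key=counts_per_cat.get)
        counts_per_cat[biggest] -= 1
    categories = [c for c, n in counts_per_cat.items() for _ in range(n)]
    categories += ["not-lipid"] * (config.n_features - len(categories))

    emfs: list[str] = []
    adducts: list[str] = []
    mzs: list[float] = []
    used_emfs: set[str] = set()
    used_positions: list[float] = []
    lo_cfg, hi_cfg = config.mz_range
    for cat in categories:
        window = _CATEGORY_MZ[cat]
        lo = max(lo_cfg, window[0]) if window else lo_cfg
        hi = min(hi_cfg, window[1]) if window else hi_cfg
        if lo >= hi:
            lo, hi = lo_cfg, hi_cfg
        placed = False
        for _ in range(500):
            target = rng.uniform(lo, hi)
            adduct = str(rng.choice(list(ADDUCT_MASS)))
            counts = _sketch_formula(target - ADDUCT_MASS[adduct], rng, cat)
            if counts is None:
                continue
            emf = hill_formula(counts)
            if emf in used_emfs:
                continue
            mz0 = peak_mz(emf, 0, adduct)
            if not (lo_cfg <= mz0 <= min(hi_cfg, MZ_LIMIT)):
                continue
            positions = [mz0 + k * C13_C12 for k in range(config.isotopologue_count)]
            if any(
                abs(p - q) < _MIN_PEAK_GAP for p in positions for q in used_positions
            ):
                continue
            used_emfs.add(emf)
            used_positions.extend(positions)
            emfs.append(emf)
            adducts.append(adduct)
            mzs.append(mz0)
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a feature; widen mz_range or reduce n_features")

    mzs_arr = np.array(mzs)
    annotations = []
    for cat, mz0 in zip(categories, mzs_arr):
        if cat == "SP":
            annotations.append("SP-high" if mz0 >= config.mz_split else "SP-low")
        else:
            annotations.append(cat)
    effects = np.array(
        [
            config.effect_log2fc.get(cat, 0.0)
            + (config.effect_log2fc.get(ann, 0.0) if cat == "SP" else 0.0)
            for cat, ann in zip(categories, annotations)
        ]
    )

    # multi-label features carry a second (spurious) category on every candidate
    multi = np.zeros(config.n_features, dtype=bool)
    label_sets: list[tuple[str, ...]] = []
    for i, cat in enumerate(categories):
        if cat != "not-lipid" and rng.random() < config.multi_label_rate:
            other = str(rng.choice([c for c in LIPID_CATEGORIES if c != cat]))
            label_sets.append(tuple(sorted((cat, other))))
            multi[i] = True
        else:
            label_sets.append((cat,))

    # --- samples -------------------------------------------------------
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    instruments = ["Fusion 1" if i % 2 == 0 else "Fusion 2" for i in range(config.n_patients)]
    statin = rng.random(config.n_patients) < config.statin_rate
    meta_rows = []
    for pid, instr, st in zip(patients, instruments, statin):
        for cls, suffix in (("cancer", "C"), ("non-cancer", "N")):
            meta_rows.append(
                {
                    "sample_id": f"{pid}-{suffix}",
                    "patient_id": pid,
                    "class": cls,
                    "instrument": instr,
                    "statin": bool(st),
                }
            )
    metadata = pd.DataFrame(meta_rows)
    sample_ids = list(metadata["sample_id"])
    is_cancer = (metadata["class"] == "cancer").to_numpy()
    is_f2 = (metadata["instrument"] == "Fusion 2").to_numpy()
    patient_index = metadata["patient_id"].map({p: i for i, p in enumerate(patients)}).to_numpy()

    # --- latent abundances --------------------------------------------
    nf, ns = config.n_features, len(sample_ids)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, nf)
    patient_eff = rng.normal(0.0, config.sigma_patient, (nf, config.n_patients))
    instr_eff = rng.normal(0.0, config.sigma_instrument, nf)
    noise = rng.normal(0.0, config.sigma_noise, (nf, ns))
    latent = (
        baseline[:, None]
        + effects[:, None] * is_cancer[None, :]
        + patient_eff[:, patient_index]
        + instr_eff[:, None] * is_f2[None, :]
        + noise
    )

    # --- left-censoring ------------------------------------------------
    observed = np.ones((nf, ns), dtype=bool)
    if config.censor_quantile > 0:
        for cls in ("cancer", "non-cancer"):
            cols = (metadata["class"] == cls).to_numpy()
            pool = latent[:, cols]
            threshold = np.quantile(pool, config.censor_quantile)
            observed[:, cols] = pool >= threshold

    # --- peak emission -------------------------------------------------
    ratio = config.isotopologue_ratio
    decoy_cache: dict[str, str | None] = {}
    peaklists: dict[str, pd.DataFrame] = {}
    for j, sid in enumerate(sample_ids):
        rows = []
        for i in np.flatnonzero(observed[:, j]):
            base_intensity = float(2.0 ** latent[i, j])
            for k in range(config.isotopologue_count):
                cands = [
                    Candidate(emfs[i], k, adducts[i], label_sets[i], multi[i])
                ]
                if config.ambiguity_rate > 0 and rng.random() < config.ambiguity_rate:
                    if emfs[i] not in decoy_cache:
                        dcounts = _decoy_emf(parse_formula(emfs[i]))
                        decoy_cache[emfs[i]] = hill_formula(dcounts) if dcounts else None
                    demf = decoy_cache[emfs[i]]
                    if demf is not None:
                        decoy_cat = str(rng.choice([c for c in LIPID_CATEGORIES if c != categories[i]]))
                        cands.append(Candidate(demf, k, adducts[i], (decoy_cat,), False))
                rows.append(
                    {
                        "mz": mzs_arr[i] + k * C13_C12,
                        "intensity": base_intensity * ratio**k,
                        "candidates": cands,
                    }
                )
        frame = pd.DataFrame(rows, columns=["mz", "intensity", "candidates"])
        peaklists[sid] = frame.sort_values("mz").reset_index(drop=True)

    # --- ground truth --------------------------------------------------
    truth_rows = []
    for k in range(config.isotopologue_count):
        for i in range(config.n_features):
            truth_rows.append(
                {
                    "feature_id": f"{emfs[i]}|M+{k}|{adducts[i]}",
                    "emf": emfs[i],
                    "imf": k,
                    "adduct": adducts[i],
                    "mz": mzs_arr[i] + k * C13_C12,
                    "category": "multiple" if multi[i] else categories[i],
                    "annotation": annotations[i],
                    "effect_log2fc": effects[i],
                    "differential": bool(abs(effects[i]) > 0),
                }
            )
    features = pd.DataFrame(truth_rows).set_index("feature_id")

    latent_df = pd.DataFrame(
        latent, index=[f"{e}|M+0|{a}" for e, a in zip(emfs, adducts)], columns=sample_ids
    )
    observed_df = pd.DataFrame(observed, index=latent_df.index, columns=sample_ids)
    return Study(config, peaklists, metadata, features, latent_df, observed_df)


def truth_table(study: Study) -> pd.DataFrame:
    """The ground-truth feature table (copy) of a generated study."""
    return study.features.copy()
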