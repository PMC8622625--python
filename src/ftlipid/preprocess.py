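"""Within-sample normalization, log2 transform, and left-censored imputation.

Raw FT-MS intensities are arbitrary units that vary with injection and
acquisition; each sample is normalized by the median intensity over *all*
of its characterized peaks (not only the corresponded or filtered ones).
Missing values are treated as below-detection: for differential-abundance
fold changes they are imputed, per tissue class, at one-half (on the raw
scale) of the lower bound of the pooled log2-intensity distribution of
that class.  Imputed data are used for fold changes and the moderated
linear model only, never for correlation or co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

STAGES = ("raw", "normalized", "log2", "imputed")


def sample_medians(spectra: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Per-sample median intensity over all characterized peaks."""
    meds = {}
    for sid, peaks in spectra.items():
        if len(peaks) == 0:
            raise ValueError(f"sample {sid!r} has no peaks")
        meds[sid] = float(np.median(np.asarray(peaks["intensity"], dtype=float)))
    return pd.Series(meds, name="median_intensity")


def normalize_peaklists(spectra: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Divide every peak intensity by its sample's median peak intensity."""
    meds = sample_medians(spectra)
    out = {}
    for sid, peaks in spectra.items():
        frame = peaks.copy()
        frame["intensity"] = np.asarray(peaks["intensity"], dtype=float) / meds[sid]
        out[sid] = frame
    return out


def median_normalize(values: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    """Normalize a features x samples matrix by per-sample medians.

    ``medians`` must come from the full peak lists (see
    :func:`sample_medians`), so the divisor reflects all characterized
    peaks of the sample, not just the matrix rows.
    """
    missing = set(values.columns) - set(medians.index)
    if missing:
        raise ValueError(f"no median for samples: {sorted(missing)}")
    return values / medians.reindex(values.columns)


def log2_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; missing entries are preserved."""
    arr = values.to_numpy(dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("log2 transform requires strictly positive observed values")
    return np.log2(values)


def impute_missing(
    values: pd.DataFrame,
    classes: pd.Series,
    q: float = 0.025,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Impute missing log2 intensities per tissue class.

    For each class, all observed log2 intensities of that class's samples
    are pooled and the ``q``-quantile ``T`` of the pool taken as the lower
    bound of its distribution; every missing entry in that class is set to
    ``T - 1`` (one-half of the bound on the raw intensity scale).  Returns
    the imputed matrix and the per-class bound ``T`` used.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    classes = classes.reindex(values.columns)
    if classes.isna().any():
        raise ValueError("class labels missing for some samples")
    imputed = values.copy()
    thresholds: dict[str, float] = {}
    for cls in classes.unique():
        cols = classes.index[classes == cls]
        pool = values[cols].to_numpy(dtype=float)
        pool = pool[np.isfinite(pool)]
        if pool.size == 0:
            raise ValueError(f"class {cls!r} has no observed values")
        threshold = float(np.quantile(pool, q))
        thresholds[cls] = threshold
        block = imputed[cols]
        imputed[cols] = block.where(block.notna(), threshold - 1.0)
    return imputed, thresholds


@dataclass
class IntensityMatrix:
    """A features x samples intensity table with an explicit pipeline stage.

    Stage transitions only move forward through
    raw -> normalized -> log2 -> imputed.
    """

    values: pd.DataFrame
    stage: str = "raw"
    meta: pd.DataFrame | None = None
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _advance(self, values: pd.DataFrame, stage: str, **kwargs) -> "IntensityMatrix":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(f"cannot move from stage {self.stage!r} back to {stage!r}")
        return IntensityMatrix(values, stage, self.meta, kwargs.get("thresholds", self.thresholds))

    def normalize(self, medians: pd.Series) -> "IntensityMatrix":
        return self._advance(median_normalize(self.values, medians), "normalized")

    def log2(self) -> "IntensityMatrix":
        return self._advance(log2_transform(self.values), "log2")

    def impute(self, classes: pd.Series, q: float = 0.025) -> "IntensityMatrix":
        if self.stage != "log2":
            raise ValueError("imputation requires the log2 stage")
        imputed, thresholds = impute_missing(self.values, classes, q)
        return self._advance(imputed, "imputed", thresholds=thresholds)
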