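"""End-to-end orchestration: correspondence through enrichment and structure.

``run_pipeline`` executes the full analysis on a directory of assigned
peak lists plus a sample-metadata table, writing every intermediate as
delimited text and a machine-readable JSON report.  The pipeline is a pure
function of its inputs and configuration: identical reruns produce
identical outputs.

``run_table1_check`` is a counts-only entry point: given a universe size,
per-direction significant counts, and per-annotation totals/overlaps, it
computes the category-level enrichment table (expected counts, exact
hypergeometric p-values, per-direction BH adjustment) without any
simulation or cohort data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import correspondence, diffabund, enrichment, icikt, io, preprocess, structure


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults are the analysis' standard settings."""

    input_dir: str | None = None
    out_dir: str = "ftlipid_out"
    tol_ppm: float = 5.0
    min_support: float = 0.5
    min_presence: float = 0.25
    impute_quantile: float = 0.025
    alpha: float = 0.01
    mz_split: float = 700.0
    linkage: str = "average"
    seed: int = 0
    run_qc: bool = True
    run_structure: bool = True
    refilter_after_qc: bool = False

    def validate(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        for name in ("min_support", "min_presence", "impute_quantile", "alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(
    config: PipelineConfig,
    spectra: Mapping[str, pd.DataFrame] | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Run correspondence -> filter -> normalize -> QC -> impute -> tests ->
    enrichment -> structure, writing intermediates and a report bundle.

    ``spectra``/``metadata`` may be passed in memory; otherwise they are
    read from ``config.input_dir``.  Returns the report dictionary (also
    written to ``<out_dir>/report.json``).
    """
    config.validate()
    if spectra is None or metadata is None:
        if config.input_dir is None:
            raise ValueError("no input: provide spectra+metadata or input_dir")
        spectra, metadata = io.read_peaklists(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    report["n_samples_initial"] = int(len(metadata))

    # correspondence
    medians = preprocess.sample_medians(spectra)
    values, annotations = correspondence.build_corresponded_matrix(
        spectra, metadata, config.tol_ppm, config.min_support
    )
    report["n_corresponded_total"] = int(len(values))
    values = correspondence.filter_by_class_presence(values, metadata, config.min_presence)
    annotations = annotations.loc[values.index]
    report["n_corresponded_filtered"] = int(len(values))
    io.write_matrix(values, out / "corresponded_raw.tsv", "raw", tol_ppm=config.tol_ppm)
    annotations.to_csv(out / "feature_annotations.tsv", sep="\t")

    # normalization
    matrix = preprocess.IntensityMatrix(values, "raw", metadata)
    matrix = matrix.normalize(medians).log2()
    io.write_matrix(matrix.values, out / "corresponded_log2.tsv", "log2")

    # QC
    removed: list[str] = []
    if config.run_qc:
        lipid_values = matrix.values.loc[~annotations["excluded"]]
        classes = metadata.set_index("sample_id")["class"]
        qc_stats = icikt.sample_outlier_stats(lipid_values, classes)
        removed, qc_full = icikt.flag_outlier_samples(qc_stats, classes)
        qc_full.to_csv(out / "qc_stats.tsv", sep="\t")
        if removed:
            metadata = metadata[~metadata["sample_id"].isin(removed)].reset_index(drop=True)
            matrix = preprocess.IntensityMatrix(
                matrix.values.drop(columns=removed), matrix.stage, metadata
            )
            if config.refilter_after_qc:
                kept = correspondence.filter_by_class_presence(
                    matrix.values, metadata, config.min_presence
                )
                matrix = preprocess.IntensityMatrix(kept, matrix.stage, metadata)
                annotations = annotations.loc[kept.index]
    report["removed_samples"] = removed
    report["n_samples_after_qc"] = int(len(metadata))

    # imputation
    classes = metadata.set_index("sample_id")["class"]
    imputed = matrix.impute(classes, config.impute_quantile)
    report["impute_thresholds"] = imputed.thresholds
    io.write_matrix(
        imputed.values, out / "corresponded_imputed.tsv", "imputed",
        q=config.impute_quantile, **{f"T_{k}": v for k, v in imputed.thresholds.items()},
    )

    # differential abundance
    model = diffabund.DifferentialAbundanceModel.from_matrices(
        imputed.values, matrix.values, metadata, config.alpha
    )
    results = model.fit()
    table = results.table.join(annotations[["category", "mz"]])
    table.to_csv(out / "differential_results.tsv", sep="\t")
    sig = table["significant"]
    report["n_significant"] = {
        "moderated": int(table["sig_moderated"].sum()),
        "two_part": int(table["sig_two_part"].sum()),
        "union": int(sig.sum()),
        "more_abundant": int((sig & (table["direction"] == "more")).sum()),
        "less_abundant": int((sig & (table["direction"] == "less")).sum()),
    }

    # enrichment over the singly categorized universe
    ann_table = enrichment.annotate_categories(annotations, config.mz_split)
    enrich = enrichment.enrichment_table(results.table, ann_table, config.alpha)
    enrich.to_csv(out / "enrichment_table.tsv", sep="\t")
    report["enrichment"] = {
        ann: {col: enrich.loc[ann, col] for col in enrich.columns}
        for ann in enrich.index
    }

    # structure analyses
    if config.run_structure:
        pca = structure.pca_scores(matrix.values, n_components=3)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        report["pca_variance_ratio"] = [float(v) for v in pca.variance_ratio]
        cooc = structure.cooccurrence_matrix(matrix.values)
        io.write_matrix(cooc, out / "cooccurrence.tsv", "cooccurrence")
        sample_cor = icikt.correlation_matrix(matrix.values, axis="samples")
        io.write_matrix(sample_cor, out / "sample_correlation.tsv", "ici_kendall_tau")
        st_features = annotations.index[annotations["category"] == "ST"]
        cancer_ids = metadata.loc[metadata["class"] == "cancer", "sample_id"]
        if len(st_features) >= 2 and len(cancer_ids) >= 2:
            subgroups = structure.subgroup_samples(
                matrix.values.loc[st_features, cancer_ids], k=2, method=config.linkage
            )
            subgroups.to_csv(out / "sterol_subgroups.tsv", sep="\t")
            report["sterol_subgroup_sizes"] = (
                subgroups.value_counts().sort_index().astype(int).to_dict()
            )
            if "statin" in metadata.columns and subgroups.nunique() == 2:
                statin = metadata.set_index("sample_id").loc[subgroups.index, "statin"]
                contingency = pd.crosstab(statin, subgroups)
                if contingency.shape == (2, 2) and (contingency.sum(0) > 0).all() and (
                    contingency.sum(1) > 0
                ).all():
                    stat, df, p = structure.chi_squared_2x2(contingency.to_numpy())
                    report["statin_chi2"] = {"statistic": stat, "df": df, "p_value": p}

    report = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_table1_check(counts: dict | str | Path | None = None) -> pd.DataFrame:
    """Category-enrichment table directly from printed counts.

    ``counts`` may be a mapping (or YAML/JSON file) with keys ``universe``,
    ``K_more``, ``K_less`` and ``annotations`` (annotation -> [total,
    observed_more, observed_less]); ``None`` uses the packaged NSCLC cohort
    counts.
    """
    if counts is None:
        counts = enrichment.NSCLC_TABLE1
    elif isinstance(counts, (str, Path)):
        with open(counts) as fh:
            counts = yaml.safe_load(fh)
    try:
        annotations = {a: tuple(v) for a, v in counts["annotations"].items()}
        return enrichment.enrichment_from_counts(
            int(counts["universe"]), int(counts["K_more"]), int(counts["K_less"]), annotations
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed counts input: {exc}") from exc
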