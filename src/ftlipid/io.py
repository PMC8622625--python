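"""Delimited-text I/O for peak lists, metadata, and intensity matrices.

Peak-list files are tab-separated with columns ``mz``, ``intensity`` and
``assignments``; the assignment list serializes each candidate as
``EMF|imf|adduct|cat1,cat2|multi`` with candidates joined by ``;``.
Intensity matrices are tab-separated features x samples tables where an
empty cell means missing; ``#``-prefixed header comments record stage
parameters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .correspondence import Candidate


def _serialize_candidates(cands) -> str:
    return ";".join(
        f"{c.emf}|{c.imf}|{c.adduct}|{','.join(c.categories)}|{int(c.multi)}" for c in cands
    )


def _parse_candidates(text: str) -> list[Candidate]:
    out = []
    for item in text.split(";"):
        emf, imf, adduct, cats, multi = item.split("|")
        out.append(Candidate(emf, int(imf), adduct, tuple(cats.split(",")), bool(int(multi))))
    return out


def write_peaklists(study, directory: str | Path) -> list[Path]:
    """Write one peak-list file per sample plus metadata and ground truth.

    Returns the list of written paths.  Round-trippable with
    :func:`read_peaklists`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, peaks in study.peaklists.items():
        path = directory / f"{sid}.tsv"
        frame = pd.DataFrame(
            {
                "mz": peaks["mz"],
                "intensity": peaks["intensity"],
                "assignments": [_serialize_candidates(c) for c in peaks["candidates"]],
            }
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    meta_path = directory / "metadata.tsv"
    study.metadata.to_csv(meta_path, sep="\t", index=False)
    written.append(meta_path)
    truth_path = directory / "ground_truth.tsv"
    study.features.to_csv(truth_path, sep="\t", float_format="%.10g")
    written.append(truth_path)
    return written


def read_peaklists(directory: str | Path) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Read a directory written by :func:`write_peaklists`.

    Returns ``(peaklists, metadata)``; ground truth, if present, is ignored
    here (the analysis never sees it).
    """
    directory = Path(directory)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t")
    peaklists: dict[str, pd.DataFrame] = {}
    for sid in metadata["sample_id"]:
        path = directory / f"{sid}.tsv"
        frame = pd.read_csv(path, sep="\t")
        if len(frame) == 0:
            peaklists[sid] = pd.DataFrame(columns=["mz", "intensity", "candidates"])
            continue
        frame["candidates"] = [_parse_candidates(a) for a in frame.pop("assignments")]
        peaklists[sid] = frame[["mz", "intensity", "candidates"]]
    return peaklists, metadata


def write_matrix(values: pd.DataFrame, path: str | Path, stage: str, **params) -> Path:
    """Write an intensity matrix with stage/parameter header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        for key, value in params.items():
            fh.write(f"# {key}: {value}\n")
        values.to_csv(fh, sep="\t", float_format="%.10g")
    return path


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a matrix written by :func:`write_matrix`."""
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            header[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        values = pd.read_csv(fh, sep="\t", index_col=0)
    return values, header
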