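"""Readers and writers for the pipeline's plain-text artifacts.

All tabular artifacts are TSV with a header; matrices and metadata are
JSON.  Readers validate at the boundary (required columns, unique subject
IDs, NEO score range 0–48, matching region labels, equal timepoint counts)
and raise with row-level diagnostics.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import AssociationResult
from .modes import REGION_LABELS, EngagementMatrix, ROITimeSeriesSet
from .profiles import FACTOR_COLUMNS, PersonalityTable, ProfileLoadings

__all__ = [
    "read_personality_table",
    "write_personality_table",
    "read_timeseries_dir",
    "write_timeseries_dir",
    "write_json",
    "read_json",
    "write_association",
]

_REQUIRED_COLUMNS = ["subject_id", "family_id", "zygosity", "gender", *FACTOR_COLUMNS]


def read_personality_table(path: str | Path) -> PersonalityTable:
    """Read and validate a personality TSV (see write_personality_table)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "family_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df.loc[df["subject_id"].duplicated(), "subject_id"]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject_id(s) {dup.tolist()}")
    scores = df[FACTOR_COLUMNS]
    if scores.isna().any().any():
        rows = scores.index[scores.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing scores in row(s) {rows}")
    out_of_range = (scores < 0) | (scores > 48)
    if out_of_range.any().any():
        rows = scores.index[out_of_range.any(axis=1)].tolist()
        raise ValueError(
            f"{path}: NEO-FFI domain scores must lie in [0, 48]; "
            f"offending row(s) {rows}"
        )
    return PersonalityTable(df)


def write_personality_table(table: PersonalityTable, path: str | Path) -> None:
    cols = [c for c in _REQUIRED_COLUMNS if c in table.frame.columns]
    extra = [c for c in table.frame.columns if c not in cols]
    table.frame[cols + extra].to_csv(path, sep="\t", index=False)


def write_timeseries_dir(ts: ROITimeSeriesSet, directory: str | Path) -> None:
    """One TSV per subject (header = region labels), named <subject_id>.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(ts.subject_ids):
        pd.DataFrame(ts.data[i], columns=ts.region_labels).to_csv(
            directory / f"{sid}.tsv", sep="\t", index=False
        )


def read_timeseries_dir(
    directory: str | Path,
    subject_ids: Sequence[str],
    region_labels: Sequence[str] = tuple(REGION_LABELS),
) -> ROITimeSeriesSet:
    """Read per-subject TSVs in the given subject order, validating labels.

    Extra files in the directory are ignored with a warning; a missing
    subject file, a label mismatch, or unequal timepoint counts is an error.
    """
    directory = Path(directory)
    region_labels = list(region_labels)
    mats = []
    for sid in subject_ids:
        f = directory / f"{sid}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"no time-series file for subject {sid}: {f}")
        df = pd.read_csv(f, sep="\t")
        if list(df.columns) != region_labels:
            raise ValueError(
                f"{f}: region labels {list(df.columns)} do not match "
                f"expected {region_labels}"
            )
        mats.append(df.to_numpy(dtype=float))
    lengths = {m.shape[0] for m in mats}
    if len(lengths) > 1:
        raise ValueError(f"unequal timepoint counts across subjects: {sorted(lengths)}")
    known = {f"{sid}.tsv" for sid in subject_ids}
    extra = sorted(p.name for p in directory.glob("*.tsv") if p.name not in known)
    if extra:
        warnings.warn(f"ignoring unlisted time-series file(s): {extra}", UserWarning)
    return ROITimeSeriesSet(
        subject_ids=list(subject_ids),
        data=np.stack(mats),
        region_labels=region_labels,
    )


def write_json(obj, path: str | Path) -> None:
    """Serialize any object exposing to_dict() (or a plain dict) as JSON."""
    d = obj.to_dict() if hasattr(obj, "to_dict") else obj
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_association(result: AssociationResult, base: str | Path) -> None:
    """Write an AssociationResult as both TSV (60 rows) and JSON."""
    base = Path(base)
    result.to_frame().to_csv(base.with_suffix(".tsv"), sep="\t", index=False)
    write_json(result, base.with_suffix(".json"))


def write_loadings(loadings: ProfileLoadings, path: str | Path) -> None:
    loadings.to_frame().to_csv(path, sep="\t", index=False)


def write_engagement(engagement: EngagementMatrix, path: str | Path) -> None:
    engagement.to_frame().to_csv(path, sep="\t", index=False)
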