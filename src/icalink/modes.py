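"""Temporal functional modes from ROI time series, and per-subject engagement.

Per-subject mean time series from twelve regions of interest are z-scored
within subject, concatenated along time across subjects, and decomposed by
full-rank temporal ICA (time as samples, regions as channels).  Each
resulting "temporal mode" is a spatial weight pattern over the regions with
an associated maximally independent time course.  Projecting a subject's
(standardized) series through the mode unmixing gives subject-specific mode
time series; the sample variance of each is that subject's "engagement" of
the mode — the scalar summary carried into the brain–behavior association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ica import ICADecomposition, center_and_scale, fastica

__all__ = [
    "REGION_LABELS",
    "ROITimeSeriesSet",
    "TemporalModeSet",
    "EngagementMatrix",
    "standardize_timeseries",
    "roi_correlation_matrix",
    "derive_temporal_modes",
    "project_mode_timeseries",
    "compute_engagement",
    "engagement_from_set",
]

REGION_LABELS = [
    "L_amygdala",
    "R_amygdala",
    "L_hippocampus",
    "R_hippocampus",
    "sgACC",
    "mPFC",
    "dACC",
    "PCC",
    "PCu",
    "dlPFC",
    "insula",
    "OFC",
]


@dataclass
class ROITimeSeriesSet:
    """Aligned per-subject (timepoints × regions) matrices.

    All subjects share the region labels/order and the timepoint count
    (required for balanced concatenation before group ICA).
    """

    subject_ids: list[str]
    data: np.ndarray  # (n_subjects, T, n_regions)
    region_labels: list[str] = field(default_factory=lambda: list(REGION_LABELS))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (subjects, timepoints, regions), got {self.data.shape}")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("data first axis must align with subject_ids")
        if self.data.shape[2] != len(self.region_labels):
            raise ValueError("data last axis must align with region_labels")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain missing or non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_regions(self) -> int:
        return self.data.shape[2]

    def subset(self, indices: Sequence[int]) -> "ROITimeSeriesSet":
        idx = list(indices)
        return ROITimeSeriesSet(
            subject_ids=[self.subject_ids[i] for i in idx],
            data=self.data[idx].copy(),
            region_labels=list(self.region_labels),
        )

    def drop_subject(self, index: int) -> "ROITimeSeriesSet":
        keep = [i for i in range(self.n_subjects) if i != index]
        return self.subset(keep)


@dataclass
class TemporalModeSet:
    """Temporal modes: spatial weights plus the training transforms.

    ``spatial_weights`` is (modes × regions) in canonical sign/order.
    Projection of a subject applies, in order: within-subject per-region
    z-scoring, the group standardization learned at training time, then
    the mode unmixing.
    """

    spatial_weights: np.ndarray  # (k, n_regions)
    unmixing: np.ndarray  # (k, n_regions)
    group_means: np.ndarray  # (n_regions,)
    group_sds: np.ndarray  # (n_regions,)
    region_labels: list[str]
    decomposition: ICADecomposition | None = None

    @property
    def n_modes(self) -> int:
        return self.spatial_weights.shape[0]

    @property
    def converged(self) -> bool:
        return True if self.decomposition is None else self.decomposition.converged

    def to_dict(self) -> dict:
        d = {
            "spatial_weights": self.spatial_weights.tolist(),
            "unmixing": self.unmixing.tolist(),
            "group_means": self.group_means.tolist(),
            "group_sds": self.group_sds.tolist(),
            "region_labels": self.region_labels,
        }
        if self.decomposition is not None:
            d["provenance"] = {
                "seed": int(self.decomposition.seed),
                "tol": float(self.decomposition.tol),
                "n_iterations": int(self.decomposition.n_iterations),
                "converged": bool(self.decomposition.converged),
                "nonlinearity": self.decomposition.nonlinearity,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TemporalModeSet":
        return cls(
            spatial_weights=np.asarray(d["spatial_weights"], float),
            unmixing=np.asarray(d["unmixing"], float),
            group_means=np.asarray(d["group_means"], float),
            group_sds=np.asarray(d["group_sds"], float),
            region_labels=list(d["region_labels"]),
        )


@dataclass
class EngagementMatrix:
    """Subjects × modes variance-of-mode-time-series (all entries ≥ 0)."""

    subject_ids: list[str]
    values: np.ndarray  # (n, k)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("engagement rows must align with subject_ids")
        if (self.values < 0).any():
            raise ValueError("engagement (a variance) cannot be negative")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.values, columns=[f"mode_{m + 1}" for m in range(self.values.shape[1])]
        )
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _standardize_subject(mat: np.ndarray, subject_id: str, labels: Sequence[str]) -> np.ndarray:
    sds = mat.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance region(s) {[labels[i] for i in bad]} in subject {subject_id}"
        )
    return (mat - mat.mean(axis=0)) / sds


def standardize_timeseries(ts: ROITimeSeriesSet) -> ROITimeSeriesSet:
    """Z-score each region's series within each subject (sample SD, n−1).

    Removes between-subject amplitude differences so the group ICA models
    co-activation structure rather than global signal scale.
    """
    out = np.empty_like(ts.data)
    for i, sid in enumerate(ts.subject_ids):
        out[i] = _standardize_subject(ts.data[i], sid, ts.region_labels)
    return ROITimeSeriesSet(
        subject_ids=list(ts.subject_ids), data=out, region_labels=list(ts.region_labels)
    )


def roi_correlation_matrix(ts: ROITimeSeriesSet) -> np.ndarray:
    """Region × region Pearson correlations of the group-concatenated series."""
    if ts.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    std = standardize_timeseries(ts)
    flat = std.data.reshape(-1, std.n_regions)
    return np.corrcoef(flat, rowvar=False)


def derive_temporal_modes(
    ts: ROITimeSeriesSet,
    nonlinearity: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> TemporalModeSet:
    """Full-rank temporal ICA on the concatenated standardized series.

    Subjects are z-scored within subject, concatenated along time, the
    concatenated matrix is standardized once more at the group level (the
    stored group transform), and ICA with as many components as regions is
    run with time as the sample dimension.
    """
    std = standardize_timeseries(ts)
    flat = std.data.reshape(-1, std.n_regions)
    Z, means, sds = center_and_scale(flat, ts.region_labels)
    dec = fastica(
        Z,
        n_components=std.n_regions,
        nonlinearity=nonlinearity,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
    )
    return TemporalModeSet(
        spatial_weights=dec.mixing.T.copy(),
        unmixing=dec.unmixing.copy(),
        group_means=means,
        group_sds=sds,
        region_labels=list(ts.region_labels),
        decomposition=dec,
    )


def project_mode_timeseries(
    subject_ts: np.ndarray,
    modes: TemporalModeSet,
    region_labels: Sequence[str] | None = None,
    subject_id: str = "?",
) -> np.ndarray:
    """Subject (T × regions) series → (T × modes) mode time series.

    Applies within-subject z-scoring, the training group standardization,
    then the mode unmixing.  For a training subject this reproduces that
    subject's rows of the group ICA source series to machine precision.
    """
    if region_labels is not None and list(region_labels) != list(modes.region_labels):
        raise ValueError(
            f"region labels do not match training: {list(region_labels)} "
            f"vs {modes.region_labels}"
        )
    mat = np.asarray(subject_ts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(modes.region_labels):
        raise ValueError(f"expected (T, {len(modes.region_labels)}) matrix, got {mat.shape}")
    Z = _standardize_subject(mat, subject_id, modes.region_labels)
    Z = (Z - modes.group_means) / modes.group_sds
    return Z @ modes.unmixing.T


def compute_engagement(
    mode_ts: Sequence[np.ndarray] | np.ndarray,
    subject_ids: Sequence[str] | None = None,
) -> EngagementMatrix:
    """Per-subject, per-mode sample variance (denominator n−1) of mode series."""
    arrays = [np.asarray(m, dtype=float) for m in mode_ts]
    if any(a.shape[0] < 2 for a in arrays):
        raise ValueError("need at least 2 timepoints to compute a variance")
    values = np.stack([a.var(axis=0, ddof=1) for a in arrays])
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(arrays))]
    return EngagementMatrix(subject_ids=list(subject_ids), values=values)


def engagement_from_set(ts: ROITimeSeriesSet, modes: TemporalModeSet) -> EngagementMatrix:
    """Project every subject in the set and summarize as engagement."""
    series = [
        project_mode_timeseries(ts.data[i], modes, ts.region_labels, ts.subject_ids[i])
        for i in range(ts.n_subjects)
    ]
    return compute_engagement(series, ts.subject_ids)
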