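"""Reproducibility machinery: leave-one-out, split-half, and out-of-sample tests.

Three complementary checks of the two ICA decompositions:

* leave-one-out stability — re-derive the decomposition with each subject
  removed (normalization included), align components to the full-sample
  solution, and report the mean ± SD matched absolute correlation per
  component;
* split-half stability — the same over random half-splits that never
  separate members of a family, reporting both half-vs-full and
  half-vs-half agreement;
* out-of-sample projection association — for each fold, learn profiles and
  temporal modes without the held-out subjects, project the held-out
  subjects onto both, and run the family-aware association on the purely
  out-of-sample (loading, engagement) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .association import AssociationResult, run_association
from .ica import match_components
from .modes import (
    ROITimeSeriesSet,
    TemporalModeSet,
    compute_engagement,
    derive_temporal_modes,
    project_mode_timeseries,
)
from .profiles import PersonalityTable, ProfileSet, derive_profiles, project_subjects

__all__ = [
    "ReproducibilityReport",
    "loo_stability",
    "split_half_stability",
    "loo_projection_association",
    "align_profiles",
    "align_modes",
]


@dataclass
class ReproducibilityReport:
    """Per-component stability summary of a resampling scheme."""

    scheme: str  # "loo" | "split-half"
    component_mean: np.ndarray  # (k,) mean matched |r| vs the full solution
    component_sd: np.ndarray  # (k,)
    n_folds: int
    seed: int | None = None
    half_vs_half_mean: np.ndarray | None = None
    half_vs_half_sd: np.ndarray | None = None
    n_excluded: int = 0

    def __post_init__(self):
        if ((self.component_mean < 0) | (self.component_mean > 1 + 1e-12)).any():
            raise ValueError("matched correlations must lie in [0, 1]")
        if (self.component_sd < 0).any():
            raise ValueError("SDs must be non-negative")

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "component_mean": self.component_mean.tolist(),
            "component_sd": self.component_sd.tolist(),
            "n_folds": int(self.n_folds),
            "seed": self.seed,
            "n_excluded": int(self.n_excluded),
        }
        if self.half_vs_half_mean is not None:
            d["half_vs_half_mean"] = self.half_vs_half_mean.tolist()
            d["half_vs_half_sd"] = self.half_vs_half_sd.tolist()
        return d

    def summary(self) -> str:
        lines = [f"{self.scheme} stability over {self.n_folds} folds"]
        for j, (m, s) in enumerate(zip(self.component_mean, self.component_sd)):
            lines.append(f"  component {j + 1}: |r| = {m:.3f} ± {s:.3f}")
        if self.half_vs_half_mean is not None:
            lines.append("  half-vs-half:")
            for j, (m, s) in enumerate(zip(self.half_vs_half_mean, self.half_vs_half_sd)):
                lines.append(f"    component {j + 1}: |r| = {m:.3f} ± {s:.3f}")
        return "\n".join(lines)


def _weights(fitted) -> np.ndarray:
    """(p, k) columns-as-components weight matrix of a fitted decomposition."""
    if isinstance(fitted, ProfileSet):
        return fitted.weights.T
    if isinstance(fitted, TemporalModeSet):
        return fitted.spatial_weights.T
    if hasattr(fitted, "mixing"):
        return np.asarray(fitted.mixing, dtype=float)
    raise TypeError(f"cannot extract component weights from {type(fitted)!r}")


def _converged(fitted) -> bool:
    return getattr(fitted, "converged", True)


def _call_deriver(deriver, data):
    out = deriver(data)
    return out[0] if isinstance(out, tuple) else out


def loo_stability(data, deriver, reference=None) -> ReproducibilityReport:
    """Leave-one-subject-out stability of a decomposition.

    ``deriver`` maps a data object (PersonalityTable or ROITimeSeriesSet,
    anything with ``n_subjects``/``drop_subject``) to a fitted
    decomposition, normalization included.  Every fold is aligned to the
    full-sample solution with Hungarian matching; non-convergent folds are
    excluded with a warning.
    """
    n = data.n_subjects
    if n < 20:
        raise ValueError(f"need at least 20 subjects for leave-one-out, got {n}")
    full = _call_deriver(deriver, data) if reference is None else reference
    ref_W = _weights(full)
    per_fold = []
    n_excluded = 0
    for i in range(n):
        fold = _call_deriver(deriver, data.drop_subject(i))
        if not _converged(fold):
            warnings.warn(f"fold {i}: ICA did not converge; fold excluded", UserWarning)
            n_excluded += 1
            continue
        _, _, rs = match_components(ref_W, _weights(fold))
        per_fold.append(rs)
    M = np.asarray(per_fold)
    return ReproducibilityReport(
        scheme="loo",
        component_mean=M.mean(axis=0),
        component_sd=M.std(axis=0, ddof=1),
        n_folds=len(per_fold),
        n_excluded=n_excluded,
    )


def _block_respecting_halves(
    n: int, blocks: list[np.ndarray] | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split that never separates a block (greedy balance)."""
    if blocks is None:
        blocks = [np.array([i]) for i in range(n)]
    order = rng.permutation(len(blocks))
    h1, h2 = [], []
    for bi in order:
        (h1 if len(h1) <= len(h2) else h2).extend(blocks[bi].tolist())
    return np.asarray(sorted(h1)), np.asarray(sorted(h2))


def split_half_stability(
    data, deriver, n_splits: int = 20, seed: int = 0, blocks=None
) -> ReproducibilityReport:
    """Split-half stability; family blocks never straddle the two halves."""
    n = data.n_subjects
    if n < 40:
        raise ValueError(f"need at least 40 subjects for split-half, got {n}")
    if blocks is not None and hasattr(blocks, "blocks"):
        blocks = blocks.blocks()
    full = _call_deriver(deriver, data)
    ref_W = _weights(full)
    rng = np.random.default_rng(seed)
    vs_full, vs_other = [], []
    n_excluded = 0
    for _ in range(n_splits):
        h1, h2 = _block_respecting_halves(n, blocks, rng)
        f1 = _call_deriver(deriver, data.subset(h1))
        f2 = _call_deriver(deriver, data.subset(h2))
        if not (_converged(f1) and _converged(f2)):
            warnings.warn("split with non-convergent ICA excluded", UserWarning)
            n_excluded += 1
            continue
        W1, W2 = _weights(f1), _weights(f2)
        _, _, r1 = match_components(ref_W, W1)
        _, _, r2 = match_components(ref_W, W2)
        vs_full.append(r1)
        vs_full.append(r2)
        _, _, r12 = match_components(W1, W2)
        vs_other.append(r12)
    F = np.asarray(vs_full)
    H = np.asarray(vs_other)
    return ReproducibilityReport(
        scheme="split-half",
        component_mean=F.mean(axis=0),
        component_sd=F.std(axis=0, ddof=1),
        n_folds=n_splits - n_excluded,
        seed=seed,
        half_vs_half_mean=H.mean(axis=0),
        half_vs_half_sd=H.std(axis=0, ddof=1),
        n_excluded=n_excluded,
    )


def align_profiles(fold: ProfileSet, reference: ProfileSet) -> ProfileSet:
    """Reorder/sign-flip a fold's profiles to match the reference solution."""
    perm, signs, _ = match_components(reference.weights.T, fold.weights.T)
    return replace(
        fold,
        weights=fold.weights[perm] * signs[:, None],
        unmixing=fold.unmixing[perm] * signs[:, None],
    )


def align_modes(fold: TemporalModeSet, reference: TemporalModeSet) -> TemporalModeSet:
    """Reorder/sign-flip a fold's temporal modes to match the reference."""
    perm, signs, _ = match_components(
        reference.spatial_weights.T, fold.spatial_weights.T
    )
    return replace(
        fold,
        spatial_weights=fold.spatial_weights[perm] * signs[:, None],
        unmixing=fold.unmixing[perm] * signs[:, None],
    )


def _grouped_folds(
    n: int, n_folds: int | None, blocks: list[np.ndarray] | None
) -> list[np.ndarray]:
    """Partition subjects into folds; families never straddle folds."""
    if blocks is None:
        blocks = [np.array([i]) for i in range(n)]
    if n_folds is None:  # strict LOO over subjects
        return [np.array([i]) for i in range(n)]
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for b in blocks:
        smallest = min(range(n_folds), key=lambda j: len(folds[j]))
        folds[smallest].extend(b.tolist())
    return [np.asarray(sorted(f)) for f in folds if f]


def loo_projection_association(
    table: PersonalityTable,
    ts: ROITimeSeriesSet,
    blocks,
    covariates: np.ndarray | None,
    n_folds: int | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
    ica_seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> AssociationResult:
    """Out-of-sample association between projected loadings and engagement.

    For every fold, both decompositions are learned without the held-out
    subjects (normalization included), aligned to the full-sample reference
    so loadings are comparable across folds, and the held-out subjects are
    projected.  The assembled out-of-sample (loading, engagement) pairs are
    then fed to the family-aware association.  ``n_folds=None`` is strict
    leave-one-subject-out; an integer gives the faster grouped (leave-k-out)
    approximation with families kept intact within a fold.
    """
    n = table.n_subjects
    if n < 30:
        raise ValueError(f"need at least 30 subjects, got {n}")
    if ts.n_subjects != n or ts.subject_ids != table.subject_ids:
        raise ValueError("personality table and time-series set are misaligned")
    block_list = blocks.blocks() if hasattr(blocks, "blocks") else [
        np.asarray(b, dtype=np.intp) for b in blocks
    ]

    ref_profiles, _ = derive_profiles(table, seed=ica_seed, tol=tol, max_iter=max_iter)
    ref_modes = derive_temporal_modes(ts, seed=ica_seed, tol=tol, max_iter=max_iter)

    oos_loadings = np.empty((n, 5))
    oos_engagement = np.empty((n, ts.n_regions))
    for fold in _grouped_folds(n, n_folds, block_list):
        train = np.setdiff1d(np.arange(n), fold)
        # training never touches held-out subjects (including normalization)
        fold_profiles, _ = derive_profiles(
            table.subset(train), seed=ica_seed, tol=tol, max_iter=max_iter
        )
        fold_modes = derive_temporal_modes(
            ts.subset(train), seed=ica_seed, tol=tol, max_iter=max_iter
        )
        fold_profiles = align_profiles(fold_profiles, ref_profiles)
        fold_modes = align_modes(fold_modes, ref_modes)
        held_table = table.subset(fold)
        oos_loadings[fold] = project_subjects(held_table, fold_profiles).values
        series = [
            project_mode_timeseries(ts.data[i], fold_modes, ts.region_labels, ts.subject_ids[i])
            for i in fold
        ]
        oos_engagement[fold] = compute_engagement(
            series, [ts.subject_ids[i] for i in fold]
        ).values

    return run_association(
        oos_engagement,
        oos_loadings,
        covariates,
        block_list,
        n_perm=n_perm,
        seed=seed,
        q=q,
    )
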