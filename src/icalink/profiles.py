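"""Independent personality profiles from five-factor (NEO-FFI) scores.

The five NEO-FFI domain scores — neuroticism (N), extraversion (E),
openness/intellect (O), agreeableness (A), conscientiousness (C) — are
empirically correlated.  Running full-rank ICA on the z-scored factor
columns (subjects as samples) yields five statistically independent
"personality profiles", each a weight vector over the original factors,
together with a per-subject loading on every profile.  The training
standardization parameters are retained so held-out subjects can be
projected onto the same profiles, which is what makes leave-one-out
validation well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ica import ICADecomposition, center_and_scale, fastica

__all__ = [
    "FACTOR_COLUMNS",
    "PersonalityTable",
    "ProfileSet",
    "ProfileLoadings",
    "factor_correlations",
    "derive_profiles",
    "project_subjects",
]

FACTOR_COLUMNS = ["N", "E", "O", "A", "C"]
META_COLUMNS = ["subject_id", "family_id", "zygosity", "gender"]


@dataclass
class PersonalityTable:
    """Subjects × five-factor scores plus subject/family/gender metadata."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("subject_id", "gender", *FACTOR_COLUMNS) if c not in self.frame.columns]
        if missing:
            raise ValueError(f"personality table missing column(s): {missing}")
        if self.frame["subject_id"].duplicated().any():
            dups = self.frame.loc[self.frame["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_id(s): {dups}")
        if self.frame[FACTOR_COLUMNS].isna().any().any():
            raise ValueError("missing factor scores")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].astype(str).tolist()

    def scores(self) -> np.ndarray:
        """(n, 5) factor score matrix in N, E, O, A, C order."""
        return self.frame[FACTOR_COLUMNS].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int]) -> "PersonalityTable":
        return PersonalityTable(self.frame.iloc[list(indices)].reset_index(drop=True))

    def drop_subject(self, index: int) -> "PersonalityTable":
        keep = [i for i in range(self.n_subjects) if i != index]
        return self.subset(keep)


@dataclass
class ProfileSet:
    """Five personality profiles: factor weights plus the training transform.

    ``weights`` is (5 profiles × 5 factors): row k holds profile k's loading
    onto N, E, O, A, C (the mixing matrix transposed, canonical sign/order).
    ``unmixing`` maps standardized scores to loadings; ``means``/``sds`` are
    the training standardization parameters applied before projection.
    """

    weights: np.ndarray  # (5, 5) profile x factor
    unmixing: np.ndarray  # (5, 5)
    means: np.ndarray  # (5,)
    sds: np.ndarray  # (5,)
    decomposition: ICADecomposition | None = None
    factor_names: list[str] = field(default_factory=lambda: list(FACTOR_COLUMNS))

    @property
    def n_profiles(self) -> int:
        return self.weights.shape[0]

    @property
    def converged(self) -> bool:
        return True if self.decomposition is None else self.decomposition.converged

    def to_dict(self) -> dict:
        d = {
            "weights": self.weights.tolist(),
            "unmixing": self.unmixing.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "factor_names": self.factor_names,
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
    def from_dict(cls, d: dict) -> "ProfileSet":
        return cls(
            weights=np.asarray(d["weights"], float),
            unmixing=np.asarray(d["unmixing"], float),
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            factor_names=list(d.get("factor_names", FACTOR_COLUMNS)),
        )


@dataclass
class ProfileLoadings:
    """Per-subject loadings on the five profiles, aligned to subject IDs."""

    subject_ids: list[str]
    values: np.ndarray  # (n, 5)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("loadings rows must align with subject_ids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"profile_{k + 1}" for k in range(self.values.shape[1])]
        )
        df.insert(0, "subject_id", self.subject_ids)
        return df


def factor_correlations(table: PersonalityTable) -> pd.DataFrame:
    """Full 5×5 Pearson correlation matrix of the factor columns."""
    X = table.scores()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects for correlations")
    if (X.std(axis=0) == 0).any():
        bad = [FACTOR_COLUMNS[i] for i in np.flatnonzero(X.std(axis=0) == 0)]
        raise ValueError(f"constant factor column(s): {bad}")
    R = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(R, index=FACTOR_COLUMNS, columns=FACTOR_COLUMNS)


def derive_profiles(
    table: PersonalityTable,
    nonlinearity: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> tuple[ProfileSet, ProfileLoadings]:
    """Full-rank ICA on z-scored factor scores → five personality profiles.

    Returns the ProfileSet (weights + training transform + provenance) and
    the training subjects' loadings.  With fewer than 10 subjects per
    factor a warning is emitted (ICA estimates become unstable).
    """
    import warnings as _warnings

    if table.n_subjects < 10 * len(FACTOR_COLUMNS):
        _warnings.warn(
            f"only {table.n_subjects} subjects for 5 factors; "
            "profile estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    Z, means, sds = center_and_scale(table.scores(), FACTOR_COLUMNS)
    dec = fastica(
        Z, n_components=5, nonlinearity=nonlinearity, tol=tol, max_iter=max_iter, seed=seed
    )
    profiles = ProfileSet(
        weights=dec.mixing.T.copy(),
        unmixing=dec.unmixing.copy(),
        means=means,
        sds=sds,
        decomposition=dec,
    )
    loadings = ProfileLoadings(subject_ids=table.subject_ids, values=dec.sources.copy())
    return profiles, loadings


def project_subjects(table: PersonalityTable, profiles: ProfileSet) -> ProfileLoadings:
    """Project (possibly held-out) subjects onto an existing ProfileSet.

    Uses the TRAINING standardization parameters, so a single held-out
    subject is projectable; on the training table itself this reproduces
    the training loadings to machine precision.
    """
    missing = [c for c in profiles.factor_names if c not in table.frame.columns]
    if missing:
        raise ValueError(f"table lacks factor column(s): {missing}")
    X = table.frame[profiles.factor_names].to_numpy(dtype=float)
    Z = (X - profiles.means) / profiles.sds
    return ProfileLoadings(subject_ids=table.subject_ids, values=Z @ profiles.unmixing.T)
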