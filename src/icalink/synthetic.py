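"""Synthetic personality scores and ROI time series with planted ground truth.

The generator emulates the structure of a twin-cohort resting-state study:

* five NEO-FFI domain scores per subject, produced by mixing independent
  non-Gaussian latent "profile" sources through a known 5×5 matrix;
* twelve region-of-interest (ROI) time series per subject, produced by
  mixing independent heavy-tailed latent "mode" time series through a known
  12×12 spatial matrix, with subject-varying mode variances;
* a planted linear coupling between a chosen profile's subject loading and
  the log-variance ("engagement") of a chosen mode;
* family blocks (singletons, monozygotic and dizygotic twin pairs) whose
  members have correlated personality sources, and gender labels.

Everything downstream — both ICA decompositions, engagement, the
family-aware permutation association and the reproducibility machinery —
is testable against the planted quantities.  All randomness flows from the
single seed in :class:`SimulationConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .modes import REGION_LABELS, ROITimeSeriesSet
from .profiles import FACTOR_COLUMNS, PersonalityTable

__all__ = [
    "GroundTruth",
    "FamilyStructure",
    "SimulationConfig",
    "random_ground_truth",
    "simulate_families",
    "simulate_personality",
    "simulate_roi_timeseries",
    "simulate_study",
]

# NEO-FFI domain means and SDs of the emulated cohort (healthy young adults).
NEO_MEANS = {"N": 16.4, "E": 30.6, "O": 28.1, "A": 32.1, "C": 34.8}
NEO_SDS = {"N": 7.15, "E": 6.12, "O": 6.11, "A": 4.89, "C": 5.73}

# Within-pair sharing of latent personality sources (heritability-flavored
# conventional defaults; they make the family-block permutations consequential).
MZ_SHARE = 0.8
DZ_SHARE = 0.5

_COND_LIMIT = 1e8


@dataclass
class GroundTruth:
    """Planted generative parameters, kept for parameter-recovery tests.

    coupling_pairs uses 0-based (profile_index, mode_index, rho) triples;
    rho is the correlation between the profile's latent source and the
    log-engagement of the mode, across subjects.
    """

    profile_mixing: np.ndarray  # (5, 5) latent profile -> factor weights
    spatial_mixing: np.ndarray  # (12, 12) latent mode -> ROI weights
    coupling_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    source_family: str = "exponential"
    seed: int = 0

    def __post_init__(self):
        self.profile_mixing = np.asarray(self.profile_mixing, dtype=float)
        self.spatial_mixing = np.asarray(self.spatial_mixing, dtype=float)
        for name, M, size in (
            ("profile_mixing", self.profile_mixing, 5),
            ("spatial_mixing", self.spatial_mixing, 12),
        ):
            if M.shape != (size, size):
                raise ValueError(f"{name} must be {size}x{size}, got {M.shape}")
            if np.linalg.cond(M) > _COND_LIMIT:
                raise ValueError(
                    f"{name} is rank deficient (condition number "
                    f"{np.linalg.cond(M):.3g})"
                )
        for k, m, rho in self.coupling_pairs:
            if not (0 <= k < 5 and 0 <= m < 12):
                raise ValueError(f"coupling indices out of range: ({k}, {m})")
            if not abs(rho) < 1:
                raise ValueError(f"coupling strength must satisfy |rho| < 1, got {rho}")

    def to_dict(self) -> dict:
        return {
            "profile_mixing": self.profile_mixing.tolist(),
            "spatial_mixing": self.spatial_mixing.tolist(),
            "coupling_pairs": [[int(k), int(m), float(r)] for k, m, r in self.coupling_pairs],
            "source_family": self.source_family,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            profile_mixing=np.asarray(d["profile_mixing"], float),
            spatial_mixing=np.asarray(d["spatial_mixing"], float),
            coupling_pairs=[tuple(p) for p in d["coupling_pairs"]],
            source_family=d.get("source_family", "exponential"),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class FamilyStructure:
    """Family-block assignment: one family per subject, twins in pairs."""

    family_ids: list[str]
    zygosity: list[str]  # per subject: "singleton" | "MZ" | "DZ"

    def __post_init__(self):
        if len(self.family_ids) != len(self.zygosity):
            raise ValueError("family_ids and zygosity must align")
        sizes = pd.Series(self.family_ids).value_counts()
        for fid, size in sizes.items():
            zyg = {z for f, z in zip(self.family_ids, self.zygosity) if f == fid}
            if size == 1 and zyg != {"singleton"}:
                raise ValueError(f"family {fid}: singleton block with twin label")
            if size == 2 and not zyg <= {"MZ", "DZ"}:
                raise ValueError(f"family {fid}: pair block without twin label")
            if size > 2:
                raise ValueError(f"family {fid}: block size {size} > 2 unsupported")

    @property
    def n_subjects(self) -> int:
        return len(self.family_ids)

    def blocks(self) -> list[np.ndarray]:
        """Subject index arrays, one per family, in first-appearance order."""
        seen: dict[str, list[int]] = {}
        for i, fid in enumerate(self.family_ids):
            seen.setdefault(fid, []).append(i)
        return [np.array(v) for v in seen.values()]

    def block_sizes(self) -> list[int]:
        return [len(b) for b in self.blocks()]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated cohort: 471 subjects with the published
    singleton/MZ/DZ proportions (237/142/92 subjects), 58.8% female, and
    one hour of resting-state data (4800 timepoints) per subject.  Noise
    levels and the coupling amplitude are generator design choices
    (see docs/methods.md).
    """

    n_subjects: int = 471
    n_timepoints: int = 4800
    noise_sd_personality: float = 0.2  # standardized score units
    noise_sd_timeseries: float = 0.3  # mode-signal units
    singleton_fraction: float = 237 / 471
    mz_fraction: float = 142 / 471
    dz_fraction: float = 92 / 471
    female_fraction: float = 277 / 471
    coupling_log_sd: float = 0.5  # SD of log mode engagement across subjects
    ar1_coef: float = 0.0  # optional AR(1) coefficient for mode series
    neo_scale: bool = True  # map scores to the NEO 0-48 integer scale
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_timepoints <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd_personality < 0 or self.noise_sd_timeseries < 0:
            raise ValueError("noise SDs must be non-negative")
        fracs = (self.singleton_fraction, self.mz_fraction, self.dz_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or abs(sum(fracs) - 1) > 1e-9:
            raise ValueError("family fractions must lie in [0,1] and sum to 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0,1]")
        if not -1 < self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in (-1, 1)")


def random_ground_truth(
    seed: int = 0,
    coupling_pairs: Sequence[tuple[int, int, float]] = (),
    cond_max: float = 4.0,
) -> GroundTruth:
    """Draw random full-rank mixing matrices with unit-norm columns.

    Matrices are built from random orthogonal factors with a geometric
    singular-value spectrum, so their condition number stays below
    ``cond_max``: the components overlap (the decomposition problem is
    non-trivial) but remain well separated, the regime in which ICA
    recovery is meaningful.  The default bound of 4 corresponds to the
    moderate inter-factor correlations typical of five-factor data.
    """
    rng = np.random.default_rng(seed)

    def draw(size: int) -> np.ndarray:
        for _ in range(200):
            U = np.linalg.qr(rng.standard_normal((size, size)))[0]
            V = np.linalg.qr(rng.standard_normal((size, size)))[0]
            s = np.geomspace(1.0, 1.0 / (0.7 * cond_max), size)
            M = (U * s) @ V.T
            M /= np.linalg.norm(M, axis=0)
            if np.linalg.cond(M) <= cond_max:
                return M
        raise RuntimeError("failed to draw a well-conditioned mixing matrix")

    return GroundTruth(
        profile_mixing=draw(5),
        spatial_mixing=draw(12),
        coupling_pairs=list(coupling_pairs),
        seed=seed,
    )


def simulate_families(config: SimulationConfig) -> FamilyStructure:
    """Assign subjects to singleton/MZ/DZ family blocks per the config fractions."""
    n = config.n_subjects
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_mz_pairs = int(round(n * config.mz_fraction / 2))
    n_dz_pairs = int(round(n * config.dz_fraction / 2))
    n_single = n - 2 * (n_mz_pairs + n_dz_pairs)
    if n_single < 0:
        warnings.warn(
            f"n_subjects={n} too small for the requested twin fractions; "
            "falling back to all singletons",
            UserWarning,
            stacklevel=2,
        )
        n_mz_pairs = n_dz_pairs = 0
        n_single = n
    family_ids: list[str] = []
    zygosity: list[str] = []
    fam = 0
    for _ in range(n_mz_pairs):
        family_ids += [f"F{fam:04d}"] * 2
        zygosity += ["MZ", "MZ"]
        fam += 1
    for _ in range(n_dz_pairs):
        family_ids += [f"F{fam:04d}"] * 2
        zygosity += ["DZ", "DZ"]
        fam += 1
    for _ in range(n_single):
        family_ids.append(f"F{fam:04d}")
        zygosity.append("singleton")
        fam += 1
    # shuffle subject order so families are interleaved as in a real roster
    order = rng.permutation(n)
    return FamilyStructure(
        family_ids=[family_ids[i] for i in order],
        zygosity=[zygosity[i] for i in order],
    )


def _draw_nonnormal(rng: np.random.Generator, shape, family: str) -> np.ndarray:
    """Zero-mean unit-variance draws from a non-Gaussian family."""
    if family == "exponential":
        return rng.exponential(1.0, size=shape) - 1.0
    if family == "laplace":
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=shape)
    if family == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=shape)
    raise ValueError(f"unknown source family {family!r}")


def _latent_personality_sources(
    config: SimulationConfig, families: FamilyStructure, rng: np.random.Generator,
    family: str,
) -> np.ndarray:
    """Per-subject latent sources; twins share a family component."""
    n = config.n_subjects
    S = np.empty((n, 5))
    indiv = _draw_nonnormal(rng, (n, 5), family)
    shared: dict[str, np.ndarray] = {}
    for i, (fid, zyg) in enumerate(zip(families.family_ids, families.zygosity)):
        if zyg == "singleton":
            S[i] = indiv[i]
            continue
        if fid not in shared:
            shared[fid] = _draw_nonnormal(rng, (5,), family)
        w = MZ_SHARE if zyg == "MZ" else DZ_SHARE
        S[i] = np.sqrt(w) * shared[fid] + np.sqrt(1.0 - w) * indiv[i]
    return S


def simulate_personality(
    config: SimulationConfig,
    truth: GroundTruth,
    families: FamilyStructure | None = None,
    return_latent: bool = False,
):
    """Generate a PersonalityTable from the planted 5×5 profile mixing.

    Factor scores are latent sources × profile_mixingᵀ plus Gaussian
    measurement noise; twins share latent sources (weights 0.8 MZ / 0.5 DZ)
    so scores correlate within family.  With ``config.neo_scale`` the raw
    scores are placed on the NEO-FFI scale (cohort means/SDs, rounded to
    integers, clipped to 0–48); without it raw continuous scores are
    returned, which makes zero-noise identity-mixing runs exactly
    reproduce the latent draws.

    Returns the table, or ``(table, latent_sources)`` if ``return_latent``.
    """
    if config.n_subjects < 10:
        raise ValueError("n_subjects < 10: downstream ICA is unidentifiable")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    if families is None:
        families = simulate_families(config)
    if families.n_subjects != config.n_subjects:
        raise ValueError("family structure does not match n_subjects")

    S = _latent_personality_sources(config, families, rng, truth.source_family)
    raw = S @ truth.profile_mixing.T
    if config.noise_sd_personality > 0:
        raw = raw + rng.normal(0.0, config.noise_sd_personality, size=raw.shape)

    if config.neo_scale:
        # place each factor on the NEO scale using its analytic raw SD
        raw_sd = np.sqrt(
            (truth.profile_mixing**2).sum(axis=1) + config.noise_sd_personality**2
        )
        means = np.array([NEO_MEANS[f] for f in FACTOR_COLUMNS])
        sds = np.array([NEO_SDS[f] for f in FACTOR_COLUMNS])
        scores = np.clip(np.round(means + sds * raw / raw_sd), 0, 48)
    else:
        scores = raw

    # gender: MZ pairs share sex, everyone else independent
    gender = np.empty(config.n_subjects, dtype=object)
    fam_gender: dict[str, str] = {}
    draws = rng.uniform(size=config.n_subjects)
    for i, (fid, zyg) in enumerate(zip(families.family_ids, families.zygosity)):
        if zyg == "MZ":
            if fid not in fam_gender:
                fam_gender[fid] = "female" if draws[i] < config.female_fraction else "male"
            gender[i] = fam_gender[fid]
        else:
            gender[i] = "female" if draws[i] < config.female_fraction else "male"

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(config.n_subjects)],
            "family_id": families.family_ids,
            "zygosity": families.zygosity,
            "gender": gender,
        }
    )
    for j, f in enumerate(FACTOR_COLUMNS):
        frame[f] = scores[:, j]
    table = PersonalityTable(frame)
    if return_latent:
        return table, S
    return table


def _mode_series(
    rng: np.random.Generator, n_timepoints: int, ar1: float
) -> np.ndarray:
    """(T, 12) independent unit-variance Laplace mode series, optional AR(1)."""
    M = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(n_timepoints, 12))
    if ar1 != 0.0:
        from scipy.signal import lfilter

        M = lfilter([1.0], [1.0, -ar1], M, axis=0)
        M *= np.sqrt(1.0 - ar1**2)  # restore unit marginal variance
    return M


def simulate_roi_timeseries(
    config: SimulationConfig,
    truth: GroundTruth,
    profile_loadings: np.ndarray,
    return_latent: bool = False,
):
    """Generate per-subject ROI time series from the planted spatial mixing.

    Each subject gets 12 independent heavy-tailed (Laplace) latent mode time
    series.  For every coupling pair (k, m, rho) the mode-m series of
    subject i is rescaled so that its log-variance is linear in profile
    loading k with cross-subject correlation ≈ rho (log-linear coupling
    keeps engagement positive).  ROI series are mode series ×
    spatial_mixingᵀ plus Gaussian noise.

    Returns the :class:`ROITimeSeriesSet`, or ``(set, latent_modes,
    log_engagement)`` when ``return_latent`` — latent_modes is the
    (n, T, 12) array of scaled mode series, log_engagement the (n, 12)
    planted log variance multipliers.
    """
    profile_loadings = np.asarray(profile_loadings, dtype=float)
    if profile_loadings.shape[0] != config.n_subjects:
        raise ValueError(
            f"profile_loadings has {profile_loadings.shape[0]} rows, "
            f"expected n_subjects={config.n_subjects}"
        )
    for k, m, rho in truth.coupling_pairs:
        if not abs(rho) < 1:
            raise ValueError(f"coupling strength must satisfy |rho| < 1, got {rho}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 47]))
    n, T = config.n_subjects, config.n_timepoints

    # planted per-subject log variance of each mode
    log_engagement = np.zeros((n, 12))
    for k, m, rho in truth.coupling_pairs:
        z = profile_loadings[:, k]
        z = (z - z.mean()) / z.std()
        eps = rng.standard_normal(n)
        log_engagement[:, m] = config.coupling_log_sd * (
            rho * z + np.sqrt(1.0 - rho**2) * eps
        )

    scale = np.exp(0.5 * log_engagement)  # (n, 12) per-mode amplitude
    data = np.empty((n, T, 12))
    latent = np.empty((n, T, 12)) if return_latent else None
    for i in range(n):
        M = _mode_series(rng, T, config.ar1_coef) * scale[i]
        if latent is not None:
            latent[i] = M
        Y = M @ truth.spatial_mixing.T
        if config.noise_sd_timeseries > 0:
            Y = Y + rng.normal(0.0, config.noise_sd_timeseries, size=Y.shape)
        data[i] = Y

    ts = ROITimeSeriesSet(
        subject_ids=[f"S{i:04d}" for i in range(n)],
        data=data,
        region_labels=list(REGION_LABELS),
    )
    if return_latent:
        return ts, latent, log_engagement
    return ts


def simulate_study(config: SimulationConfig, truth: GroundTruth):
    """Convenience end-to-end draw: families, personality, ROI series.

    Returns (table, ts, families, latent_personality_sources).  The ROI
    coupling is driven by the true latent personality sources, so planted
    couplings refer to ground-truth profile indices.
    """
    families = simulate_families(config)
    table, S = simulate_personality(config, truth, families, return_latent=True)
    ts = simulate_roi_timeseries(config, truth, S)
    return table, ts, families, S
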