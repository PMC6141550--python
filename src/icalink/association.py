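"""Gender-corrected profile–engagement association with family-aware inference.

Each of the 5 personality profiles is tested against each of the 12
temporal-mode engagements (60 cells).  The statistic is the partial Pearson
correlation after residualizing both variables on the covariates (an
intercept plus, typically, gender).  Significance comes from
Freedman–Lane permutation of the covariate-residualized outcome, with
permutations restricted to respect family structure: free reordering
within a family block plus whole-block exchanges between families of equal
size — twins are never split across families.  Benjamini–Hochberg FDR is
applied once across all 60 cells.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationSet",
    "AssociationResult",
    "residualize",
    "partial_correlation",
    "blocks_from_family_ids",
    "generate_block_permutations",
    "count_block_permutations",
    "permutation_pvalue",
    "fdr_adjust",
    "run_association",
    "correlate_nuisance",
]


@dataclass
class PermutationSet:
    """Block-structure-preserving subject permutations; identity first."""

    perms: np.ndarray  # (m, n) int; row 0 is the identity
    blocks: list[np.ndarray]
    seed: int
    exhaustive: bool

    def __post_init__(self):
        self.perms = np.asarray(self.perms, dtype=np.intp)
        if self.perms.ndim != 2 or self.perms.shape[0] < 1:
            raise ValueError("perms must be a non-empty (m, n) array")
        n = self.perms.shape[1]
        if not np.array_equal(self.perms[0], np.arange(n)):
            raise ValueError("first permutation must be the identity")

    @property
    def n_perms(self) -> int:
        return self.perms.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.perms.shape[1]

    def check_block_preserving(self) -> None:
        """Assert every permutation maps each block onto an equal-size block.

        Vectorized: positions are labelled by block id and size; a
        permutation is valid iff every block's image lies in a single block
        of the same size (with the partition property this makes the block
        map a bijection).
        """
        n = self.n_subjects
        pos_block = np.empty(n, dtype=np.intp)
        pos_size = np.empty(n, dtype=np.intp)
        for bid, b in enumerate(self.blocks):
            pos_block[b] = bid
            pos_size[b] = len(b)
        for b in self.blocks:
            img_block = pos_block[self.perms[:, b]]  # (m, |b|)
            img_size = pos_size[self.perms[:, b]]
            same = (img_block == img_block[:, :1]).all(axis=1)
            sized = (img_size == len(b)).all(axis=1)
            bad = np.flatnonzero(~(same & sized))
            if bad.size:
                r = int(bad[0])
                raise AssertionError(
                    f"permutation {r} maps block {b.tolist()} outside the "
                    f"block structure (image {sorted(self.perms[r, b].tolist())})"
                )

    def digest(self) -> str:
        sizes = ",".join(str(len(b)) for b in self.blocks)
        return hashlib.sha1(sizes.encode()).hexdigest()[:12]


@dataclass
class AssociationResult:
    """All 5 × 12 profile-by-mode association cells."""

    r: np.ndarray  # (5, 12) partial correlations
    p: np.ndarray  # (5, 12) permutation p-values
    p_adjusted: np.ndarray  # (5, 12) BH-adjusted
    significant: np.ndarray  # (5, 12) bool, adjusted p < q
    q: float
    n_permutations: int
    seed: int
    block_digest: str
    n_subjects: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.r.shape[0]):
            for m in range(self.r.shape[1]):
                rows.append(
                    {
                        "profile": k + 1,
                        "mode": m + 1,
                        "r": self.r[k, m],
                        "p_perm": self.p[k, m],
                        "p_fdr": self.p_adjusted[k, m],
                        "significant": bool(self.significant[k, m]),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "r": self.r.tolist(),
            "p": self.p.tolist(),
            "p_adjusted": self.p_adjusted.tolist(),
            "significant": self.significant.astype(bool).tolist(),
            "q": self.q,
            "n_permutations": int(self.n_permutations),
            "seed": int(self.seed),
            "block_digest": self.block_digest,
            "n_subjects": int(self.n_subjects),
        }


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError(f"covariates have {C.shape[0]} rows, expected {n}")
    D = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate matrix (plus intercept) is rank deficient")
    return D


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [intercept, covariates]."""
    y = np.asarray(y, dtype=float)
    D = _design(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Pearson correlation of the two covariate-residualized vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    c = 0 if covariates is None else np.atleast_2d(np.asarray(covariates).T).shape[0]
    if n < c + 3:
        raise ValueError(f"need n >= c + 3 (n={n}, c={c})")
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance residual; correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def blocks_from_family_ids(family_ids: Sequence) -> list[np.ndarray]:
    """Subject index arrays grouped by family id (first-appearance order)."""
    seen: dict = {}
    for i, fid in enumerate(family_ids):
        seen.setdefault(fid, []).append(i)
    return [np.asarray(v, dtype=np.intp) for v in seen.values()]


def _as_blocks(blocks) -> list[np.ndarray]:
    if hasattr(blocks, "blocks"):  # FamilyStructure-like
        return [np.asarray(b, dtype=np.intp) for b in blocks.blocks()]
    return [np.asarray(b, dtype=np.intp) for b in blocks]


def count_block_permutations(blocks) -> int:
    """Number of block-preserving permutations: Π sizes! × Π (class count)!."""
    blocks = _as_blocks(blocks)
    total = 1
    by_size: dict[int, int] = {}
    for b in blocks:
        total *= math.factorial(len(b))
        by_size[len(b)] = by_size.get(len(b), 0) + 1
    for count in by_size.values():
        total *= math.factorial(count)
    return total


def _enumerate_block_permutations(blocks: list[np.ndarray], n: int) -> np.ndarray:
    by_size: dict[int, list[np.ndarray]] = {}
    for b in blocks:
        by_size.setdefault(len(b), []).append(b)
    class_choices = []  # one iterable of (size, assignments) per size class
    for size, blist in sorted(by_size.items()):
        c = len(blist)
        # each choice: a mapping of blocks within the class plus within-block orders
        within = list(itertools.permutations(range(size)))
        choices = []
        for sigma in itertools.permutations(range(c)):
            for taus in itertools.product(within, repeat=c):
                choices.append((blist, sigma, taus))
        class_choices.append(choices)
    perms = []
    for combo in itertools.product(*class_choices):
        perm = np.arange(n, dtype=np.intp)
        for blist, sigma, taus in combo:
            for j, b in enumerate(blist):
                src = blist[sigma[j]]
                perm[b] = src[list(taus[j])]
        perms.append(perm)
    return np.asarray(perms, dtype=np.intp)


def _sample_block_permutations(
    blocks: list[np.ndarray], n: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized uniform draw of m block-preserving permutations."""
    perms = np.tile(np.arange(n, dtype=np.intp), (m, 1))
    by_size: dict[int, list[np.ndarray]] = {}
    for b in blocks:
        by_size.setdefault(len(b), []).append(b)
    for size, blist in by_size.items():
        c = len(blist)
        pos = np.stack(blist)  # (c, size) positions per block
        # whole-block exchange within the size class
        order = rng.permuted(np.tile(np.arange(c), (m, 1)), axis=1)  # (m, c)
        src = pos[order]  # (m, c, size)
        if size > 1:
            within = rng.permuted(
                np.tile(np.arange(size), (m, c, 1)), axis=2
            )  # (m, c, size)
            src = np.take_along_axis(src, within, axis=2)
        perms[:, pos.reshape(-1)] = src.reshape(m, -1)
    return perms


def generate_block_permutations(blocks, n_perm: int, seed: int = 0) -> PermutationSet:
    """Family-structure-respecting permutations (identity included first).

    Allowed moves: reordering within a block and exchanging whole blocks of
    equal size.  If the total number of such permutations is at most
    ``n_perm`` they are enumerated exhaustively (no duplicates); otherwise
    ``n_perm − 1`` are sampled uniformly with the seed and prepended with
    the identity.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    blocks = _as_blocks(blocks)
    if not blocks:
        raise ValueError("empty block structure")
    n = int(sum(len(b) for b in blocks))
    idx = np.sort(np.concatenate(blocks))
    if not np.array_equal(idx, np.arange(n)):
        raise ValueError("blocks must partition subject indices 0..n-1")

    total = count_block_permutations(blocks)
    if total <= n_perm:
        perms = _enumerate_block_permutations(blocks, n)
        identity_row = int(np.flatnonzero((perms == np.arange(n)).all(axis=1))[0])
        order = [identity_row] + [i for i in range(perms.shape[0]) if i != identity_row]
        return PermutationSet(perms=perms[order], blocks=blocks, seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    sampled = _sample_block_permutations(blocks, n, n_perm - 1, rng)
    perms = np.vstack([np.arange(n, dtype=np.intp)[None, :], sampled])
    return PermutationSet(perms=perms, blocks=blocks, seed=seed, exhaustive=False)


def _freedman_lane_null_rs(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None, perms: PermutationSet
) -> tuple[float, np.ndarray]:
    """Observed partial r and the null |r| distribution via Freedman–Lane.

    The outcome is residualized on the covariates; residuals are permuted,
    the covariate fit re-added, and the partial correlation recomputed.
    Algebraically this equals correlating the residualized predictor with
    the re-residualized permuted residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    D = _design(covariates, n)
    Q, _ = np.linalg.qr(D)

    def resid(M):
        return M - Q @ (Q.T @ M)

    rx = resid(x)
    ry = resid(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance residual; correlation undefined")
    rxn = rx / np.linalg.norm(rx)
    r_obs = float(rxn @ (ry / np.linalg.norm(ry)))

    RY = resid(ry[perms.perms[1:].T])  # (n, m-1): permuted residuals re-residualized
    norms = np.linalg.norm(RY, axis=0)
    norms[norms == 0] = np.inf
    null_rs = rxn @ (RY / norms)
    return r_obs, null_rs


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    perms: PermutationSet,
) -> float:
    """Two-sided Freedman–Lane permutation p-value for the partial correlation.

    p = (1 + #{permuted |r| ≥ observed |r|}) / (#non-identity permutations + 1);
    the add-one convention means p is never exactly zero.
    """
    if perms.n_perms - 1 < 100:
        warnings.warn(
            f"only {perms.n_perms - 1} permutations; p-value resolution floor "
            f"is {1.0 / perms.n_perms:.3g}",
            UserWarning,
            stacklevel=2,
        )
    r_obs, null_rs = _freedman_lane_null_rs(x, y, covariates, perms)
    exceed = int(np.sum(np.abs(null_rs) >= abs(r_obs)))
    return (1 + exceed) / (len(null_rs) + 1)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def run_association(
    engagement,
    loadings,
    covariates: np.ndarray | None,
    blocks,
    n_perm: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
) -> AssociationResult:
    """All 60 profile × mode partial correlations with shared permutations.

    Parameters
    ----------
    engagement : EngagementMatrix or (n, 12) array
    loadings : ProfileLoadings or (n, 5) array
    covariates : (n, c) array or None
        Typically the gender indicator.
    blocks : FamilyStructure, or sequence of subject-index blocks
    n_perm : int
        Size of the shared PermutationSet (identity included).

    One PermutationSet is drawn and reused for every cell; p-values are
    BH-adjusted across the full 5 × 12 grid and flagged at adjusted p < q.
    """
    E, eng_ids = _values_and_ids(engagement)
    L, load_ids = _values_and_ids(loadings)
    if eng_ids is not None and load_ids is not None and eng_ids != load_ids:
        mism = [a for a, b in zip(eng_ids, load_ids) if a != b][:5]
        raise ValueError(f"subject IDs misaligned between inputs, e.g. {mism}")
    n = E.shape[0]
    if L.shape[0] != n:
        raise ValueError(f"row mismatch: engagement {n}, loadings {L.shape[0]}")

    perms = generate_block_permutations(blocks, n_perm, seed=seed)
    if perms.n_subjects != n:
        raise ValueError("block structure does not cover all subjects")

    D = _design(covariates, n)
    Q, _ = np.linalg.qr(D)

    def resid(M):
        return M - Q @ (Q.T @ M)

    RX = resid(L)  # (n, 5)
    RY = resid(E)  # (n, 12)
    if (RX.std(axis=0) == 0).any() or (RY.std(axis=0) == 0).any():
        raise ValueError("zero-variance residual column")
    RXn = RX / np.linalg.norm(RX, axis=0)
    RYn = RY / np.linalg.norm(RY, axis=0)
    r_obs = RXn.T @ RYn  # (5, 12)

    m_non_id = perms.n_perms - 1
    exceed = np.zeros_like(r_obs, dtype=np.int64)
    abs_obs = np.abs(r_obs)
    for row in perms.perms[1:]:
        RYp = resid(RY[row])
        norms = np.linalg.norm(RYp, axis=0)
        norms[norms == 0] = np.inf
        null_r = RXn.T @ (RYp / norms)
        exceed += np.abs(null_r) >= abs_obs
    p = (1 + exceed) / (m_non_id + 1)

    p_adj = fdr_adjust(p.reshape(-1)).reshape(p.shape)
    return AssociationResult(
        r=r_obs,
        p=p,
        p_adjusted=p_adj,
        significant=p_adj < q,
        q=q,
        n_permutations=perms.n_perms,
        seed=seed,
        block_digest=perms.digest(),
        n_subjects=n,
    )


def _values_and_ids(obj) -> tuple[np.ndarray, list[str] | None]:
    if hasattr(obj, "values") and hasattr(obj, "subject_ids"):
        return np.asarray(obj.values, dtype=float), list(obj.subject_ids)
    return np.asarray(obj, dtype=float), None


def correlate_nuisance(loadings, nuisance: np.ndarray) -> pd.DataFrame:
    """Per-profile Pearson r against a nuisance scalar (e.g. head motion RMS).

    Returns a frame with r, the parametric p, and the BH-adjusted p across
    the five profiles — the standard check that a profile is not a motion
    artifact.
    """
    L, _ = _values_and_ids(loadings)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.shape[0] != L.shape[0]:
        raise ValueError("nuisance vector must align with loadings")
    rs, ps = [], []
    for k in range(L.shape[1]):
        r, pv = stats.pearsonr(L[:, k], nuisance)
        rs.append(r)
        ps.append(min(max(pv, np.finfo(float).tiny), 1.0))
    return pd.DataFrame(
        {
            "profile": np.arange(1, L.shape[1] + 1),
            "r": rs,
            "p": ps,
            "p_fdr": fdr_adjust(ps),
        }
    )
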