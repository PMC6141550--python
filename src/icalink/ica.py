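"""Fixed-point ICA with symmetric decorrelation, plus component-comparison tools.

This module is the shared engine for both decompositions in the package:
the five-factor personality profiles (subjects as samples, factors as
channels) and the temporal functional modes (concatenated timepoints as
samples, regions of interest as channels).  It implements the classic
fixed-point ("FastICA") algorithm with parallel updates and symmetric
decorrelation, and the standard utilities needed to compare two ICA
solutions despite ICA's inherent sign and order ambiguity: a canonical
sign/order convention, the Amari performance index, and Hungarian-algorithm
component matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ICADecomposition",
    "center_and_scale",
    "fastica",
    "amari_index",
    "match_components",
    "canonical_order_and_signs",
]

NONLINEARITIES = ("logcosh", "exp", "cube")

# relative eigenvalue floor below which the input is declared rank deficient
_EIG_FLOOR = 1e-10


@dataclass
class ICADecomposition:
    """Result of a FastICA run in canonical form.

    Attributes
    ----------
    mixing : (p, k) array
        Columns are component weight patterns in the original channel space;
        ``X ≈ sources @ mixing.T`` for centered/scaled input ``X``.
    unmixing : (k, p) array
        Maps centered/scaled data to sources: ``sources = X @ unmixing.T``.
    sources : (n, k) array
        Estimated component scores, unit variance, mutually decorrelated.
    whitener : (k, p) array
        The whitening transform applied before rotation.
    """

    mixing: np.ndarray
    unmixing: np.ndarray
    sources: np.ndarray
    whitener: np.ndarray
    n_iterations: int
    converged: bool
    tol: float
    seed: int
    nonlinearity: str = "logcosh"

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def to_dict(self) -> dict:
        return {
            "mixing": self.mixing.tolist(),
            "unmixing": self.unmixing.tolist(),
            "whitener": self.whitener.tolist(),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "tol": float(self.tol),
            "seed": int(self.seed),
            "nonlinearity": self.nonlinearity,
        }

    @classmethod
    def from_dict(cls, d: dict, sources: np.ndarray | None = None) -> "ICADecomposition":
        k = len(d["unmixing"])
        return cls(
            mixing=np.asarray(d["mixing"], dtype=float),
            unmixing=np.asarray(d["unmixing"], dtype=float),
            sources=np.zeros((0, k)) if sources is None else np.asarray(sources, float),
            whitener=np.asarray(d["whitener"], dtype=float),
            n_iterations=int(d["n_iterations"]),
            converged=bool(d["converged"]),
            tol=float(d["tol"]),
            seed=int(d["seed"]),
            nonlinearity=d.get("nonlinearity", "logcosh"),
        )


def center_and_scale(
    X: np.ndarray, columns: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize each column to mean 0, sample SD 1 (denominator n−1).

    Returns the standardized matrix together with the per-column means and
    SDs so the identical affine transform can be re-applied to held-out
    subjects (required for leave-one-out projection).

    Raises
    ------
    ValueError
        If any column is constant (zero sample SD) or contains missing values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if not np.isfinite(X).all():
        raise ValueError("input contains missing or non-finite values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = [columns[i] if columns is not None else str(i) for i in bad]
        raise ValueError(f"constant column(s), cannot standardize: {names}")
    return (X - means) / sds, means, sds


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W ← (W Wᵀ)^(−1/2) W via eigendecomposition."""
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, np.finfo(float).tiny, None)
    return (u * (1.0 / np.sqrt(s))) @ u.T @ W


def _contrast(name: str):
    if name == "logcosh":
        def g(u):
            gu = np.tanh(u)
            return gu, 1.0 - gu**2
    elif name == "exp":
        def g(u):
            e = np.exp(-(u**2) / 2.0)
            return u * e, (1.0 - u**2) * e
    elif name == "cube":
        def g(u):
            return u**3, 3.0 * u**2
    else:
        raise ValueError(f"unknown nonlinearity {name!r}; choose from {NONLINEARITIES}")
    return g


def canonical_order_and_signs(mixing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical component order and signs for a mixing matrix.

    Order: descending variance explained in the (unit-variance-source) input,
    i.e. descending squared column norm.  Sign: each column oriented so its
    maximum-absolute-value entry is positive.  Resolves ICA's inherent
    order/sign ambiguity so repeated runs are comparable.
    """
    mixing = np.asarray(mixing, dtype=float)
    norms = (mixing**2).sum(axis=0)
    order = np.argsort(-norms, kind="stable")
    signs = np.empty(mixing.shape[1])
    for j_out, j in enumerate(order):
        col = mixing[:, j]
        signs[j_out] = 1.0 if col[np.argmax(np.abs(col))] >= 0 else -1.0
    return order, signs


def fastica(
    X: np.ndarray,
    n_components: int | None = None,
    nonlinearity: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 5,
) -> ICADecomposition:
    """Fixed-point ICA with parallel updates and symmetric decorrelation.

    Parameters
    ----------
    X : (n, p) array
        Data with samples in rows; expected centered and scaled
        (see :func:`center_and_scale`).  It is re-centered defensively.
    n_components : int, optional
        Number of components; default full rank.
    nonlinearity : {"logcosh", "exp", "cube"}
        Contrast function; ``logcosh`` (a=1) is the standard default.
    tol, max_iter
        Convergence is declared when the maximal change in weight-vector
        alignment ``max_j |1 − |⟨w_j_new, w_j_old⟩||`` drops below ``tol``.
    seed : int
        Seeds the random initial unmixing matrix; a run is deterministic
        given (X, options, seed).
    n_restarts : int
        The fixed-point iteration can oscillate near its tolerance at small
        sample sizes; up to this many differently-initialized attempts
        (all derived deterministically from ``seed``) are made and the
        first converged one is returned.

    Notes
    -----
    Whitening is by eigendecomposition of the sample covariance, retaining
    the requested components; eigenvalues below ``1e-10`` times the largest
    mark numerically deficient input and are rejected.  Non-convergence
    returns a result with ``converged=False`` plus a warning, never a
    silent failure.  Output is canonicalized: components ordered by
    descending explained variance, each mixing column signed so its
    largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than channels (n={n}, p={p})")
    X = X - X.mean(axis=0)

    cov = (X.T @ X) / (n - 1)
    d, E = np.linalg.eigh(cov)
    order = np.argsort(-d)
    d, E = d[order], E[:, order]
    rank = int(np.sum(d > d[0] * _EIG_FLOOR))
    k = rank if n_components is None else int(n_components)
    if k > rank:
        raise ValueError(
            f"requested {k} components but input has numerical rank {rank}"
        )
    whitener = (E[:, :k] / np.sqrt(d[:k])).T  # (k, p)
    Z = X @ whitener.T  # (n, k), identity covariance

    g = _contrast(nonlinearity)

    def attempt(attempt_seed: int) -> tuple[np.ndarray, int, bool]:
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt_seed]))
        W = _sym_decorrelate(rng.standard_normal((k, k)))
        for it in range(max_iter):
            U = Z @ W.T  # (n, k)
            gu, gpu = g(U)
            W_new = (gu.T @ Z) / n - (gpu.mean(axis=0)[:, None]) * W
            W_new = _sym_decorrelate(W_new)
            delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
            W = W_new
            if delta < tol:
                return W, it + 1, True
        return W, max_iter, False

    converged = False
    for restart in range(max(1, n_restarts)):
        W, n_iterations, converged = attempt(restart)
        if converged:
            break
    if not converged:
        warnings.warn(
            f"fastica did not converge in {max_iter} iterations over "
            f"{max(1, n_restarts)} restarts; returning converged=False",
            RuntimeWarning,
            stacklevel=2,
        )

    unmixing = W @ whitener  # (k, p)
    sources = Z @ W.T
    mixing = np.linalg.pinv(unmixing)  # (p, k)

    comp_order, signs = canonical_order_and_signs(mixing)
    mixing = mixing[:, comp_order] * signs
    unmixing = unmixing[comp_order, :] * signs[:, None]
    sources = sources[:, comp_order] * signs

    return ICADecomposition(
        mixing=mixing,
        unmixing=unmixing,
        sources=sources,
        whitener=whitener,
        n_iterations=n_iterations,
        converged=converged,
        tol=tol,
        seed=seed,
        nonlinearity=nonlinearity,
    )


def amari_index(A: np.ndarray, B: np.ndarray) -> float:
    """Amari performance index between two mixing matrices, in [0, 1].

    Computes ``P = A⁻¹ B`` and sums, over rows and columns of |P|, the
    mass not concentrated on the per-row/per-column maximum, normalized by
    ``2 k (k − 1)``.  Zero iff P is a scaled permutation, i.e. A and B
    span the same components up to ICA's order/sign/scale ambiguity.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square matrices of equal size")
    k = A.shape[0]
    if k < 2:
        raise ValueError("Amari index needs k >= 2")
    if np.linalg.cond(A) > 1 / np.finfo(float).eps:
        raise np.linalg.LinAlgError("A is singular or numerically so")
    P = np.abs(np.linalg.solve(A, B))
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row + col) / (2.0 * k * (k - 1)))


def _component_matrix(obj) -> np.ndarray:
    """Extract a (p, k) columns-as-components matrix from supported inputs."""
    if isinstance(obj, ICADecomposition):
        return obj.mixing
    return np.asarray(obj, dtype=float)


def match_components(ref, other) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal one-to-one component matching between two solutions.

    Parameters are :class:`ICADecomposition` objects or plain (p, k)
    matrices with components in columns.  The Hungarian algorithm maximizes
    the sum of absolute Pearson correlations between matched weight
    columns; signs are chosen so matched correlations are non-negative.

    Returns
    -------
    permutation : (k,) int array
        ``permutation[j]`` is the column of ``other`` matched to column
        ``j`` of ``ref``.
    signs : (k,) array of ±1
    matched_correlations : (k,) array
        Absolute correlation of each matched pair, in ref order.
    """
    A = _component_matrix(ref)
    B = _component_matrix(other)
    if A.shape != B.shape:
        raise ValueError(f"component shapes differ: {A.shape} vs {B.shape}")
    if A.std(axis=0).min() == 0 or B.std(axis=0).min() == 0:
        raise ValueError("degenerate zero-variance weight column")
    Ac = (A - A.mean(axis=0)) / A.std(axis=0)
    Bc = (B - B.mean(axis=0)) / B.std(axis=0)
    C = (Ac.T @ Bc) / A.shape[0]  # (k, k) correlations
    rows, cols = linear_sum_assignment(-np.abs(C))
    permutation = cols[np.argsort(rows)]
    picked = C[np.arange(C.shape[0]), permutation]
    signs = np.where(picked >= 0, 1.0, -1.0)
    return permutation, signs, np.abs(picked)
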