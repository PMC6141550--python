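"""Unit tests for the fixed-point ICA engine and component-comparison tools."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icalink import amari_index, center_and_scale, fastica, match_components
from icalink.ica import canonical_order_and_signs


class TestCenterAndScale:
    def test_three_point_column(self):
        Z, means, sds = center_and_scale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1.0, 0.0, 1.0])
        assert means[0] == 2.0 and sds[0] == 1.0

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        Z, _, _ = center_and_scale(X)
        Z2, _, _ = center_and_scale(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-12)

    def test_hand_computed_column(self):
        # mean 5, sample SD sqrt(32/7) ≈ 2.138, first entry -3/2.138 ≈ -1.403
        x = np.array([[2.0], [4.0], [4.0], [4.0], [5.0], [5.0], [7.0], [9.0]])
        Z, means, sds = center_and_scale(x)
        assert means[0] == 5.0
        np.testing.assert_allclose(sds[0], np.sqrt(32.0 / 7.0))
        np.testing.assert_allclose(Z[0, 0], -3.0 / np.sqrt(32.0 / 7.0), rtol=1e-12)
        np.testing.assert_allclose(Z[0, 0], -1.40312, atol=1e-5)

    def test_constant_column_rejected_by_name(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="B"):
            center_and_scale(X, columns=["A", "B"])

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="missing"):
            center_and_scale(X)


def _whitened_rotation_grid_amari(Z, truth_mixing):
    """Brute-force oracle for 2-source ICA: scan all 2-D rotations of the
    whitened data for the minimum-Gaussianity orientation (logcosh
    contrast) and return the Amari index of that orientation vs truth."""
    best, best_val = None, -np.inf
    E_g_gauss = 0.37456  # E[log cosh(x)] for standard normal x
    for theta in np.linspace(0, np.pi / 2, 721):
        c, s = np.cos(theta), np.sin(theta)
        W = np.array([[c, s], [-s, c]])
        proj = Z @ W.T
        val = float(((np.log(np.cosh(proj)).mean(axis=0) - E_g_gauss) ** 2).sum())
        if val > best_val:
            best_val, best = val, W
    # mixing in whitened space is W.T for a rotation
    return amari_index(truth_mixing, best.T)


class TestFastICA:
    def test_recovers_two_uniform_sources(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(2000, 2))
        Z, _, _ = center_and_scale(S)  # identity mixing
        dec = fastica(Z, 2, seed=0)
        assert dec.converged
        assert amari_index(np.eye(2), dec.mixing) < 0.05
        # independent check: exhaustive rotation scan finds the same orientation
        white = Z / Z.std(axis=0)
        assert _whitened_rotation_grid_amari(white, np.eye(2)) < 0.05

    def test_gaussian_sources_unidentifiable(self):
        # pure Gaussian input: ICA may not converge and any rotation is a
        # valid solution; only the decorrelation contract is required
        rng = np.random.default_rng(1)
        Z, _, _ = center_and_scale(rng.standard_normal((1000, 2)))
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dec = fastica(Z, 2, seed=0, max_iter=200)
        cov = np.cov(dec.sources, rowvar=False)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        S = rng.exponential(1.0, size=(500, 4)) - 1.0
        A = rng.standard_normal((4, 4))
        Z, _, _ = center_and_scale(S @ A.T)
        d1 = fastica(Z, 4, seed=11)
        d2 = fastica(Z, 4, seed=11)
        assert np.array_equal(d1.mixing, d2.mixing)
        assert np.array_equal(d1.unmixing, d2.unmixing)
        assert np.array_equal(d1.sources, d2.sources)
        assert d1.n_iterations == d2.n_iterations

    def test_source_decorrelation_invariant(self):
        rng = np.random.default_rng(5)
        S = rng.laplace(size=(800, 5))
        A = rng.standard_normal((5, 5))
        Z, _, _ = center_and_scale(S @ A.T)
        dec = fastica(Z, 5, seed=2)
        cov = (dec.sources.T @ dec.sources) / (len(dec.sources) - 1)
        np.testing.assert_allclose(cov, np.eye(5), atol=1e-6)

    def test_rank_deficient_input_rejected_with_rank(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        X = np.column_stack([x, 2 * x, rng.standard_normal(100)])
        X = X - X.mean(axis=0)
        with pytest.raises(ValueError, match="rank 2"):
            fastica(X, 3, seed=0)

    def test_mixing_unmixing_pseudo_inverse(self):
        rng = np.random.default_rng(9)
        S = rng.exponential(1.0, size=(600, 3)) - 1.0
        A = rng.standard_normal((3, 3))
        Z, _, _ = center_and_scale(S @ A.T)
        dec = fastica(Z, 3, seed=1)
        np.testing.assert_allclose(dec.unmixing @ dec.mixing, np.eye(3), atol=1e-8)

    def test_agrees_with_sklearn_reference(self):
        # independent implementation cross-check on identical data
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(21)
        S = rng.exponential(1.0, size=(1500, 4)) - 1.0
        A = rng.standard_normal((4, 4))
        Z, _, _ = center_and_scale(S @ A.T)
        ours = fastica(Z, 4, seed=3)
        ref = sklearn.FastICA(
            n_components=4, random_state=0, whiten="unit-variance", max_iter=1000
        ).fit(Z)
        _, _, rs = match_components(ours.mixing, ref.mixing_)
        assert rs.min() > 0.99


class TestAmariIndex:
    def test_identical_matrices_give_zero(self):
        A = np.random.default_rng(0).standard_normal((4, 4))
        assert amari_index(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_permutation_and_sign(self):
        A = np.random.default_rng(1).standard_normal((4, 4))
        B = A[:, [2, 0, 3, 1]] * np.array([1, -1, 1, -1])
        assert amari_index(A, B) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_offdiagonal_case(self):
        # P = [[1,1],[0,1]]: row sums of off-max mass 1+0, column 0+1,
        # normalized by 2k(k-1) = 4 → 0.5
        assert amari_index(np.eye(2), np.array([[1.0, 1.0], [0.0, 1.0]])) == pytest.approx(0.5)

    def test_singular_reference_rejected(self):
        A = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            amari_index(A, np.eye(3))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_property(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        B = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        assert amari_index(A, B) >= 0.0


class TestMatchComponents:
    def test_recovers_reversal_and_sign_flip(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 3))
        B = A[:, ::-1].copy()
        B[:, 0] *= -1
        perm, signs, rs = match_components(A, B)
        np.testing.assert_array_equal(perm, [2, 1, 0])
        np.testing.assert_allclose(rs, 1.0)
        assert signs[2] == -1.0  # ref column 2 matches the flipped column

    def test_small_noise_keeps_high_correlations(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((12, 5))
        B = A + 0.01 * A.std() * rng.standard_normal(A.shape)
        _, _, rs = match_components(A, B)
        assert rs.min() > 0.99

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_agrees_with_exhaustive_assignment(self, k):
        # brute-force oracle over all k! assignments
        rng = np.random.default_rng(k)
        A = rng.standard_normal((8, k))
        B = rng.standard_normal((8, k))
        perm, _, rs = match_components(A, B)

        def corr(a, b):
            return abs(np.corrcoef(a, b)[0, 1])

        best_val, best_perm = -np.inf, None
        for cand in itertools.permutations(range(k)):
            val = sum(corr(A[:, j], B[:, cand[j]]) for j in range(k))
            if val > best_val:
                best_val, best_perm = val, cand
        assert tuple(perm) == best_perm
        assert rs.sum() == pytest.approx(best_val)

    def test_degenerate_column_rejected(self):
        A = np.random.default_rng(0).standard_normal((5, 2))
        B = A.copy()
        B[:, 1] = 3.0
        with pytest.raises(ValueError, match="zero-variance"):
            match_components(A, B)


def test_canonicalization_is_idempotent():
    rng = np.random.default_rng(13)
    M = rng.standard_normal((6, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
    order, signs = canonical_order_and_signs(M)
    canonical = M[:, order] * signs
    order2, signs2 = canonical_order_and_signs(canonical)
    np.testing.assert_array_equal(order2, np.arange(4))
    np.testing.assert_array_equal(signs2, np.ones(4))
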