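"""Tests of partial correlation, block permutations, Freedman–Lane p-values,
and FDR — each checked against an independent oracle where one exists."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icalink import (
    SimulationConfig,
    correlate_nuisance,
    count_block_permutations,
    fdr_adjust,
    generate_block_permutations,
    partial_correlation,
    permutation_pvalue,
    residualize,
    run_association,
    simulate_families,
)


class TestResidualize:
    def test_orthogonal_covariate_only_removes_mean(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, -1.0, -1.0, 1.0])  # zero sample correlation with y
        res = residualize(y, c[:, None])
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_exactly_linear_outcome_gives_zero(self):
        c = np.arange(6.0)
        y = 3.0 + 2.0 * c
        np.testing.assert_allclose(residualize(y, c[:, None]), 0.0, atol=1e-10)

    def test_hand_computed_six_subject_case(self):
        # c=[0..5], y=[1,3,2,5,4,6]: normal equations give slope 31/35,
        # intercept 9/7 (hand arithmetic); residuals follow
        c = np.arange(6.0)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        slope, intercept = 31.0 / 35.0, 9.0 / 7.0
        expected = y - (intercept + slope * c)
        np.testing.assert_allclose(residualize(y, c[:, None]), expected, atol=1e-12)

    def test_rank_deficient_covariates_rejected(self):
        y = np.arange(5.0)
        C = np.column_stack([np.ones(5), 2 * np.ones(5)])
        with pytest.raises(ValueError, match="rank"):
            residualize(y, C)


class TestPartialCorrelation:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).standard_normal(30)
        assert partial_correlation(x, x) == pytest.approx(1.0)

    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert partial_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(80),
                "y": rng.standard_normal(80),
                "z": rng.standard_normal(80),
            }
        )
        ours = partial_correlation(df.x.values, df.y.values, df.z.values[:, None])
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")["r"].iloc[0]
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_monte_carlo_recovery_of_planted_rho(self):
        rng = np.random.default_rng(3)
        n, rho = 400, 0.4
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        g = rng.integers(0, 2, n).astype(float)
        assert partial_correlation(x, y, g[:, None]) == pytest.approx(rho, abs=0.12)


def _brute_force_block_perms(block_sizes):
    """Independent enumeration oracle: filter all n! permutations for those
    mapping each block onto an equal-size block with members kept together."""
    blocks, start = [], 0
    for s in block_sizes:
        blocks.append(tuple(range(start, start + s)))
        start += s
    n = start
    block_sets = {frozenset(b): len(b) for b in blocks}
    valid = []
    for perm in itertools.permutations(range(n)):
        ok = all(
            frozenset(perm[i] for i in b) in block_sets
            and len(b) == block_sets[frozenset(perm[i] for i in b)]
            for b in blocks
        )
        if ok:
            valid.append(perm)
    return set(valid)


class TestBlockPermutations:
    @pytest.mark.parametrize(
        "sizes,expected_count",
        [([1, 1, 1], 6), ([2, 2], 8), ([2, 1], 2), ([2, 2, 1, 1], 16)],
    )
    def test_exhaustive_enumeration_matches_brute_force(self, sizes, expected_count):
        blocks, start = [], 0
        for s in sizes:
            blocks.append(np.arange(start, start + s))
            start += s
        assert count_block_permutations(blocks) == expected_count
        ps = generate_block_permutations(blocks, n_perm=10_000, seed=0)
        assert ps.exhaustive
        got = {tuple(p) for p in ps.perms}
        assert got == _brute_force_block_perms(sizes)
        assert len(got) == ps.n_perms  # no duplicates
        ps.check_block_preserving()

    def test_identity_always_first(self):
        blocks = [np.array([0, 1]), np.array([2]), np.array([3, 4])]
        ps = generate_block_permutations(blocks, n_perm=5, seed=3)
        np.testing.assert_array_equal(ps.perms[0], np.arange(5))

    def test_sampled_permutations_preserve_blocks(self):
        cfg = SimulationConfig(n_subjects=60, seed=4)
        fam = simulate_families(cfg)
        ps = generate_block_permutations(fam, n_perm=200, seed=1)
        assert not ps.exhaustive
        assert ps.n_perms == 200
        ps.check_block_preserving()

    def test_sampling_deterministic_given_seed(self):
        cfg = SimulationConfig(n_subjects=40, seed=5)
        fam = simulate_families(cfg)
        p1 = generate_block_permutations(fam, 50, seed=9)
        p2 = generate_block_permutations(fam, 50, seed=9)
        np.testing.assert_array_equal(p1.perms, p2.perms)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_block_preservation_property(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.choice([1, 1, 2, 2, 3], size=4, replace=True)
        blocks, start = [], 0
        for s in sizes:
            blocks.append(np.arange(start, start + int(s)))
            start += int(s)
        ps = generate_block_permutations(blocks, n_perm=40, seed=seed)
        ps.check_block_preserving()


class TestPermutationPvalue:
    def test_perfect_association_hits_resolution_floor(self):
        x = np.arange(20.0)
        blocks = [np.array([i]) for i in range(20)]
        perms = generate_block_permutations(blocks, n_perm=100, seed=0)
        p = permutation_pvalue(x, x.copy(), None, perms)
        assert p == pytest.approx(1.0 / 100.0)

    def test_p_is_never_zero(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        blocks = [np.array([i]) for i in range(15)]
        with pytest.warns(UserWarning, match="resolution"):
            perms = generate_block_permutations(blocks, n_perm=50, seed=0)
            p = permutation_pvalue(x, y, None, perms)
        assert p > 0.0

    def test_null_type_one_error_calibrated(self):
        # independent x, y: rejection rate at alpha=0.05 near nominal
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(n_subjects=60, seed=8)
        fam = simulate_families(cfg)
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60)
            g = rng.integers(0, 2, 60).astype(float)
            perms = generate_block_permutations(fam, 500, seed=rep)
            rej += permutation_pvalue(x, y, g[:, None], perms) <= 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_freedman_lane_removes_covariate_effect(self):
        # y driven purely by the covariate: association must be null
        rng = np.random.default_rng(9)
        g = rng.integers(0, 2, 80).astype(float)
        x = rng.standard_normal(80) + 0.5 * g
        y = 2.0 * g + 0.1 * rng.standard_normal(80)
        blocks = [np.array([i]) for i in range(80)]
        perms = generate_block_permutations(blocks, 500, seed=0)
        p = permutation_pvalue(x, y, g[:, None], perms)
        assert p > 0.05


def _brute_force_bh(p):
    """Direct implementation of the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestFDRAdjust:
    def test_hand_applied_step_up_rule(self):
        np.testing.assert_allclose(
            fdr_adjust([0.005, 0.03, 0.04]), [0.015, 0.04, 0.04], atol=1e-12
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_array_equal(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), _brute_force_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=25,
        )
    )
    def test_step_up_property(self, p):
        adj = fdr_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()
        np.testing.assert_allclose(adj, _brute_force_bh(p), atol=1e-12)


class TestRunAssociation:
    def test_sixty_cells_and_flags(self, small_study):
        cfg, table, ts, families, latent = small_study
        rng = np.random.default_rng(0)
        eng = np.exp(rng.standard_normal((40, 12)))
        res = run_association(
            eng, latent, None, families, n_perm=200, seed=0
        )
        assert res.r.shape == (5, 12)
        assert res.to_frame().shape[0] == 60
        assert ((res.p > 0) & (res.p <= 1)).all()
        assert (res.p_adjusted >= res.p - 1e-12).all()
        np.testing.assert_array_equal(res.significant, res.p_adjusted < 0.05)

    def test_misaligned_subject_ids_rejected(self, small_study):
        from icalink import EngagementMatrix, ProfileLoadings

        cfg, table, ts, families, latent = small_study
        eng = EngagementMatrix(
            subject_ids=[f"X{i}" for i in range(40)],
            values=np.ones((40, 12)),
        )
        loadings = ProfileLoadings(subject_ids=table.subject_ids, values=latent)
        with pytest.raises(ValueError, match="misaligned"):
            run_association(eng, loadings, None, families, n_perm=10, seed=0)

    def test_deterministic_given_seed(self, small_study):
        cfg, table, ts, families, latent = small_study
        rng = np.random.default_rng(1)
        eng = np.exp(rng.standard_normal((40, 12)))
        r1 = run_association(eng, latent, None, families, n_perm=300, seed=5)
        r2 = run_association(eng, latent, None, families, n_perm=300, seed=5)
        np.testing.assert_array_equal(r1.p, r2.p)

    def test_single_cell_agrees_with_permutation_pvalue(self, small_study):
        # the vectorized 60-cell path must equal the scalar reference path
        cfg, table, ts, families, latent = small_study
        rng = np.random.default_rng(2)
        eng = np.exp(rng.standard_normal((40, 12)))
        g = rng.integers(0, 2, 40).astype(float)[:, None]
        res = run_association(eng, latent, g, families, n_perm=400, seed=7)
        from icalink import generate_block_permutations as gbp

        perms = gbp(families, 400, seed=7)
        for k, m in [(0, 0), (4, 11), (2, 5)]:
            p_scalar = permutation_pvalue(latent[:, k], eng[:, m], g, perms)
            assert res.p[k, m] == pytest.approx(p_scalar)
            assert res.r[k, m] == pytest.approx(
                partial_correlation(latent[:, k], eng[:, m], g)
            )


class TestNuisanceCorrelation:
    def test_copy_of_loading_column_has_unit_r(self):
        rng = np.random.default_rng(11)
        L = rng.standard_normal((100, 5))
        out = correlate_nuisance(L, L[:, 2].copy())
        assert out.shape[0] == 5
        assert out.loc[2, "r"] == pytest.approx(1.0)
        assert out.loc[2, "p_fdr"] < 1e-6

    def test_independent_nuisance_small_r(self):
        rng = np.random.default_rng(12)
        L = rng.standard_normal((400, 5))
        out = correlate_nuisance(L, rng.standard_normal(400))
        assert (out["r"].abs() < 0.15).all()
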