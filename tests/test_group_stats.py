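"""Multivariate permutation contrasts, ratio maps, CDF curves, volumes."""

import warnings
from itertools import combinations

import numpy as np
import pytest

from tubemorph.errors import ParameterError
from tubemorph.stats import (HotellingPermutationTest, compare_volumes,
                             mahalanobis_stat, permutation_pmap, pvalue_cdf,
                             ratio_map)


class TestMahalanobisStat:
    def test_identical_means_give_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 10, 4))
        A = np.concatenate([base, base])
        M = mahalanobis_stat(A[:4], A[4:])
        assert np.allclose(M, 0.0, atol=1e-10)

    def test_scalar_oracle(self):
        """1-D reduction: groups {1,2,3} vs {4,5,6} against the direct
        scalar formula M = (n1 n2 / (n1+n2)) (m1-m2)^2 / s2_pooled."""
        A = np.array([1.0, 2.0, 3.0]).reshape(3, 1)
        B = np.array([4.0, 5.0, 6.0]).reshape(3, 1)
        expected = (9 / 6) * (2.0 - 5.0) ** 2 / 1.0
        assert mahalanobis_stat(A, B)[0] == pytest.approx(expected,
                                                          abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 8, 4))
        B = rng.normal(size=(7, 8, 4)) + 0.3
        assert np.allclose(mahalanobis_stat(A, B), mahalanobis_stat(B, A),
                           atol=1e-10)

    def test_matches_lapack_solve_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(9, 20, 4))
        B = rng.normal(size=(11, 20, 4)) + 0.2
        M = mahalanobis_stat(A, B)
        # independent route: explicit pooled covariance + solve per vertex
        mA, mB = A.mean(0), B.mean(0)
        d = mA - mB
        expect = np.empty(20)
        for w in range(20):
            S = (np.cov(A[:, w, :].T, ddof=1) * 8
                 + np.cov(B[:, w, :].T, ddof=1) * 10) / 18
            expect[w] = (9 * 11 / 20) * d[w] @ np.linalg.solve(S, d[w])
        assert np.allclose(M, expect, rtol=1e-8)

    def test_tiny_group_rejected(self):
        with pytest.raises(ParameterError):
            mahalanobis_stat(np.zeros((1, 5, 4)), np.zeros((4, 5, 4)))


class TestPermutationPmap:
    def test_defaults_match_study_settings(self):
        from tubemorph.stats import DEFAULT_ALPHA, DEFAULT_N_PERM

        assert DEFAULT_N_PERM == 10_000
        assert DEFAULT_ALPHA == 0.05

    def test_sampled_p_within_3_se_of_exhaustive_enumeration(self):
        """3-vs-3 groups on 5 vertices against the 20-split oracle."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 5, 4))
        B = rng.normal(size=(3, 5, 4)) + 0.5
        X = np.concatenate([A, B])
        M_obs = mahalanobis_stat(A, B)
        splits = list(combinations(range(6), 3))
        exact = np.zeros(5)
        for s in splits:
            rest = [i for i in range(6) if i not in s]
            exact += mahalanobis_stat(X[list(s)], X[rest]) >= M_obs - 1e-9
        p_exact = exact / len(splits)
        n_perm = 2000
        res = permutation_pmap(A, B, n_perm=n_perm, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert (np.abs(res.p_uncorrected - p_exact)
                <= 3 * se + 2 / n_perm).all()

    def test_p_bounded_below_by_estimator_floor(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(6, 30, 4))
        B = rng.normal(size=(6, 30, 4)) + 3.0     # huge effect
        res = permutation_pmap(A, B, n_perm=300, seed=0)
        assert res.p_uncorrected.min() >= 1 / 301 - 1e-12
        assert (res.p_uncorrected <= 1.0).all()

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(5, 20, 4))
        B = rng.normal(size=(5, 20, 4))
        r1 = permutation_pmap(A, B, n_perm=300, seed=4)
        r2 = permutation_pmap(A, B, n_perm=300, seed=4)
        assert np.array_equal(r1.p_uncorrected, r2.p_uncorrected)
        assert r1.corrected_p == r2.corrected_p

    def test_chunking_invariance(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(5, 50, 4))
        B = rng.normal(size=(5, 50, 4)) + 0.4
        r1 = HotellingPermutationTest(A, B).fit(n_perm=200, seed=1,
                                                chunk_size=7)
        r2 = HotellingPermutationTest(A, B).fit(n_perm=200, seed=1,
                                                chunk_size=1000)
        assert np.array_equal(r1.p_uncorrected, r2.p_uncorrected)
        assert r1.corrected_p == r2.corrected_p

    def test_parameter_validation(self):
        A = np.zeros((3, 5, 4))
        with pytest.raises(ParameterError):
            permutation_pmap(A, A, n_perm=50)
        with pytest.raises(ParameterError):
            HotellingPermutationTest(A, A, alpha=1.5)

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(3)
        res = permutation_pmap(rng.normal(size=(4, 10, 4)),
                               rng.normal(size=(4, 10, 4)),
                               n_perm=150, seed=0)
        text = res.summary()
        assert "p feature" in text and "corrected p" in text


class TestRatioMap:
    def test_identical_groups_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        d = np.abs(rng.normal(1.0, 0.05, size=(6, 20)))
        rm = ratio_map(d, d.copy(), np.ones(20, dtype=bool))
        assert np.allclose(rm.ratio, 1.0, atol=1e-12)

    def test_uniform_atrophy_classified(self):
        d1 = np.full((5, 10), 1.0)
        d2 = np.full((5, 10), 0.81)
        rm = ratio_map(d1, d2, np.ones(10, dtype=bool), ("NC", "HM"))
        assert np.allclose(rm.ratio, 1 / 0.81, atol=1e-12)
        assert rm.atrophy_mask.all()

    def test_group_order_reversal_inverts(self):
        rng = np.random.default_rng(4)
        d1 = np.abs(rng.normal(1.0, 0.1, size=(4, 15)))
        d2 = np.abs(rng.normal(0.9, 0.1, size=(6, 15)))
        mask = np.ones(15, dtype=bool)
        r12 = ratio_map(d1, d2, mask).ratio
        r21 = ratio_map(d2, d1, mask).ratio
        assert np.allclose(r12 * r21, 1.0, atol=1e-12)

    def test_empty_mask_warns(self):
        d = np.full((3, 5), 1.0)
        with pytest.warns(UserWarning):
            rm = ratio_map(d, d, np.zeros(5, dtype=bool))
        assert np.isnan(rm.ratio).all()


class TestPvalueCdf:
    def test_uniform_grid_sits_on_diagonal(self):
        p = (np.arange(1, 101)) / 100.0
        _, _, dev = pvalue_cdf(p)
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_pile_at_floor_has_maximal_deviation(self):
        p = np.full(200, 1 / 1001)
        _, _, dev = pvalue_cdf(p)
        assert dev > 0.99


class TestCompareVolumes:
    def test_identical_lists_not_significant(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert compare_volumes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                   n_perm=500, seed=0) > 0.5

    def test_extreme_separation_reaches_enumeration_floor(self):
        p = compare_volumes([1, 2, 3], [101, 102, 103], n_perm=4000, seed=1)
        # most extreme two-sided mean split: exhaustive p = 2/20
        exhaustive = 2 / 20
        assert abs(p - exhaustive) < 0.03

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            if compare_volumes(a, b, n_perm=200, seed=rep) < 0.05:
                rejections += 1
        assert 0.02 < rejections / n_rep < 0.09

    def test_degenerate_input_warns_p1(self):
        with pytest.warns(UserWarning):
            assert compare_volumes([2.0, 2.0], [2.0, 2.0]) == 1.0
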