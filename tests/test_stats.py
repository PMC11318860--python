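"""Inference: correlation tests, minimal n, permutations, FDR, bootstrap."""

import itertools

import numpy as np
import pytest

from chillconn import (
    bh_fdr,
    bootstrap_corr_diff,
    critical_r,
    linear_trend_r2,
    min_n_for_r,
    paired_edge_test,
    pearson_r_p,
    permutation_test,
)
from chillconn.exceptions import BoundedSearchError


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_r_p(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_exactly_orthogonal_gives_p_one(self):
        x = np.arange(10.0)
        y = (x - x.mean()) ** 2  # symmetric around the mean: r = 0 exactly
        res = pearson_r_p(x, y, sided="two")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_sided_doubles_one_sided_for_positive_r(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(scale=1.0, size=20)
        one = pearson_r_p(x, y, sided="one")
        two = pearson_r_p(x, y, sided="two")
        assert two.p == pytest.approx(2 * one.p, rel=1e-9)

    def test_degenerate_flagged(self):
        res = pearson_r_p(np.ones(5), np.arange(5.0))
        assert res.degenerate
        assert res.p == 1.0


class TestCriticalRAndMinN:
    def test_minimal_significant_sample_inversion(self):
        # one-sided alpha = .05 at n = 11 requires r ~ 0.52
        assert critical_r(11, 0.05, "one") == pytest.approx(0.52, abs=5e-3)

    def test_alpha_half_needs_no_correlation(self):
        assert critical_r(11, 0.5, "one") == 0.0

    def test_three_points_critical(self):
        # t(0.95, df=1) = 6.314 -> r = t/sqrt(t^2+1) = 0.988
        assert critical_r(3, 0.05, "one") == pytest.approx(0.988, abs=1e-3)

    def test_min_n_for_the_observed_accuracy(self):
        # a decoder accuracy of r = 0.53 first reaches one-sided p <= .05
        # at n = 11 - the minimal replication sample
        assert min_n_for_r(0.53, 0.05, "one") == 11

    def test_min_n_brute_force_consistency(self):
        for r in (0.3, 0.53, 0.8):
            n = min_n_for_r(r, 0.05, "one")
            assert _r_p(r, n) <= 0.05 < _r_p(r, n - 1)

    def test_near_perfect_r_needs_three(self):
        assert min_n_for_r(0.9999, 0.05, "one") == 3

    def test_unreachable_r_raises(self):
        with pytest.raises(BoundedSearchError):
            min_n_for_r(0.01, 0.05, "one", n_max=20)


def _r_p(r, n):
    from scipy import stats as sps
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return sps.t.sf(t, n - 2)


class TestPermutation:
    @staticmethod
    def _stat(X, y):
        return float(np.corrcoef(X[:, 0], y)[0, 1])

    def test_strong_effect_hits_p_floor(self, rng):
        X = rng.normal(size=(40, 3))
        y = 5 * X[:, 0] + rng.normal(scale=0.1, size=40)
        res = permutation_test(self._stat, X, y, n_perm=99, seed=0)
        assert res.p == pytest.approx(1 / 100)

    def test_reproducible_and_in_unit_interval(self, rng):
        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        a = permutation_test(self._stat, X, y, n_perm=50, seed=4)
        b = permutation_test(self._stat, X, y, n_perm=50, seed=4)
        assert a.p == b.p
        assert 0 < a.p <= 1


class TestBhFdr:
    @staticmethod
    def _brute_force(pvals, alpha=0.05):
        """Textbook step-up: reject all p <= p_(k*), k* the largest k with
        p_(k) <= k/m * alpha; adjusted p by the monotone cummin rule."""
        p = np.asarray(pvals, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        thresh = alpha * (np.arange(1, m + 1)) / m
        passing = np.nonzero(p[order] <= thresh)[0]
        reject = np.zeros(m, bool)
        if passing.size:
            reject[order[: passing.max() + 1]] = True
        adj = np.empty(m)
        prev = 1.0
        for i in range(m - 1, -1, -1):
            prev = min(prev, p[order[i]] * m / (i + 1))
            adj[order[i]] = prev
        return reject, adj

    def test_matches_brute_force_on_all_short_grids(self):
        grid = (0.001, 0.02, 0.04, 0.2, 1.0)
        for length in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, length):
                reject, adj = bh_fdr(np.array(combo))
                bf_r, bf_a = self._brute_force(np.array(combo))
                assert np.array_equal(reject, bf_r), combo
                assert np.allclose(adj, bf_a, atol=1e-12), combo

    def test_graded_small_pvalues_all_rejected(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_single_p_unchanged_and_all_ones_kept(self):
        _, adj = bh_fdr([0.3])
        assert adj[0] == pytest.approx(0.3)
        reject, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()


class TestBootstrap:
    def test_identical_predictors_span_zero(self, rng):
        y = rng.normal(size=30)
        a = y + rng.normal(scale=0.5, size=30)
        res = bootstrap_corr_diff(y, a, a, n_boot=500, seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.ci[0] <= 0 <= res.ci[1]

    def test_informative_beats_noise(self, rng):
        y = rng.normal(size=38)
        good = y + rng.normal(scale=0.3, size=38)
        noise = rng.normal(size=38)
        res = bootstrap_corr_diff(y, good, noise, n_boot=2000, seed=2)
        assert res.ci[0] > 0
        assert res.p < 0.05

    def test_seeded_reproducibility(self, rng):
        y = rng.normal(size=20)
        a = y + rng.normal(size=20)
        b = rng.normal(size=20)
        r1 = bootstrap_corr_diff(y, a, b, n_boot=200, seed=9)
        r2 = bootstrap_corr_diff(y, a, b, n_boot=200, seed=9)
        assert r1.ci == r2.ci and r1.p == r2.p


class TestTrend:
    def test_exact_line_r2_one(self):
        x = np.arange(20, 42, 2.0)
        res = linear_trend_r2(x, 0.01 * x + 0.1)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_r2_zero(self):
        res = linear_trend_r2(np.arange(11.0), np.full(11, 0.4))
        assert res.statistic == 0.0

    def test_matches_normal_equations(self, rng):
        x = np.arange(11.0)
        y = 0.3 * x + rng.normal(scale=1.0, size=11)
        res = linear_trend_r2(x, y)
        X = np.column_stack([np.ones(11), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ss_res = np.sum((y - X @ beta) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert res.statistic == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)


class TestPairedEdgeTest:
    def test_identical_conditions_no_rejections(self, rng):
        A = rng.normal(size=(10, 8))
        out = paired_edge_test(A, A + rng.normal(scale=1.0, size=(10, 8)))
        # random differences: occasional raw p < .05 but FDR should be quiet
        assert out["significant"].sum() <= 1

    def test_shifted_edge_detected(self, rng):
        A = rng.normal(size=(12, 8))
        B = A + rng.normal(scale=0.1, size=(12, 8))
        B[:, 3] += 5.0
        out = paired_edge_test(A, B)
        assert out.loc[3, "significant"]
        assert out.drop(index=3)["significant"].sum() == 0

    def test_t_matches_hand_formula(self, rng):
        A = rng.normal(size=(9, 3))
        B = rng.normal(size=(9, 3))
        out = paired_edge_test(A, B)
        d = A - B
        t_hand = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(9))
        assert np.allclose(out["t"], t_hand, atol=1e-10)
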