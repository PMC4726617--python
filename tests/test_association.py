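"""Statistical layer: correlation, regression, rank tests, power."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ugtphen.association import (correlation_power, kruskal_wallis,
                                 linear_regression, pearson,
                                 wilcoxon_rank_sum)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).estimate == pytest.approx(1.0)
        assert pearson(x, -x).estimate == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 30))
        base = pearson(x, y)
        perm = rng.permutation(30)
        shuffled = pearson(x[perm], y[perm])
        assert shuffled.estimate == pytest.approx(base.estimate, rel=1e-12)
        assert shuffled.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_null_type_one_error(self):
        # 10^4 null replicates at n = 24: rejection rate 0.05 +/- 0.01
        rng = np.random.default_rng(1)
        n, reps = 24, 10000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1)
                                            * (yc**2).sum(axis=1))
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(tstat), n - 2)
        # spot-check the vectorized p against the package implementation
        ref = pearson(x[0], y[0])
        assert p[0] == pytest.approx(ref.p_value, rel=1e-9)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestLinearRegression:
    def test_published_anc_line_recovered_exactly(self):
        # noise-free ANC = 129.2 + 89461.5 * K23 over a realistic K23 spread
        rng = np.random.default_rng(2)
        k23 = 0.0086 * np.exp(rng.standard_normal(24) * 0.7)
        anc = 129.2 + 89461.5 * k23
        res = linear_regression(k23, anc)
        assert res.estimate == pytest.approx(89461.5, rel=1e-9)
        assert res.intercept == pytest.approx(129.2, rel=1e-9)
        assert res.r == pytest.approx(1.0)

    def test_constant_y_gives_zero_slope(self):
        res = linear_regression(np.arange(5.0), np.full(5, 3.0))
        assert res.estimate == 0.0

    def test_slope_sd_ratio_equals_r(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        res = linear_regression(x, y)
        assert res.estimate * np.std(x, ddof=1) / np.std(y, ddof=1) == \
            pytest.approx(res.r, rel=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression(np.ones(5), np.arange(5.0))


class TestWilcoxonRankSum:
    def test_exact_p_by_enumeration(self):
        # (1,2,3) vs (10,11,12): most extreme split; enumerate all C(6,3)
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        res = wilcoxon_rank_sum(a, b)
        values = np.array(a + b)
        ranks = stats.rankdata(values)
        observed = ranks[:3].sum()
        null = [sum(c) for c in itertools.combinations(ranks, 3)]
        mean_null = np.mean(null)
        p_exact = np.mean([abs(s - mean_null) >= abs(observed - mean_null)
                           for s in null])
        assert res.p_value == pytest.approx(p_exact)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 0.5, 3.5])
        assert res.p_value > 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(8)
        b = rng.standard_normal(9) + 0.5
        base = wilcoxon_rank_sum(a, b)
        trans = wilcoxon_rank_sum(np.exp(a), np.exp(b))
        assert trans.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_switches_to_asymptotic_for_large_groups(self):
        rng = np.random.default_rng(5)
        res = wilcoxon_rank_sum(rng.standard_normal(20),
                                rng.standard_normal(20))
        assert "asymptotic" in res.method

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0, 2.0, 3.0])


class TestKruskalWallis:
    def test_two_groups_matches_rank_sum_asymptotics(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 0.8
        kw = kruskal_wallis([a, b])
        z = stats.norm.isf(wilcoxon_rank_sum(a, b).p_value / 2)
        assert kw.estimate == pytest.approx(z**2, rel=0.05)

    def test_identical_values_h_zero(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_null_type_one_error(self):
        # 3 groups x 8 from one distribution, 10^4 reps
        rng = np.random.default_rng(7)
        rejected = 0
        reps = 10000
        for _ in range(reps):
            g = rng.standard_normal((3, 8))
            if stats.kruskal(*g).pvalue < 0.05:
                rejected += 1
        # spot-check scipy path against the package wrapper
        g = rng.standard_normal((3, 8))
        assert kruskal_wallis(list(g)).p_value == pytest.approx(
            stats.kruskal(*g).pvalue)
        assert rejected / reps == pytest.approx(0.05, abs=0.01)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestCorrelationPower:
    def test_study_design_worked_example(self):
        # detecting r = 0.600 with 19 subjects at alpha 0.05: ~80% power
        power = correlation_power(0.600, 19, 0.05)
        assert 0.79 <= power <= 0.81

    def test_size_under_null(self):
        assert correlation_power(0.0, 19, 0.05) == pytest.approx(0.05)

    def test_monotone_in_n(self):
        powers = [correlation_power(0.5, n) for n in range(5, 60, 5)]
        assert np.all(np.diff(powers) > 0)

    def test_domain(self):
        with pytest.raises(ValueError):
            correlation_power(1.0, 19)
        with pytest.raises(ValueError):
            correlation_power(0.5, 3)

    def test_agrees_with_simulation(self):
        # Monte-Carlo check of the Fisher-z approximation at the design point
        rng = np.random.default_rng(8)
        n, reps, rho = 19, 4000, 0.6
        cov = np.array([[1.0, rho], [rho, 1.0]])
        l_factor = np.linalg.cholesky(cov)
        hits = 0
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ l_factor.T
            if stats.pearsonr(xy[:, 0], xy[:, 1]).pvalue < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(correlation_power(rho, n), abs=0.03)
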