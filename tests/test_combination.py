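import math

import numpy as np
import pytest
from scipy import stats

from seamsel import (
    FinalOutcome,
    InterimDecision,
    StageStatistics,
    closed_test_decision,
    combination_statistic,
    conditional_critical_value,
    critical_value_c2,
    estimate_hazard_ratio,
    estimate_rho,
    intersection_pvalue,
    intersection_threshold,
    logrank_z,
    make_scenario_fixture,
    simulate_cohort,
)
from seamsel.combination import ZeroVarianceError, bivariate_normal_cdf

W1 = math.sqrt(50 / 190)
W2 = math.sqrt(140 / 190)


class TestLogrank:
    def test_identical_arms(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        assert logrank_z(t, e, g) == pytest.approx(0.0, abs=1e-12)

    def test_hand_tabulation(self):
        """Toy data, oracle = explicit hypergeometric tabulation over the six
        event times, recomputed here step by step."""
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, dtype=int)
        group = np.array([0, 0, 0, 1, 1, 1])
        # independent oracle: loop over event times
        U = V = 0.0
        for t in time:
            at_risk = time >= t
            n = at_risk.sum()
            n1 = (at_risk & (group == 1)).sum()
            d = 1
            U += (group[time == t] == 1).sum() - d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = -U / math.sqrt(V)
        assert expected > 0  # treatment events later -> protective
        assert logrank_z(time, event, group) == pytest.approx(expected, abs=1e-12)

    def test_against_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.8).astype(int)
        g = np.repeat([0, 1], 40)
        z = logrank_z(t, e, g)
        ref = logrank_test(t[g == 0], t[g == 1], event_observed_A=e[g == 0], event_observed_B=e[g == 1])
        assert z**2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_power_under_effect(self, design, scenario3):
        """Simulated common-HR-0.7 cohorts at the confirmatory sample size:
        positive mean z and rejection rate near the planning power target."""
        rejections = 0
        zs = []
        for k in range(300):
            ds = simulate_cohort(scenario3, design, "phase3", n_per_arm=140, seed=500 + k)
            full = ds.observed_at(ds.analysis_time + 48.0)
            z = logrank_z(full, population="F")
            zs.append(z)
            rejections += z > 1.96
        assert np.mean(zs) > 0
        assert 0.65 < rejections / 300 < 0.95

    def test_no_events_raises(self):
        with pytest.raises(ZeroVarianceError):
            logrank_z(np.array([1.0, 2.0]), np.array([0, 0]), np.array([0, 1]))


class TestCombinationNumerics:
    def test_combination_statistic(self):
        assert combination_statistic(0.0, 2.0, 0.6, 0.8) == pytest.approx(1.6)
        assert combination_statistic(1.0, 1.0, 0.6, 0.8) == pytest.approx(1.4)
        assert combination_statistic(2.0, 2.0, W1, W2) == pytest.approx(2 * (W1 + W2), abs=1e-12)
        with pytest.raises(ValueError):
            combination_statistic(1.0, 1.0, 0.9, 0.9)

    def test_c2_degenerate_limit(self):
        assert critical_value_c2(1.0, 0.025) == pytest.approx(stats.norm.ppf(0.975), abs=1e-9)

    def test_c2_independence_closed_form(self):
        assert critical_value_c2(0.0, 0.025) == pytest.approx(stats.norm.ppf(math.sqrt(0.975)), abs=1e-8)

    def test_c2_interior_and_monotone(self):
        lo, hi = stats.norm.ppf(0.975), stats.norm.ppf(math.sqrt(0.975))
        grid = [critical_value_c2(t, 0.025) for t in np.linspace(0, 1, 11)]
        assert lo < grid[5] < hi
        assert all(a > b for a, b in zip(grid, grid[1:]))  # strictly decreasing in corr

    def test_c2_mc_oracle(self, rng):
        tau = 0.7
        c2 = critical_value_c2(tau, 0.025)
        n = 10**6
        z = rng.multivariate_normal([0, 0], [[1, tau], [tau, 1]], size=n)
        p = (z.max(axis=1) >= c2).mean()
        se = math.sqrt(0.025 * 0.975 / n)
        assert abs(p - 0.025) < 4 * se

    def test_c2_invalid(self):
        with pytest.raises(ValueError):
            critical_value_c2(0.7, 0.7)
        with pytest.raises(ValueError):
            critical_value_c2(1.5, 0.025)

    def test_conditional_critical_value(self):
        assert conditional_critical_value(2.0, 0.0, 0.8, 0.8) == pytest.approx(2.5)
        assert conditional_critical_value(2.0, 1.3, 0.0, 0.8) == pytest.approx(2.5)
        assert conditional_critical_value(2.0, 0.5, 0.8, W2) == pytest.approx(1.6 / W2, abs=1e-12)
        assert conditional_critical_value(2.0, 0.5, 0.8, W2) == pytest.approx(1.8639, abs=1e-4)
        with pytest.raises(ValueError):
            conditional_critical_value(2.0, 0.5, 0.8, 0.0)

    def test_intersection_pvalue_independence(self):
        p = intersection_pvalue(1.96, 0.0)
        assert p == pytest.approx(1 - stats.norm.cdf(1.96) ** 2, abs=1e-9)
        assert p == pytest.approx(0.049375, abs=1e-4)

    def test_intersection_pvalue_perfect_correlation(self):
        assert intersection_pvalue(1.96, 1.0) == pytest.approx(1 - stats.norm.cdf(1.96), abs=1e-9)

    def test_intersection_pvalue_monotone(self):
        zs = np.linspace(-1, 4, 21)
        ps = [intersection_pvalue(z, 0.7) for z in zs]
        assert all(1 >= a > b >= 0 for a, b in zip(ps, ps[1:]))
        # higher correlation makes the two tests more redundant, so the
        # intersection p-value at fixed z_max falls toward the single-test
        # p-value (Slepian inequality)
        taus = np.linspace(0, 0.99, 15)
        pt = [intersection_pvalue(2.0, t) for t in taus]
        assert all(a > b for a, b in zip(pt, pt[1:]))
        assert pt[0] == pytest.approx(1 - stats.norm.cdf(2.0) ** 2, abs=1e-9)

    def test_intersection_pvalue_mc_oracle(self, rng):
        tau, zmax = 0.7, 2.2
        n = 10**6
        z = rng.multivariate_normal([0, 0], [[1, tau], [tau, 1]], size=n)
        mc = (z.max(axis=1) > zmax).mean()
        p = intersection_pvalue(zmax, tau)
        se = math.sqrt(mc * (1 - mc) / n)
        assert abs(p - mc) < 4 * se

    def test_intersection_threshold_closed_forms(self):
        c2 = 2.2389
        p = intersection_threshold(c2, 0.0, 0.0, 0.0, W2, 0.0)
        assert p == pytest.approx(1 - stats.norm.cdf(c2 / W2) ** 2, abs=1e-9)
        # degenerate correlation with equal stage-1 statistics
        p = intersection_threshold(c2, 0.4, 0.4, 0.8, W2, 1.0)
        assert p == pytest.approx(1 - stats.norm.cdf((c2 - 0.8 * 0.4) / W2), abs=1e-9)

    def test_intersection_threshold_consistency_identity(self):
        # with null stage-1 statistics the threshold equals the intersection
        # p-value evaluated at c2 / w2
        c2 = critical_value_c2(0.7, 0.025)
        a = intersection_threshold(c2, 0.0, 0.0, 0.8, W2, 0.7)
        b = intersection_pvalue(c2 / W2, 0.7)
        assert a == pytest.approx(b, abs=1e-10)

    def test_randomized_grid_vs_mc(self, rng):
        """Every bivariate-normal probability matches a large MC estimate."""
        for _ in range(5):
            c2 = rng.uniform(1.8, 2.4)
            s1F, s1S = rng.uniform(-1, 1, 2)
            rho = rng.uniform(0, 1)
            w2 = rng.uniform(0.6, 0.95)
            tau = rng.uniform(0.05, 0.95)
            a = (c2 - rho * s1F) / w2
            b = (c2 - rho * s1S) / w2
            n = 10**6
            z = rng.multivariate_normal([0, 0], [[1, tau], [tau, 1]], size=n)
            mc = ((z[:, 0] < a) & (z[:, 1] < b)).mean()
            exact = 1.0 - intersection_threshold(c2, s1F, s1S, rho, w2, tau)
            se = math.sqrt(max(mc * (1 - mc), 1e-12) / n)
            assert abs(exact - mc) < 4 * se + 1e-9

    def test_bivariate_cdf_edges(self):
        assert bivariate_normal_cdf(0.0, 5.0, 0.0) == pytest.approx(0.5, abs=1e-6)
        assert bivariate_normal_cdf(1.0, 2.0, 1.0) == pytest.approx(stats.norm.cdf(1.0), abs=1e-9)
        with pytest.raises(ValueError):
            bivariate_normal_cdf(0, 0, 1.5)


class TestClosedTesting:
    def _stats(self, **kw):
        base = dict(z1b_F=0.5, z1b_S=0.7, w1=W1, w2=W2)
        base.update(kw)
        return StageStatistics(**base)

    def test_futility_no_tests(self, design):
        out = closed_test_decision(self._stats(), InterimDecision.FUTILITY, design)
        assert out == FinalOutcome(False, False, False, False, False)

    def test_single_population_rule(self, design):
        st_ = self._stats(z2_F=5.0)
        out = closed_test_decision(st_, InterimDecision.F_ONLY, design)
        assert out.reject_F and not out.reject_S and not out.tested_S
        thr = conditional_critical_value(st_.c2, st_.s1_F, design.rho, design.w2)
        assert out.threshold_F == pytest.approx(thr)
        c2 = critical_value_c2(design.subgroup_test_corr, design.alpha)
        thr_S = conditional_critical_value(c2, W1 * 0.7, design.rho, design.w2)
        st_ = self._stats(z2_S=thr_S)  # exactly at threshold: no rejection
        out = closed_test_decision(st_, InterimDecision.S_ONLY, design)
        assert not out.reject_S and out.tested_S

    def test_closed_testing_blocks_without_intersection(self, design):
        # both individual statistics large but equal and the intersection
        # threshold tuned so the intersection fails -> no rejections
        st_ = self._stats(z1b_F=3.0, z1b_S=3.0, z2_F=2.2, z2_S=2.2)
        out = closed_test_decision(st_, InterimDecision.F_AND_S, design)
        if not out.reject_intersection:
            assert not out.reject_F and not out.reject_S
        else:
            assert out.reject_F == (st_.z2_F > out.threshold_F)

    def test_intersection_required_and_sufficient_parts(self, design):
        st_ = self._stats(z2_F=6.0, z2_S=6.0)
        out = closed_test_decision(st_, InterimDecision.F_AND_S, design)
        assert out.reject_intersection and out.reject_F and out.reject_S
        st_ = self._stats(z2_F=6.0, z2_S=-1.0)
        out = closed_test_decision(st_, InterimDecision.F_AND_S, design)
        assert out.tested_F and out.tested_S
        assert not out.reject_S

    def test_missing_statistics(self, design):
        with pytest.raises(ValueError, match="missing"):
            closed_test_decision(self._stats(), InterimDecision.F_ONLY, design)

    def test_s_statistics_recompute(self):
        st_ = self._stats(z1_F=1.0, z2_F=2.0)
        assert st_.s1_F == pytest.approx(W1 * 0.5)
        assert st_.s2_F == pytest.approx(W1 * 1.0 + W2 * 2.0)
        assert math.isnan(st_.s2_S)


class TestEstimators:
    def test_rho_reasonable_and_deterministic(self, design):
        scens = [make_scenario_fixture(i) for i in (1, 3)]
        r1 = estimate_rho(design, scens, n_sim=120, seed=9)
        r2 = estimate_rho(design, scens, n_sim=120, seed=9)
        assert r1 == r2
        assert 0.6 < r1 < 0.95

    def test_hr_consistency_large_n(self, design):
        scen = make_scenario_fixture(3)
        ds = simulate_cohort(scen, design, "phase3", n_per_arm=10000, seed=60)
        full = ds.observed_at(ds.analysis_time + 600.0)
        hr = estimate_hazard_ratio(full.subset("S"), "F")
        assert hr == pytest.approx(0.7, abs=0.02)

    def test_hr_identical_arms(self, design, scenario1):
        ds = simulate_cohort(scenario1, design, "phase3", n_per_arm=10000, seed=61)
        full = ds.observed_at(ds.analysis_time + 600.0)
        assert estimate_hazard_ratio(full, "F") == pytest.approx(1.0, abs=0.05)

    def test_cox_agrees_with_exponential(self, design, scenario3):
        ds = simulate_cohort(scenario3, design, "phase3", n_per_arm=2000, seed=62)
        full = ds.observed_at(ds.analysis_time + 120.0)
        assert estimate_hazard_ratio(full, "F", "cox") == pytest.approx(
            estimate_hazard_ratio(full, "F", "exponential"), abs=0.03
        )

    def test_hr_no_events(self, design, scenario1):
        ds = simulate_cohort(scenario1, design, "phase2", seed=63)
        ds.df.loc[ds.df["arm"] == 1, "event"] = 0
        with pytest.raises(ZeroVarianceError):
            estimate_hazard_ratio(ds, "F")
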