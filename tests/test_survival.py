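"""Kaplan-Meier, log-rank/O-E hazard ratio, Cox, ROC, Fisher, Dunn and
correlation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats

from ihcsig import (
    SimulationConfig,
    correlation_band,
    cox_fit,
    fisher_2x2,
    group_compare,
    km_estimate,
    logrank_test,
    roc_at_horizon,
    score_correlation,
    simulate_cohort,
)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([2.0, 5.0, 5.0, 8.0, 11.0])
        km = km_estimate(times, np.ones_like(times))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_all_censored_curve_constant_one(self):
        km = km_estimate([3, 6, 9], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        # times (1,2,3), events (1,1,0): S(1)=2/3, S(2)=1/3, S(3)=1/3
        km = km_estimate([1, 2, 3], [1, 1, 0]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(1 / 3)

    def test_at_risk_counts_non_increasing(self):
        km = km_estimate([1, 2, 2, 4, 7], [1, 0, 1, 1, 0])
        assert (np.diff(km["at_risk"]) <= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        lr = logrank_test(t, e, t, e)
        assert lr.chi2 == pytest.approx(0.0, abs=1e-12)
        assert lr.p == pytest.approx(1.0)
        assert lr.hr == pytest.approx(1.0)

    def test_swap_inverts_hr_keeps_p(self):
        rng = np.random.default_rng(0)
        t1, t2 = rng.exponential(10, 30), rng.exponential(20, 30)
        e1, e2 = np.ones(30, int), np.ones(30, int)
        lr = logrank_test(t1, e1, t2, e2)
        sw = logrank_test(t2, e2, t1, e1)
        assert sw.p == pytest.approx(lr.p)
        assert sw.hr == pytest.approx(1 / lr.hr)
        assert lr.swap().hr == pytest.approx(sw.hr)

    def test_matches_lifelines_chi2(self):
        rng = np.random.default_rng(1)
        t1, t2 = rng.exponential(10, 40), rng.exponential(25, 35)
        e1 = (rng.random(40) < 0.8).astype(int)
        e2 = (rng.random(35) < 0.8).astype(int)
        lr = logrank_test(t1, e1, t2, e2)
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert lr.chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert lr.p == pytest.approx(ref.p_value, rel=1e-6)

    def test_exact_permutation_small_n(self):
        """The chi-squared p on a small fixture is consistent with the exact
        permutation distribution of the statistic (within the chi-squared
        approximation's coarseness on n=10)."""
        times = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1])
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        obs = logrank_test(times[labels], events[labels], times[~labels], events[~labels]).chi2
        perm_stats = []
        for idx in itertools.combinations(range(10), 5):
            lab = np.zeros(10, bool)
            lab[list(idx)] = True
            perm_stats.append(
                logrank_test(times[lab], events[lab], times[~lab], events[~lab]).chi2
            )
        p_perm = np.mean(np.array(perm_stats) >= obs - 1e-12)
        p_chi2 = logrank_test(times[labels], events[labels], times[~labels], events[~labels]).p
        assert abs(p_perm - p_chi2) < 0.15

    def test_zero_event_group_flagged(self):
        lr = logrank_test([5, 6, 7], [0, 0, 0], [1, 2, 3], [1, 1, 1])
        assert lr.degenerate
        assert lr.hr == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1], [1])


class TestCox:
    def test_binary_covariate_matches_logrank_hr(self):
        """On a large simulated two-arm cohort the Cox HR and the log-rank
        O/E HR agree within 5%."""
        cohort = simulate_cohort(
            SimulationConfig(
                n_patients=3000, seed=4, effect_hrs={"PTEN": 0.4}, restrict_effects=False,
                signature_hr=None, unknown_marker_rate=0.0,
                missing_rates={},
            )
        )
        high = cohort["high_PTEN"].astype(float)
        cox = cox_fit(cohort["time_months"], cohort["event"], pd.DataFrame({"high": high}))
        lr = logrank_test(
            cohort.loc[high == 1, "time_months"], cohort.loc[high == 1, "event"],
            cohort.loc[high == 0, "time_months"], cohort.loc[high == 0, "event"],
        )
        assert cox.loc["high", "hr"] == pytest.approx(lr.hr, rel=0.05)

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(2)
        cover = 0
        for _ in range(20):
            t = rng.exponential(10, 150)
            e = np.ones(150, int)
            x = rng.random(150) < 0.5
            cox = cox_fit(t, e, pd.DataFrame({"x": x.astype(float)}))
            if cox.loc["x", "hr_lo"] <= 1.0 <= cox.loc["x", "hr_hi"]:
                cover += 1
        assert cover >= 16  # nominal 95%, Monte-Carlo slack

    def test_duplicated_column_rank_error(self):
        x = np.array([0, 1, 0, 1, 1], float)
        with pytest.raises(ValueError, match="rank"):
            cox_fit([1, 2, 3, 4, 5], [1, 1, 1, 1, 0], pd.DataFrame({"a": x, "b": x}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_at_horizon([1, 2, 3, -1, -2, -3], [99, 99, 99, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_constant_score_is_chance(self):
        roc = roc_at_horizon([1] * 6, [99, 99, 99, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_pair_counting(self):
        scores = np.array([3, 1, 2, -1, 0, 2.0])
        times = np.array([80, 70, 20, 10, 90, 15.0])
        events = np.array([0, 0, 1, 1, 0, 1])
        roc = roc_at_horizon(scores, times, events)
        free, rel = scores[events == 0], scores[events == 1]
        pairs = [(a > b) + 0.5 * (a == b) for a in free for b in rel]
        assert roc.auc == pytest.approx(np.mean(pairs))

    def test_sensitivity_specificity_at_signature_cutoff(self):
        scores = np.array([2, 1, -1, 0, 1, -2.0])
        times = np.array([99, 99, 5, 99, 10, 8.0])
        events = np.array([0, 0, 1, 0, 1, 1])
        roc = roc_at_horizon(scores, times, events, cutoff=0.0)
        # relapse-free scores (2,1,0): 2 of 3 above 0; relapsed (-1,1,-2): 2 of 3 <= 0
        assert roc.sensitivity == pytest.approx(2 / 3)
        assert roc.specificity == pytest.approx(2 / 3)

    def test_horizon_excludes_early_censored(self):
        roc = roc_at_horizon([1, 2, 3, 4.0], [10, 70, 20, 30], [0, 0, 1, 1], horizon=60.0)
        assert roc.n_excluded == 1
        roc2 = roc_at_horizon([1, 2, 3, 4.0], [10, 70, 20, 30], [0, 0, 1, 1], horizon=60.0,
                              censored_as_negative=True)
        assert roc2.n_excluded == 0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_at_horizon([1, 2], [5, 6], [0, 0])


class TestContingencyAndCorrelation:
    def test_fisher_extreme_table(self):
        # all-or-nothing 2x2 with margins 5/5: two-sided p = 2/252
        assert fisher_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_fisher_shape_and_sign_checks(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_2x2([[-1, 2], [3, 4]])

    def test_kruskal_matches_scipy_and_dunn_orders_pairs(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        grps = np.repeat(["a", "b", "c"], 30)
        res = group_compare(vals, grps)
        h, p = stats.kruskal(vals[:30], vals[30:60], vals[60:])
        assert res["kruskal_h"] == pytest.approx(h)
        assert res["kruskal_p"] == pytest.approx(p)
        pw = res["pairwise"].set_index(["group_a", "group_b"])
        assert pw.loc[("a", "b"), "p_adj"] > 0.1
        assert pw.loc[("a", "c"), "p_adj"] < 0.001
        assert pw.loc[("b", "c"), "p_adj"] < 0.001

    def test_identical_vectors_r_one(self):
        x = np.arange(10.0)
        r, p, band = score_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert band == "strong"

    @pytest.mark.parametrize("r,band", [(0.3968, "weak"), (0.6559, "moderate"), (0.75, "strong"), (-0.5, "moderate")])
    def test_bands(self, r, band):
        assert correlation_band(r) == band

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_correlation([1, 2, 3], [1, 2])
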