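"""Survival statistics against closed forms and independent implementations."""

import numpy as np
import pytest

import tumorshape as ts
from tumorshape.survival import SurvivalDataError

from conftest import random_survival


class TestKaplanMeier:
    def test_three_events_closed_form(self):
        km = ts.kaplan_meier([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored(self):
        km = ts.kaplan_meier([5.0, 7.0, 9.0], [False, False, False])
        assert np.allclose(km.survival, 1.0)
        assert np.isnan(km.median)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 80) + 0.1
        km = ts.kaplan_meier(t, np.ones(80, bool))
        emp = 1.0 - np.searchsorted(np.sort(t), km.times, side="right") / 80
        assert np.allclose(km.survival, emp, atol=1e-12)

    def test_censoring_at_event_time_counted_at_risk(self):
        # censoring tied with an event at t=2: still at risk for that event
        km = ts.kaplan_meier([1, 2, 2, 3], [True, True, False, True])
        assert np.allclose(km.survival, [3 / 4, 3 / 4 * 2 / 3, 3 / 4 * 2 / 3 * 0])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        for _ in range(10):
            t, e = random_survival(rng, int(rng.integers(5, 60)))
            km = ts.kaplan_meier(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            ref = kmf.survival_function_["KM_estimate"].to_numpy()[1:]
            assert np.allclose(km.survival, ref, atol=1e-9)
            if not np.isnan(km.median):
                assert km.median == pytest.approx(kmf.median_survival_time_)

    def test_empty_input_rejected(self):
        with pytest.raises(SurvivalDataError):
            ts.kaplan_meier([], [])

    def test_curve_invariants(self):
        rng = np.random.default_rng(11)
        t, e = random_survival(rng, 50)
        km = ts.kaplan_meier(t, e)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all(np.diff(km.at_risk) < 0)
        assert km.survival[0] <= 1.0


class TestLogrank:
    def test_identical_groups_null(self):
        t = [3.0, 5.0, 8.0, 13.0]
        e = [True, True, False, True]
        res = ts.logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_events_rejected(self):
        with pytest.raises(SurvivalDataError):
            ts.logrank_test([1, 2], [False, False], [3, 4], [False, False])

    def test_group_label_symmetry(self):
        rng = np.random.default_rng(2)
        ta, ea = random_survival(rng, 30)
        tb, eb = random_survival(rng, 25, scale=150)
        ab = ts.logrank_test(ta, ea, tb, eb)
        ba = ts.logrank_test(tb, eb, ta, ea)
        assert ab.statistic == pytest.approx(ba.statistic, rel=1e-12)

    def test_rank_invariance_under_monotone_time_transform(self):
        rng = np.random.default_rng(4)
        ta, ea = random_survival(rng, 30)
        tb, eb = random_survival(rng, 25, scale=150)
        r1 = ts.logrank_test(ta, ea, tb, eb)
        r2 = ts.logrank_test(np.log1p(ta), ea, np.log1p(tb), eb)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        for _ in range(10):
            ta, ea = random_survival(rng, int(rng.integers(5, 40)))
            tb, eb = random_survival(rng, int(rng.integers(5, 40)), scale=150)
            mine = ts.logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, ea, eb)
            assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_type_one_error_rate(self):
        # equal exponential hazards, n=500 per arm: rejection rate ~ alpha
        rng = np.random.default_rng(12345)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            ta = rng.exponential(100, 500)
            tb = rng.exponential(100, 500)
            ca = rng.uniform(0, 300, 500)
            cb = rng.uniform(0, 300, 500)
            res = ts.logrank_test(np.minimum(ta, ca) + 1e-3, ta <= ca,
                                  np.minimum(tb, cb) + 1e-3, tb <= cb)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestMaxstat:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        idx = np.concatenate([np.full(10, 0.2), np.full(10, 0.9)])
        time = np.concatenate([rng.exponential(30, 10), rng.exponential(800, 10)]) + 1
        res = ts.maxstat_cutpoint(idx, time, np.ones(20, bool),
                                  n_perm=2000, seed=1)
        assert 0.2 < res.cutpoint < 0.9
        assert res.p_value <= 0.01
        assert res.n_candidates == 1

    def test_cutpoint_inside_quantile_band(self):
        rng = np.random.default_rng(5)
        x = rng.random(60)
        t, e = random_survival(rng, 60)
        res = ts.maxstat_cutpoint(x, t, e, min_prop=0.2, n_perm=50, seed=0)
        xs = np.sort(x)
        assert xs[11] <= res.cutpoint <= xs[-12]
        assert res.n_low >= 12 and res.n_high >= 12
        assert res.statistic == pytest.approx(np.max(res.statistics))

    def test_single_candidate_reduces_to_logrank(self):
        # binary index: the maximal statistic IS the plain standardized log-rank
        rng = np.random.default_rng(8)
        x = (rng.random(40) > 0.5).astype(float)
        t, e = random_survival(rng, 40)
        res = ts.maxstat_cutpoint(x, t, e, n_perm=50, seed=0)
        low = x <= res.cutpoint
        lr = ts.logrank_test(t[low], e[low], t[~low], e[~low])
        assert res.statistic**2 == pytest.approx(lr.statistic, rel=1e-9)
        assert res.p_value_naive == pytest.approx(lr.p_value, rel=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(21)
        x = rng.random(30)
        t, e = random_survival(rng, 30)
        r1 = ts.maxstat_cutpoint(x, t, e, n_perm=200, seed=42)
        r2 = ts.maxstat_cutpoint(x, t, e, n_perm=200, seed=42)
        assert (r1.cutpoint, r1.statistic, r1.p_value) == (
            r2.cutpoint, r2.statistic, r2.p_value)
        r3 = ts.maxstat_cutpoint(x, t, e, n_perm=2000, seed=43)
        # different seed: only the Monte-Carlo p moves, and not by much
        assert r3.cutpoint == r1.cutpoint and r3.statistic == r1.statistic
        assert abs(r3.p_value - r1.p_value) < 0.15

    def test_too_few_candidates_error(self):
        t, e = random_survival(np.random.default_rng(1), 12)
        with pytest.raises(SurvivalDataError, match="admissible"):
            ts.maxstat_cutpoint(np.ones(12), t, e, n_perm=10, seed=0)

    def test_too_few_subjects_error(self):
        rng = np.random.default_rng(1)
        with pytest.raises(SurvivalDataError):
            ts.maxstat_cutpoint(rng.random(5), rng.random(5) + 1,
                                np.ones(5, bool), n_perm=10, seed=0)


class TestKendallTauB:
    def test_perfect_concordance_and_reversal(self):
        tau, _ = ts.kendall_tau_b([1, 2, 3, 4], [1, 2, 3, 4])
        assert tau == pytest.approx(1.0)
        tau, _ = ts.kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_matches_bruteforce_pair_counts_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 3, 30).astype(float)
        tau, _ = ts.kendall_tau_b(x, y)
        conc = disc = tie_x = tie_y = 0
        n = len(x)
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    tie_x += 1
                    tie_y += 1
                elif dx == 0:
                    tie_x += 1
                elif dy == 0:
                    tie_y += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        expected = (conc - disc) / np.sqrt((n0 - tie_x) * (n0 - tie_y))
        assert tau == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import kendalltau

        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            x = rng.integers(0, 5, n).astype(float)
            y = np.round(x + rng.normal(0, 2, n))
            tau, p = ts.kendall_tau_b(x, y)
            ref = kendalltau(x, y, method="asymptotic")
            assert tau == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_small_sample_p(self):
        tau, p = ts.kendall_tau_b([1, 2, 3, 4], [1, 2, 3, 4])
        # only identity and full reversal reach |tau| = 1: p = 2/4!
        assert p == pytest.approx(2 / 24)

    def test_all_tied_flagged(self):
        with pytest.warns(UserWarning, match="tied"):
            tau, p = ts.kendall_tau_b([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(tau)


class TestFriedman:
    def test_identical_rows_null(self):
        chi2, p = ts.friedman_test(np.tile([1.0, 1.0, 1.0], (5, 1)))
        assert chi2 == 0.0 and p == 1.0

    def test_strictly_increasing_rows_closed_form(self):
        blocks = np.tile([1.0, 2.0, 3.0], (10, 1)) + np.arange(10)[:, None]
        chi2, p = ts.friedman_test(blocks)
        assert chi2 == pytest.approx(20.0, rel=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import friedmanchisquare

        rng = np.random.default_rng(10)
        for _ in range(10):
            m = rng.normal(size=(int(rng.integers(5, 20)), int(rng.integers(3, 6))))
            if rng.random() < 0.5:
                m = np.round(m)  # force ties
            chi2, p = ts.friedman_test(m)
            ref = friedmanchisquare(*m.T)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_incomplete_rows_dropped_with_warning(self):
        m = np.array([[1.0, 2, 3], [2, 3, 1], [np.nan, 1, 2], [3, 1, 2]])
        with pytest.warns(UserWarning, match="incomplete"):
            chi2, _ = ts.friedman_test(m)
        ref, _ = ts.friedman_test(m[[0, 1, 3]])
        assert chi2 == ref

    def test_too_few_complete_rows(self):
        m = np.array([[1.0, 2, 3], [np.nan, 1, 2]])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ts.friedman_test(m)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert ts.cohen_kappa([0, 1, 2, 0], [0, 1, 2, 0]) == 1.0

    def test_two_by_two_closed_form(self):
        # confusion [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        a = [0] * 25 + [1] * 25
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert ts.cohen_kappa(a, b) == pytest.approx(0.4, rel=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(99)
        a = rng.integers(0, 4, 10000)
        b = rng.integers(0, 4, 10000)
        assert abs(ts.cohen_kappa(a, b)) < 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(14)
        a = rng.integers(0, 3, 200)
        b = np.where(rng.random(200) < 0.6, a, rng.integers(0, 3, 200))
        assert ts.cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b),
                                                     rel=1e-12)

    def test_constant_identical_raters_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(ts.cohen_kappa([1, 1, 1], [1, 1, 1]))
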