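import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import brentq

from crptraj.response import (CutoffResult, EarlyDecline, ResponseCounts,
                              LogisticSeparationError, decline_cox,
                              decline_km_display, early_decline,
                              early_decline_table, fisher_exact, logistic_fit,
                              orr_with_ci, youden_cutoff)
from crptraj.simulate import SimTruth, simulate_cohort, simulate_decline_cohort
from crptraj.survival import CoxDivergenceError


def clopper_pearson_oracle(k, n, level=0.95):
    """Independent CI by inverting the binomial tail sums directly."""
    a = (1 - level) / 2

    def upper_tail(p):  # P(X >= k)
        return sum(stats.binom.pmf(i, n, p) for i in range(k, n + 1))

    def lower_tail(p):  # P(X <= k)
        return sum(stats.binom.pmf(i, n, p) for i in range(0, k + 1))

    lo = 0.0 if k == 0 else brentq(lambda p: upper_tail(p) - a, 1e-12, 1 - 1e-12)
    hi = 1.0 if k == n else brentq(lambda p: lower_tail(p) - a, 1e-12, 1 - 1e-12)
    return lo, hi


class TestOrr:
    def test_study_worked_example(self):
        """2 CR + 16 PR of 90 evaluable: 20% with exact CI rounding to 12-30."""
        res = orr_with_ci(ResponseCounts(18, 90))
        assert res.percent == 20.0
        assert res.rounded() == (20, 12, 30)
        lo, hi = clopper_pearson_oracle(18, 90)
        assert res.ci_low == pytest.approx(100 * lo, abs=1e-6)
        assert res.ci_high == pytest.approx(100 * hi, abs=1e-6)

    def test_boundary_cases(self):
        assert orr_with_ci(ResponseCounts(0, 20)).ci_low == 0.0
        assert orr_with_ci(ResponseCounts(20, 20)).ci_high == 100.0

    @pytest.mark.parametrize("n", [1, 5, 13, 30])
    def test_matches_tail_sum_oracle_all_k(self, n):
        for k in range(n + 1):
            res = orr_with_ci(ResponseCounts(k, n))
            lo, hi = clopper_pearson_oracle(k, n)
            assert res.ci_low == pytest.approx(100 * lo, abs=1e-7)
            assert res.ci_high == pytest.approx(100 * hi, abs=1e-7)
            assert res.ci_low <= res.percent <= res.ci_high

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            ResponseCounts(5, 3)


class TestFisherExact:
    def test_flat_table(self):
        assert fisher_exact(np.array([[1, 1], [1, 1]])) == 1.0

    @pytest.mark.parametrize("table", [
        [[3, 7], [8, 2]], [[1, 9], [11, 3]], [[0, 5], [5, 0]], [[2, 2], [2, 2]],
    ])
    def test_two_by_two_matches_hypergeometric_oracle(self, table):
        mine = fisher_exact(np.array(table))
        ref = stats.fisher_exact(np.array(table))[1]
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_row_and_column_permutation(self):
        t = np.array([[5, 3, 2, 1], [5, 7, 8, 9]])
        p = fisher_exact(t)
        assert fisher_exact(t[::-1]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact(t[:, [2, 0, 3, 1]]) == pytest.approx(p, abs=1e-12)

    def test_enumeration_matches_monte_carlo(self):
        t = np.array([[5, 3, 2, 1], [5, 7, 8, 9]])
        exact = fisher_exact(t)
        mc = fisher_exact(t, max_exact_n=0, n_mc=200_000, seed=3)
        assert abs(exact - mc) < 0.01

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[1, -1], [1, 1]]))
        with pytest.raises(ValueError):
            fisher_exact(np.ones((3, 2), int))


class TestLogistic:
    def test_saturated_two_by_two_closed_form(self):
        # responders: 5 of 10 at x=1; 2 of 10 at x=0 -> OR = (5*8)/(5*2) = 4
        df = pd.DataFrame({"y": [1] * 5 + [0] * 5 + [1] * 2 + [0] * 8,
                           "x": [1.0] * 10 + [0.0] * 10})
        ests, _ = logistic_fit(df, "y", ["x"])
        assert ests[0].point == pytest.approx(4.0, rel=1e-6)

    def test_complete_separation_raises(self):
        df = pd.DataFrame({"y": [0, 0, 0, 1, 1, 1],
                           "x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        with pytest.raises(LogisticSeparationError):
            logistic_fit(df, "y", ["x"])


class TestEarlyDecline:
    def test_window_definition(self):
        ed = early_decline(np.array([-3, 10, 30]), np.array([50, 40, 60.0]), 50.0)
        assert ed.decline_pct == 20.0 and ed.evaluable

    def test_increase_only_floored_at_zero(self):
        ed = early_decline(np.array([10, 40]), np.array([55, 70.0]), 50.0)
        assert ed.decline_pct == 0.0

    def test_no_measurement_in_window_inevaluable(self):
        ed = early_decline(np.array([-5, 60]), np.array([50, 10.0]), 50.0)
        assert not ed.evaluable and np.isnan(ed.decline_pct)

    def test_day_56_is_inside_day_57_outside(self):
        assert early_decline(np.array([56]), np.array([25.0]), 50.0).decline_pct == 50.0
        assert not early_decline(np.array([57]), np.array([25.0]), 50.0).evaluable

    @given(st.lists(st.tuples(st.integers(1, 56), st.floats(0.3, 350.0)),
                    min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_invariance_to_order_and_outside_window_points(self, pairs):
        t = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        ref = early_decline(t, v, 50.0).decline_pct
        perm = np.random.default_rng(0).permutation(len(t))
        extra_t = np.r_[t[perm], [-10, 70]]
        extra_v = np.r_[v[perm], [0.5, 0.5]]
        assert early_decline(extra_t, extra_v, 50.0).decline_pct == \
            pytest.approx(ref)

    def test_table_from_cohort(self, default_cohort):
        _, cohort = default_cohort
        tab = early_decline_table(cohort)
        assert len(tab) == cohort.n_patients
        ok = tab["evaluable"]
        assert (tab.loc[ok, "decline_pct"] >= 0).all()
        assert (tab.loc[ok, "decline_pct"] <= 100).all()


class TestYouden:
    def test_perfect_separation(self):
        res = youden_cutoff(np.array([1.0, 2, 3, 4]),
                            np.array([0, 0, 1, 1], bool))
        assert res.cutoff == 2.5 and res.youden_j == 1.0

    def test_matches_brute_force_on_fixture(self, rng):
        marker = rng.normal(size=20)
        outcome = rng.random(20) < 0.5
        if outcome.all() or (~outcome).all():
            outcome[0] = not outcome[0]
        res = youden_cutoff(marker, outcome)
        # brute force over a fine threshold grid
        best_j = -2
        for c in np.linspace(marker.min() - 1, marker.max() + 1, 5001):
            pred = marker >= c
            sens = (pred & outcome).sum() / outcome.sum()
            spec = (~pred & ~outcome).sum() / (~outcome).sum()
            best_j = max(best_j, sens + spec - 1)
        assert res.youden_j == pytest.approx(best_j, abs=1e-9)

    def test_tie_breaks_toward_smaller_cutoff(self):
        res = youden_cutoff(np.array([1.0, 2.0, 3.0, 4.0]),
                            np.array([0, 1, 0, 1], bool))
        # J = 0.5 at cutoffs 1.5 and 3.5; the smaller wins
        assert res.cutoff == 1.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff(np.array([1.0, 2.0]), np.array([1, 1], bool))


class TestDeclineCox:
    def test_degenerate_decline_flagged(self):
        tab = pd.DataFrame({"patient_id": list("abcd"),
                            "decline_pct": [0.0] * 4, "evaluable": True})
        ep = pd.DataFrame({"patient_id": list("abcd"),
                           "time_months": [1.0, 2, 3, 4],
                           "event": [True, True, False, True]})
        with pytest.raises(CoxDivergenceError):
            decline_cox(tab, ep)

    def test_protective_effect_recovered(self):
        df = simulate_decline_cohort(600, seed=5, hr_per_10pct=0.91)
        est, fit = decline_cox(df[["patient_id", "decline_pct", "evaluable"]],
                               df[["patient_id", "time_months", "event"]])
        assert est.ci_low <= 0.91 <= est.ci_high

    def test_landmark_variant_restricts_and_rebases(self):
        df = simulate_decline_cohort(300, seed=6)
        est, fit = decline_cox(df[["patient_id", "decline_pct", "evaluable"]],
                               df[["patient_id", "time_months", "event"]],
                               landmark_weeks=8.0)
        lm = 8.0 * 7.0 / 30.4375
        n_expected = (df["time_months"] > lm).sum()
        assert fit.n == n_expected
        assert fit.data["time_months"].min() > 0

    def test_km_display_runs(self):
        df = simulate_decline_cohort(200, seed=7)
        disp = decline_km_display(df[["patient_id", "decline_pct", "evaluable"]],
                                  df[["patient_id", "time_months", "event"]],
                                  cutoff_pct=15.6)
        assert set(disp["curves"]) == {"decline>=cutoff", "decline<cutoff"}
        assert 0 <= disp["p"] <= 1
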