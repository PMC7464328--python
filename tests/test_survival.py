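import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from crptraj.simulate import simulate_baseline_cohort
from crptraj.survival import (CoxDivergenceError, SurvivalInputError, cox_fit,
                              km_fit, logrank_test, reverse_km_followup,
                              schoenfeld_ph_test, wald_estimate)


def brute_force_km(time, event):
    """Independent product-limit oracle: explicit product over risk sets."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event])):
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & event)
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


class TestKaplanMeier:
    def test_hand_worked_three_events(self):
        km = km_fit([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_fit([1.0, 2.0, 3.0], [False, False, False])
        assert km.survival_at(3.0) == 1.0
        assert np.isinf(km.median)      # median undefined

    def test_matches_brute_force_oracle_mixed_fixture(self):
        time = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        event = [True, False, True, True, False, True]
        km = km_fit(time, event)
        t_ref, s_ref = brute_force_km(time, event)
        np.testing.assert_allclose(km.times, t_ref)
        np.testing.assert_allclose(km.survival, s_ref, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(5.0, 40).round(2) + 0.01
        km = km_fit(time, np.ones(40, bool))
        for t in km.times:
            assert abs(km.survival_at(t) - np.mean(time > t)) < 1e-12

    def test_greenwood_variance_nonnegative_increasing_cumulative(self):
        km = km_fit([1, 2, 3, 4, 5.0], [1, 1, 0, 1, 1])
        assert (km.variance >= 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(SurvivalInputError):
            km_fit([], [])


class TestReverseKm:
    def test_reduces_to_km_of_censor_times(self):
        med, _ = reverse_km_followup([1.0, 2.0, 3.0], [False, False, False])
        assert med == 2.0

    def test_all_events_followup_undefined(self):
        med, _ = reverse_km_followup([1.0, 2.0, 3.0], [True, True, True])
        assert np.isinf(med)

    def test_administrative_censoring_recovered(self):
        df = simulate_baseline_cohort(400, seed=4, censor_rate=0.002)
        med, _ = reverse_km_followup(df["time_months"].to_numpy(),
                                     df["event"].to_numpy())
        assert abs(med - 24.0) < 0.5


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.r_[[1, 2, 3, 4.0], [1, 2, 3, 4.0]]
        event = np.r_[[1, 1, 0, 1], [1, 1, 0, 1]].astype(bool)
        group = np.r_[["a"] * 4, ["b"] * 4]
        chi2, df, p = logrank_test(time, event, group)
        assert chi2 < 1e-10 and df == 1 and p > 0.999

    def test_four_groups_df_three(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(5, 80)
        event = rng.random(80) < 0.8
        group = np.repeat(["Q1", "Q2", "Q3", "Q4"], 20)
        _, df, _ = logrank_test(time, event, group)
        assert df == 3

    def test_empty_group_rejected(self):
        with pytest.raises(SurvivalInputError):
            logrank_test([1.0], [True], ["a"])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 200
        for _ in range(reps):
            time = rng.exponential(5, 80)
            event = rng.random(80) < 0.8
            group = np.repeat(["a", "b"], 40)
            _, _, p = logrank_test(time, event, group)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.10


def efron_free_partial_loglik(beta, time, event, x):
    """Partial likelihood for untied data (Efron == Breslow there)."""
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


class TestCox:
    # six subjects, distinct event times, one binary covariate
    TOY = pd.DataFrame({
        "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [True, True, False, True, True, False],
        "x": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
    })

    def test_toy_matches_brute_force_maximizer(self):
        fit = cox_fit(self.TOY, ["x"])
        t = self.TOY["time_months"].to_numpy()
        e = self.TOY["event"].to_numpy()
        x = self.TOY["x"].to_numpy()
        res = minimize_scalar(lambda b: -efron_free_partial_loglik(b, t, e, x),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert abs(fit.coef[0] - res.x) < 1e-5

    def test_mirrored_groups_give_zero_effect(self):
        df = pd.concat([self.TOY, self.TOY.assign(x=1.0 - self.TOY["x"])],
                       ignore_index=True)
        fit = cox_fit(df, ["x"])
        assert abs(fit.coef[0]) < 1e-6

    def test_translation_invariance_and_scaling_equivariance(self):
        df = simulate_baseline_cohort(200, seed=5, log_hr_per_unit=0.3)
        base = cox_fit(df, ["x"])
        shifted = cox_fit(df.assign(x=df["x"] + 7.0), ["x"])
        scaled = cox_fit(df.assign(x=df["x"] * 2.0), ["x"])
        assert abs(base.coef[0] - shifted.coef[0]) < 1e-5
        assert abs(base.coef[0] - 2.0 * scaled.coef[0]) < 1e-5

    def test_efron_breslow_agree_without_ties(self):
        df = simulate_baseline_cohort(150, seed=6, log_hr_per_unit=0.3)
        ev = df.loc[df["event"], "time_months"]
        assert ev.nunique() == len(ev)
        efron = cox_fit(df, ["x"], ties="efron")
        breslow = cox_fit(df, ["x"], ties="breslow")
        assert abs(efron.coef[0] - breslow.coef[0]) < 1e-4

    def test_wald_ci_covers_generating_hazard_ratio(self):
        covered = 0
        for s in range(10):
            df = simulate_baseline_cohort(500, seed=40 + s,
                                          log_hr_per_unit=np.log(1.4))
            e = cox_fit(df, ["x"]).estimates[0]
            covered += e.ci_low <= 1.4 <= e.ci_high
        assert covered >= 8

    def test_monotone_likelihood_raises(self):
        df = pd.DataFrame({
            "time_months": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [True, True, True, False, False, False],
            "x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
        })
        with pytest.raises(CoxDivergenceError):
            cox_fit(df, ["x"])

    def test_no_events_rejected(self):
        df = self.TOY.assign(event=False)
        with pytest.raises(SurvivalInputError):
            cox_fit(df, ["x"])


class TestSchoenfeld:
    def test_single_covariate_global_equals_covariate(self):
        df = simulate_baseline_cohort(200, seed=8, log_hr_per_unit=0.3)
        tab = schoenfeld_ph_test(cox_fit(df, ["x"]))
        assert abs(tab.iloc[0]["p"] - tab.iloc[-1]["p"]) < 1e-12

    def test_calibration_under_proportional_hazards(self):
        rej = 0
        reps = 60
        for s in range(reps):
            df = simulate_baseline_cohort(250, seed=900 + s,
                                          log_hr_per_unit=np.log(1.4))
            p = schoenfeld_ph_test(cox_fit(df, ["x"])).iloc[0]["p"]
            rej += p < 0.05
        assert rej <= 9          # ~5% nominal; allow sampling slack

    def test_power_against_decaying_hazard_ratio(self):
        """A hazard ratio shrinking 0.57-fold per year must be detected in
        most cohorts of 300."""
        rej = 0
        for s in range(10):
            df = simulate_baseline_cohort(300, seed=950 + s,
                                          log_hr_per_unit=np.log(1.41),
                                          hr_decay_per_year=0.57)
            p = schoenfeld_ph_test(cox_fit(df, ["x"])).iloc[0]["p"]
            rej += p < 0.05
        assert rej >= 6

    def test_km_transform_available(self):
        df = simulate_baseline_cohort(200, seed=10, log_hr_per_unit=0.3)
        tab = schoenfeld_ph_test(cox_fit(df, ["x"]), transform="km")
        assert 0.0 <= tab.iloc[0]["p"] <= 1.0

    def test_fewer_events_than_covariates_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": [True, False],
                           "x": [0.0, 1.0], "z": [1.0, 0.0]})
        with pytest.raises((SurvivalInputError, CoxDivergenceError)):
            schoenfeld_ph_test(cox_fit(df, ["x", "z"]))


def test_effect_estimate_validates_ci():
    with pytest.raises(ValueError):
        from crptraj.survival import EffectEstimate
        EffectEstimate("bad", "HR", 2.0, 2.5, 3.0, 0.5)
    e = wald_estimate("hr", np.log(2.0), 0.1)
    assert e.ci_low < 2.0 < e.ci_high
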