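# crptraj

Statistical toolkit for evaluating C-reactive protein (CRP) — at treatment
start and longitudinally — as a biomarker of immune-checkpoint-inhibitor
(ICI) outcome in advanced non-small cell lung cancer, exercised end to end
on synthetic cohorts.

Patients starting anti PD-(L)1 therapy have frequent routine CRP
measurements (mg/L). Two clinical questions drive the package:

1. **Is pretreatment CRP prognostic?** Baseline CRP (the draw within 14 days
   before the start date closest to it) enters Kaplan–Meier / log-rank
   analyses by quartile (cutoffs 7.7 / 21.6 / 66.1 mg/L), Cox models per
   doubling (log2 CRP), Schoenfeld proportional-hazards diagnostics, and —
   when proportionality fails — a flexible parametric model on the
   log cumulative-hazard scale with a linear-in-time covariate effect.
   Response analyses use exact binomial (Clopper–Pearson) intervals,
   Fisher's exact test and logistic regression.

2. **Does the CRP *trajectory* carry risk information?** The core model is a
   joint model of longitudinal and time-to-event data: a linear mixed model
   for the CRP trajectory m_i(t) (polynomial time, random intercept or
   intercept + slope, AIC-selected degree) is linked to a Weibull
   proportional-hazards submodel through an association parameter α:

       h_i(t | b_i) = λ κ t^{κ-1} exp( γ'w_i + α_v m_i(t) + α_s m_i'(t) )

   with b_i ~ N(0, D) shared between submodels. The marginal likelihood
   integrates b_i out by adaptive (posterior-centered) Gauss–Hermite
   quadrature; the reported effect is the hazard ratio per 10 mg/L of
   current CRP, exp(10 α_v), or per 10 mg/L/month of CRP slope. A fitted
   model yields personalized *dynamic predictions*: the probability of a
   progression event within Δ months given survival to the landmark t and
   the patient's own CRP history,
   π(t, Δ) = 1 − E[S_i(t+Δ|b)/S_i(t|b) | history].

   An exploratory statistic, the **early CRP decline** (maximum percent
   decrease from baseline in the first 8 weeks, floored at 0 for patients
   whose CRP only rises), is related to progression-free survival with a
   Cox model per 10% decline and dichotomized with a Youden-index cutoff.

Real patient-level data for this setting are not shareable, so the package
ships a first-class synthetic-cohort generator (`crptraj.simulate`) that
draws cohorts from the joint model's exact generative assumptions — with
known truth attached — plus focused generators for the cross-sectional
analyses. All estimators are validated by recovery of those truths.

## Worked example

```python
import numpy as np
from crptraj import (SimTruth, simulate_cohort, JointSpec, build_model,
                     fit_joint, hr_per_unit, predict_risk)
from crptraj.cohort import DAYS_PER_MONTH

truth = SimTruth(n_patients=300, seed=42, kappa=1.1, alpha_value=0.0157)
cohort = simulate_cohort(truth)          # 300 patients, ~13 CRP draws each

fit = fit_joint(build_model(cohort, JointSpec()))
est = hr_per_unit(fit, "value", 10.0)
print(f"HR per 10 mg/L: {est.point:.3f} ({est.ci_low:.3f}-{est.ci_high:.3f})")

pid = cohort.endpoints("PFS").query("time_months > 9").patient_id.iloc[0]
hist = cohort.patient_measurements(pid).assign(
    time_months=lambda d: d.time_days / DAYS_PER_MONTH)
risk = predict_risk(fit, hist, t=6.0, delta=3.0)
print(f"3-month risk at the 6-month landmark for {pid}: {risk.risk:.2f}")
```

Output:

```
HR per 10 mg/L: 1.083 (0.954-1.230)
3-month risk at the 6-month landmark for P0009: 0.48
```

The first line is the joint-model hazard ratio per 10 mg/L of current CRP
with its Wald CI (the generating value is exp(10·0.0157) ≈ 1.17; a single
cohort of 300 estimates it with an SE of about 0.006 on the α scale). The
second is a personalized dynamic prediction: given this patient's CRP
history up to month 6 and being event-free there, the chance of progressing
within the next three months.

A shell interface covers the same pipeline:

```bash
crptraj simulate --seed 7 --n 200 --out cohort/
crptraj all --baseline cohort/baseline.csv --labs cohort/labs.csv --out results/
crptraj predict --baseline cohort/baseline.csv --labs cohort/labs.csv \
        --patient P0009 --landmark 6 --horizon 3
```

`crptraj all` writes `report.txt`, machine-readable estimate tables
(`baseline_cox.csv`, `joint_estimates.csv`, `early_decline.csv`, ...) and
figure files (KM by quartile, trajectory spaghetti with inverted time axis,
risk profiles, decline KM).

## Input formats

Delimited text. Baseline: one row per patient with columns `patient_id,
start_day, age_years, sex, stage_iv_at_dx, treatment_line, response, nlr,
ldh, lipi` plus outcome columns `progression_months, death_months,
last_contact_months` (empty cell = missing). Labs: `patient_id, time_days,
crp_mg_per_l` with `time_days` relative to ICI start (negative = before).
CRP values must lie in the assay quantification range 0.3–350 mg/L; PFS/OS
are truncated administratively at 24 months.

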