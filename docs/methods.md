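# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `crptraj`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and deterministic derivations

Time is stored in integer days relative to ICI start (day 0) and converted
to months with the fixed divisor 30.4375 so conversions are bit-for-bit
reproducible. CRP is in mg/L; values outside the assay quantification range
[0.3, 350] are rejected at load (never clamped) because an out-of-range
value in an input file indicates a data error, while the generator models
the range explicitly.

* **Baseline CRP** is the measurement in the window [−14, 0] days closest to
  the start date. Day 0 is included: the window is described as "within 14
  days prior", which does not address same-day draws; including them
  maximizes usable baselines and is the package's documented choice.
* **Endpoints.** PFS event = progression or death, whichever first (death
  without documented progression counts as a PFS event at the death date,
  the standard PFS convention); OS event = death. Otherwise censoring at
  last contact; any time beyond 24 months is administratively censored at
  24. Outcome times ride along as optional columns of the baseline file.
* **Quartiles** use closed upper bounds (value ≤ cutoff → lower category)
  with default cutoffs 7.7 / 21.6 / 66.1 mg/L, reusable unchanged on an
  external cohort.
* **Complete cases** are formed per analysis: each operation drops only the
  patients missing a variable that that analysis uses.

## Synthetic-cohort generator

`simulate_cohort` draws from exactly the generative model the joint model
assumes: latent trajectory m_i(t) = β₀ + β₁t (+ β₂t² + β₃t³) + b₀ᵢ (+ b₁ᵢt)
with bᵢ ~ N(0, D); hazard λκt^{κ−1}·exp(γ'wᵢ + α_v m_i(t) + α_s m_i′(t));
event times by inverting the cumulative hazard with bracketed root-finding
(Brent on [1e−9, 240] months, cumulative hazard by 60-point Gauss–Legendre);
independent exponential censoring plus administrative censoring at 24
months; visits at a baseline draw in [−14, 0] days then every 14 ± 3 days
(uniform jitter) until the endpoint; observed CRP = m_i(t) + ε clipped to
[0.3, 350], ε ~ N(0, σ²). Clamp events are counted and are <1% under the
defaults.

Defaults (β₀ = 30 mg/L, β₁ = 2 mg/L/month, sd(b₀) = 10, σ = 7, λ = 0.07,
κ = 1.1, α_v = 0.0157/mg/L, censor rate 0.03/month, 14-day spacing) were
chosen once so that the simulated cohorts match the study conditions the
estimators face: median PFS ≈ 4–5 months, roughly 13 CRP draws per patient
with a 1–54 range, and a per-10 mg/L hazard ratio of exp(10·0.0157) ≈ 1.17.
The association scale, visit-count range and quartile anchors are the
printed study values; the variance components are the package's own
realistic choices.

What the generator does **not** emulate: the raw-scale Gaussian random
intercept makes the implied baseline-CRP distribution symmetric, so it
cannot reproduce the strongly right-skewed observed distribution whose
quartiles are 7.7/21.6/66.1 mg/L. For the cross-sectional analyses
(per-doubling Cox/logistic, quartile displays) a lognormal baseline sampler
matched to those quartiles is provided instead. There is also no
outcome-dependent visit scheduling ("sicker measured more often") beyond
truncation at the event, and no left-censoring of values below a reporting
threshold. Passing recovery tests therefore show correctness of the
estimators under the model's own assumptions, not robustness to real-data
features outside them.

Dedicated generators cover the remaining designs: `simulate_tvc_cohort`
draws from the log-cumulative-hazard model with a linear-in-time binary
covariate effect (κ = 1.2 keeps the implied hazard positive over the whole
24-month window, making it a valid distribution whose time-interaction
parameter the flexible parametric fit estimates with no parameterization
gap); `simulate_baseline_cohort` provides a hazard-scale time-decaying
effect for Schoenfeld power checks; `simulate_decline_cohort` gives
early-decline data with a known protective hazard ratio.

## Baseline survival machinery

KM estimation, the reverse-KM follow-up estimate, log-rank tests and the
Efron-ties Cox model delegate to lifelines (Breslow ties to statsmodels
PHReg); Greenwood variances and the Grambsch–Therneau proportional-hazards
test are computed in-package from lifelines' Schoenfeld residuals. The PH
test regresses residuals on a transform of event time — identity on
analysis time by default, matching the linear-in-time interaction used in
the validation analysis; a KM transform is available by flag. The global
statistic is the score form m/(g'g)·U'VU with U the residual-weighted
centered transform and V the coefficient covariance; with one covariate it
reduces exactly to the per-covariate test. Medians and their CIs come from
inverting the log(−log) confidence band (Brookmeyer–Crowley style). Ties:
Efron by default for its better small-sample behavior.

## Flexible parametric model

log H(t|x) = s(log t) + β'x + θ·x·(t/12), with s a restricted cubic spline
(Durrleman–Simon basis; default 3 interior knots at the 25/50/75 percentiles
of uncensored log event times, boundary knots at the extremes). Reported
quantities are exp(β) (effect at t = 0) and exp(θ) (multiplicative change
per year). The log-hazard term log(dη/dt) uses a softplus floor (sharpness
1000) so the likelihood stays smooth when the optimizer visits a negative
hazard; maximization is L-BFGS-B followed by a BFGS polish, SEs from a
central-difference Hessian. Positivity of the implied hazard is enforced on
the baseline-hazard grid and at every observed event; with a negative time
interaction the model genuinely implies a negative hazard at covariate/time
combinations far outside the data, which are deliberately not constrained.
If the check fails the fit is retried with fewer knots before erroring.

## Linear mixed models

ML (not REML), because the AIC comparison across fixed-effect time
specifications (degrees 1–3) requires likelihoods comparable across mean
structures. Fitting delegates to statsmodels MixedLM (falling back from
L-BFGS to Powell/Nelder–Mead when a variance component sits on the
boundary); an independent closed-form evaluator of the marginal likelihood
(per-patient multivariate-normal density via Woodbury) serves as the oracle
and is reused by the joint model. CRP is modeled on the raw mg/L scale so
the joint-model effects are per-mg/L; log-scale smoothing (LOWESS,
tricube local linear via statsmodels) is used for trajectory displays with
an optional inverted time axis (time before event/censoring). The default
random-effects structure is a random intercept; a slope association
downstream requires intercept + slope with unstructured 2×2 D.

## Joint model

The marginal likelihood multiplies, per patient, the longitudinal Gaussian
density, the event/censoring contribution h^δ·exp(−H), and the N(0, D)
prior, integrated over b. Numerics:

* **Pseudo-adaptive Gauss–Hermite.** The Gaussian longitudinal posterior of
  b given the patient's measurements is available in closed form, so the
  integrand is rewritten as (marginal LMM density) × (survival factor)
  against that posterior, and 9-node (tensorized 9×9 for two random
  effects) Gauss–Hermite quadrature centered and scaled at it absorbs only
  the smooth survival factor. At α = 0 the survival factor is constant in b
  and the scheme is *exact* for any node count — the factorization identity
  the tests assert to 1e−6. Node count is a configuration knob checked by a
  refinement test (9→15 nodes moves the log-likelihood by <1e−3 on a
  300-patient cohort).
* **Cumulative hazard** by per-patient Gauss–Legendre (default 15 points)
  after the substitution u = t^κ, which integrates the Weibull baseline
  exactly and removes the t^{κ−1} endpoint singularity.
* **Parameterization** log λ, log κ, log σ and the Cholesky factor of D
  (log-diagonal), so the optimizer's domain is unconstrained and D cannot
  leave the PSD cone.
* **Optimization** L-BFGS-B from a warm start (separate LMM and Weibull
  fits, α = 0) with a BFGS polish; convergence requires a scaled gradient
  norm < 1e−4. SEs come from the central-difference observed information;
  a non-positive-definite Hessian withholds SEs rather than failing.
  Non-finite likelihood values at wild line-search excursions are mapped to
  a large finite penalty.

Association variants: current value, slope ("1st derivative"), or both.
The slope-only variant is the sensitivity specification; whether a
published "1st derivative" model retains the current-value term is
ambiguous, so both are available and labeled. Time inside the model is
months; slope effects are reported per 10 mg/L/month (a printed unit of
"mg/mL/month" in the source literature is read as a typographical slip for
mg/L/month). All patients enter at t = 0 (no left truncation).

## Dynamic prediction

π(t, Δ) = 1 − E[S(t+Δ|b)/S(t|b)] with the expectation over the posterior of
b given the history up to t *and* survival to t. `posterior_effects`
maximizes that posterior (BFGS from the closed-form longitudinal posterior
mean) and returns mode and curvature. The default plug-in evaluates the
ratio at the mode (fast, deterministic); a fixed-seed Monte-Carlo average
over the normal approximation quantifies the plug-in error — the two agree
within 0.02 on test cohorts, which is the package's internal standard since
no reference implementation of this prediction rule is available to copy.
Measurements after the landmark are ignored by construction. The landmark
defaults to the last visit in the CLI. The risk definition conditions on
being event-free at t with no window-censoring adjustment inside (t, t+Δ].

## Early decline and cutoff selection

EarlyΔCRPmax = max over (0, 56] days of 100·(baseline − CRP(t))/baseline,
floored at 0; patients without a post-baseline draw in the window are
inevaluable. The Cox analysis reports the hazard ratio per 10% decline. The
accompanying dichotomized KM display uses a Youden-index cutoff scanned
over midpoints between adjacent distinct observed values (ties broken
toward the smaller cutoff). Because the decline is computed over the first
8 weeks while follow-up starts at ICI initiation, the dichotomized analysis
carries a guarantee-time bias; an optional week-8 landmark variant
restricts to patients event-free at 8 weeks and restarts the clock there.
For ROC-style cutoff selection the outcome is the PFS event indicator
within the truncated 2-year window, ignoring censoring time — a documented
simplification; an event-by-horizon variant can be formed by the caller.

## Exact small-sample inference

Clopper–Pearson intervals (scipy's binomial-test inversion) are the exact
method because they reproduce the worked response-rate example; mid-P or
Wilson intervals do not. Fisher's exact test enumerates all 2×K tables with
the observed margins (multivariate hypergeometric probabilities, ties at
the observed probability included with 1e−9 relative tolerance) for totals
up to 200, beyond which a fixed-seed Monte-Carlo over margin-preserving
permutations takes over.

## Problem sizes in the committed tests

The committed recovery tests run scaled-down replicate counts chosen as the
package's own balance of precision against runtime: 20 replicates (n = 300)
for current-value recovery with bounds widened accordingly (MAE ≤ 0.008,
coverage ≥ 80%), 10 replicates (n = 400) for the slope and time-interaction
recoveries, 50 for the Wald-test size (bounds 1–11%), 20 (n = 600) for the
early-decline recovery. `scripts/acceptance.py` uses similar sizes and
derives every seed from its `--seed` argument.

## Known limitations

* No Bayesian estimation, competing risks, frailty terms, left truncation,
  multi-biomarker joint models, or serial within-patient correlation
  (AR(1)) in the LMM.
* The flexible parametric time interaction is linear on the
  log-cumulative-hazard linear predictor; equivalence with other software's
  internal parameterization of time-dependent effects is not claimed, only
  the reported quantities (effect at t = 0 and per-year multiplier).
* Joint-model SEs are Wald-type from numerical observed information;
  profile-likelihood intervals are not implemented.
* The generator's visit process is calibrated only to the printed
  per-patient measurement-count range; the real scheduling mechanism is
  unknown.
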