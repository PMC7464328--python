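"""Synthetic cohorts drawn from the joint model's own generative assumptions.

The generator produces exactly the data structure the downstream stages
consume: a per-patient baseline table, a long-format CRP series sampled on a
visit schedule, and event/censoring times drawn from a Weibull proportional
hazards model whose hazard depends on the current value (and/or slope) of the
latent patient-level trajectory

    m_i(t) = beta0 + beta1 t (+ beta2 t^2 + beta3 t^3) + b0_i (+ b1_i t),

with t in months, random effects b_i ~ N(0, D), Gaussian residuals on the
observed CRP, independent exponential censoring, and administrative censoring
at 24 months.  Every parameter is carried in a :class:`SimTruth` so recovery
tests can compare estimates against the generating values.

Because the latent trajectory is Gaussian on the raw mg/L scale, the implied
baseline-CRP distribution is symmetric; a lognormal baseline sampler matched
to the observed quartile cutoffs (7.7 / 21.6 / 66.1 mg/L) is provided for the
cross-sectional analyses where a right-skewed marker is the realistic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import (CohortTable, CRP_LOWER, CRP_UPPER, DAYS_PER_MONTH,
                     TRUNCATION_MONTHS)

_MAX_LINPRED = 50.0

from functools import lru_cache


@lru_cache(maxsize=8)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


@dataclass
class SimTruth:
    """Generating parameters for one synthetic cohort.

    Units: fixed effects in mg/L (per month^k for the time powers); D in
    (mg/L)^2 and (mg/L/month)^2; Weibull scale ``lam`` per month^kappa;
    ``alpha_value`` per mg/L and ``alpha_slope`` per (mg/L/month);
    ``censor_rate`` per month; ``visit_spacing_days`` in days.
    """

    n_patients: int = 90
    beta: tuple[float, ...] = (30.0, 2.0)          # intercept, slope [, quad, cubic]
    D: tuple[tuple[float, ...], ...] = ((100.0,),)  # 1x1 or 2x2
    sigma: float = 7.0
    lam: float = 0.07
    kappa: float = 1.1
    gamma: dict = field(default_factory=dict)       # covariate name -> coefficient
    alpha_value: float = 0.0157
    alpha_slope: float = 0.0
    censor_rate: float = 0.03
    visit_spacing_days: float = 14.0
    visit_jitter_days: float = 3.0
    detection_floor: float = CRP_LOWER
    detection_ceiling: float = CRP_UPPER
    ne_fraction: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] not in (1, 2):
            raise ValueError("D must be 1x1 or 2x2")
        if not np.allclose(D, D.T):
            raise ValueError("D must be symmetric")
        if np.linalg.eigvalsh(D).min() < -1e-10:
            raise ValueError("D must be positive semidefinite")
        if self.sigma <= 0 or self.lam <= 0 or self.kappa <= 0:
            raise ValueError("sigma, lam and kappa must be positive")
        if len(self.beta) < 2 or len(self.beta) > 4:
            raise ValueError("beta must have 2-4 components (degree 1-3)")

    @property
    def degree(self) -> int:
        return len(self.beta) - 1

    def as_dict(self) -> dict:
        return asdict(self)


def _trajectory(beta: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    """m_i(t) for one patient: polynomial fixed part plus random effects."""
    m = np.polyval(beta[::-1], t) + b[0]
    if len(b) > 1:
        m = m + b[1] * t
    return m


def _trajectory_slope(beta: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    dcoef = np.array([k * beta[k] for k in range(1, len(beta))])
    s = np.polyval(dcoef[::-1], t) if len(dcoef) else np.zeros_like(t)
    if len(b) > 1:
        s = s + b[1]
    return s


def _cumhaz(t: float, truth: SimTruth, b: np.ndarray, loggw: float,
            n_nodes: int = 60) -> float:
    """Cumulative hazard H_i(t) by Gauss-Legendre quadrature on [0, t]."""
    if t <= 0:
        return 0.0
    x, w = _leggauss(n_nodes)
    u = 0.5 * t * (x + 1.0)
    beta = np.asarray(truth.beta, dtype=float)
    lp = (loggw
          + truth.alpha_value * _trajectory(beta, b, u)
          + truth.alpha_slope * _trajectory_slope(beta, b, u))
    h = truth.lam * truth.kappa * u ** (truth.kappa - 1.0) * np.exp(np.clip(lp, -700, 700))
    return float(0.5 * t * np.dot(w, h))


def _draw_event_time(truth: SimTruth, b: np.ndarray, loggw: float,
                     u: float, t_max: float = 240.0) -> float:
    """Invert H(T) = -log(u) by bracketed root-finding; returns inf when the
    target is not reached by t_max (the event is then censored anyway)."""
    target = -np.log(u)
    if _cumhaz(t_max, truth, b, loggw) < target:
        return np.inf
    return brentq(lambda t: _cumhaz(t, truth, b, loggw) - target, 1e-9, t_max,
                  xtol=1e-8, rtol=1e-10)


def lognormal_baseline_crp(n: int, rng: np.random.Generator,
                           median: float = 21.6, sigma_log: float = 1.6) -> np.ndarray:
    """Right-skewed baseline CRP with quartiles near 7.7 / 21.6 / 66.1 mg/L,
    clipped to the assay quantification range."""
    x = np.exp(np.log(median) + sigma_log * rng.standard_normal(n))
    return np.clip(x, CRP_LOWER, CRP_UPPER)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline demographics with marginals near the discovery cohort."""
    age = np.clip(rng.normal(67.0, 9.0, n), 30.0, 92.0)
    sex = np.where(rng.random(n) < 0.49, "female", "male")
    stage = rng.random(n) < 0.61
    line = rng.choice(["1", "2", "3+"], size=n, p=[0.42, 0.49, 0.09])
    nlr = np.exp(rng.normal(np.log(4.7), 0.55, n))
    ldh = np.exp(rng.normal(np.log(263.0), 0.35, n))
    lipi = rng.choice([0, 1, 2], size=n, p=[0.27, 0.44, 0.29])
    return pd.DataFrame({
        "age_years": np.round(age, 1), "sex": sex, "stage_iv_at_dx": stage,
        "treatment_line": line, "nlr": np.round(nlr, 2),
        "ldh": np.round(ldh, 1), "lipi": lipi,
    })


def simulate_cohort(truth: SimTruth) -> CohortTable:
    """Draw one cohort under ``truth``.  Identical seed, identical cohort.

    The simulated terminal event is the PFS event (progression or death,
    whichever first); for OS analyses a post-progression residual survival
    time is attached so both endpoints are derivable.  Observed CRP values
    are clamped to the assay range; the number of clamped observations is
    recorded in ``cohort.baseline.attrs['n_clamped']``.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n_patients
    beta = np.asarray(truth.beta, dtype=float)
    D = np.asarray(truth.D, dtype=float)
    q = D.shape[0]
    L = np.linalg.cholesky(D + 1e-12 * np.eye(q))

    cov = _draw_covariates(n, rng)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    loggw = np.zeros(n)
    for name, g in truth.gamma.items():
        col = cov[name].to_numpy()
        if col.dtype == bool:
            col = col.astype(float)
        loggw += g * np.asarray(col, dtype=float)

    b_all = (L @ rng.standard_normal((q, n))).T  # (n, q)

    event_time = np.empty(n)
    for i in range(n):
        lp0 = loggw[i] + truth.alpha_value * _trajectory(beta, b_all[i], np.array([0.0]))[0]
        if abs(lp0) > _MAX_LINPRED:
            raise ValueError(
                "hazard linear predictor exceeds +/-50 at baseline; rescale "
                "alpha/beta/gamma (values this large overflow exp())"
            )
        event_time[i] = _draw_event_time(truth, b_all[i], loggw[i], rng.random())
    # an event on the start day itself is recorded at a minimal positive
    # time so month-rounded outcomes stay strictly positive
    event_time = np.maximum(event_time, 0.01)

    censor_time = (rng.exponential(1.0 / truth.censor_rate, n)
                   if truth.censor_rate > 0 else np.full(n, np.inf))
    followup = np.minimum.reduce([event_time, censor_time,
                                  np.full(n, TRUNCATION_MONTHS)])
    is_event = event_time <= np.minimum(censor_time, TRUNCATION_MONTHS)

    # PFS event split into progression vs death; residual survival after
    # progression supplies the OS endpoint (plumbing for OS analyses only).
    death_is_first = rng.random(n) < 0.3
    resid_os = rng.exponential(6.0, n)
    progression_months = np.where(is_event & ~death_is_first, event_time, np.nan)
    death_months = np.where(is_event & death_is_first, event_time,
                            np.where(is_event, event_time + resid_os, np.nan))
    last_contact = np.where(is_event,
                            np.where(np.isnan(death_months), followup + resid_os,
                                     death_months),
                            followup)
    # death after the recorded last contact is inconsistent; align
    last_contact = np.fmax(last_contact, np.where(np.isnan(death_months), 0.0,
                                                  death_months))

    # visit schedule: baseline draw in [-14, 0], then every `spacing` days
    # with +/- jitter until the endpoint
    rows = []
    n_clamped = 0
    for i in range(n):
        t_end_days = followup[i] * DAYS_PER_MONTH
        t0 = -float(rng.integers(0, 15))
        times = [t0]
        t = max(t0, 0.0)
        while True:
            t = t + truth.visit_spacing_days + rng.uniform(-truth.visit_jitter_days,
                                                           truth.visit_jitter_days)
            if t > t_end_days:
                break
            times.append(round(t))
        times = sorted(set(int(x) for x in times))
        tm = np.array(times, dtype=float) / DAYS_PER_MONTH
        mu = _trajectory(beta, b_all[i], tm)
        y = mu + truth.sigma * rng.standard_normal(len(tm))
        clipped = np.clip(y, truth.detection_floor, truth.detection_ceiling)
        n_clamped += int(np.sum(clipped != y))
        for t_day, val in zip(times, clipped):
            rows.append((ids[i], int(t_day), float(np.round(val, 2))))

    labs = pd.DataFrame(rows, columns=["patient_id", "time_days", "crp_mg_per_l"])
    base = pd.DataFrame({"patient_id": ids, "start_day": 0})
    base = pd.concat([base, cov], axis=1)
    base["response"] = np.nan
    base["progression_months"] = np.round(progression_months, 4)
    base["death_months"] = np.round(death_months, 4)
    base["last_contact_months"] = np.round(last_contact, 4)
    base["b0_true"] = b_all[:, 0]
    if q > 1:
        base["b1_true"] = b_all[:, 1]
    base["event_time_true"] = event_time

    cohort = CohortTable(baseline=base, labs=labs,
                         provenance=f"synthetic:seed={truth.seed}")
    cohort.baseline.attrs["n_clamped"] = n_clamped
    cohort.baseline.attrs["n_obs"] = len(labs)
    cohort.baseline.attrs["truth"] = truth.as_dict()
    return cohort


def simulate_response(cohort: CohortTable, truth: SimTruth,
                      or_per_doubling: float = 0.68,
                      baseline_orr: float = 0.30) -> pd.Series:
    """Attach response labels driven by baseline CRP.

    logit P(responder) = eta0 + ln(OR) * log2(baseline CRP), with eta0 chosen
    so that a patient at the median simulated baseline CRP has probability
    ``baseline_orr``; a fixed fraction of patients is set to NE (not
    evaluable) to exercise the exclusion rule.  Responders are labelled PR,
    non-responders PD.
    """
    if or_per_doubling <= 0:
        raise ValueError("or_per_doubling must be positive")
    rng = np.random.default_rng(truth.seed + 1_000_003)
    crp = cohort.baseline_crp()
    log2crp = np.log2(np.clip(crp.to_numpy(dtype=float), CRP_LOWER, None))
    center = np.nanmedian(log2crp)
    eta0 = np.log(baseline_orr / (1 - baseline_orr))
    eta = eta0 + np.log(or_per_doubling) * (log2crp - center)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.where(np.isnan(p), 0.0, p)
    responder = rng.random(len(p)) < p
    labels = np.where(responder, "PR", "PD").astype(object)
    ne = rng.random(len(p)) < truth.ne_fraction
    labels[ne] = "NE"
    labels[np.isnan(log2crp)] = np.nan
    s = pd.Series(labels, index=cohort.baseline["patient_id"], name="response")
    cohort.baseline["response"] = s.to_numpy()
    return s


# ---------------------------------------------------------------------------
# cross-sectional simulator for the baseline (per-doubling / quartile /
# time-dependent-effect) analyses
# ---------------------------------------------------------------------------

def simulate_decline_cohort(n: int, seed: int,
                            hr_per_10pct: float = 0.91,
                            lam: float = 0.12,
                            censor_rate: float = 0.03) -> pd.DataFrame:
    """Early-decline survival data with a known protective effect.

    Half the patients show no decline (0%), the rest a uniform decline up to
    80%; PFS events are exponential with hazard lam * hr_per_10pct^(decline/10),
    censored independently and administratively at 24 months.  Returns a
    frame shaped like :func:`crptraj.response.early_decline_table` merged
    with endpoints (decline_pct, evaluable, time_months, event).
    """
    rng = np.random.default_rng(seed)
    decline = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0.0, 80.0, n))
    rate = lam * hr_per_10pct ** (decline / 10.0)
    T = rng.exponential(1.0 / rate)
    cens = rng.exponential(1.0 / censor_rate, n) if censor_rate > 0 else np.full(n, np.inf)
    time = np.minimum.reduce([T, cens, np.full(n, TRUNCATION_MONTHS)])
    event = T <= np.minimum(cens, TRUNCATION_MONTHS)
    return pd.DataFrame({
        "patient_id": [f"D{i + 1:04d}" for i in range(n)],
        "decline_pct": np.round(decline, 2), "evaluable": True,
        "time_months": time, "event": event,
    })


def simulate_tvc_cohort(n: int, seed: int,
                        hr_at_t0: float = 1.41,
                        hr_decay_per_year: float = 0.57,
                        lam: float = 0.05, kappa: float = 1.2,
                        censor_rate: float = 0.03) -> pd.DataFrame:
    """Survival data drawn from the spline-free log-cumulative-hazard model
    with a linear-in-time covariate effect:

        log H(t | x) = log(lam) + kappa*log(t) + x*(log hr_at_t0
                                                    + log(hr_decay_per_year)*t/12),

    with a binary covariate x (e.g. CRP above vs below the median).  With
    kappa >= 1.2 and |log decay|/12 <= kappa/24 the implied hazard stays
    positive over the whole 24-month window, so this is a valid generating
    distribution whose time-interaction parameter the flexible parametric fit
    estimates without any parameterization gap.
    """
    b = np.log(hr_at_t0)
    c = np.log(hr_decay_per_year) / 12.0
    if kappa / TRUNCATION_MONTHS + min(c, 0.0) <= 0:
        raise ValueError("hazard not positive over the follow-up window; "
                         "increase kappa or weaken the decay")
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)

    def cumhaz(t, xi):
        return lam * t ** kappa * np.exp(xi * (b + c * t))

    T = np.empty(n)
    for i in range(n):
        target = -np.log(rng.random())
        hi = TRUNCATION_MONTHS + 1.0
        if cumhaz(hi, x[i]) < target:
            T[i] = np.inf
        else:
            T[i] = brentq(lambda t: cumhaz(t, x[i]) - target, 1e-9, hi)
    cens = rng.exponential(1.0 / censor_rate, n) if censor_rate > 0 else np.full(n, np.inf)
    time = np.minimum.reduce([T, cens, np.full(n, TRUNCATION_MONTHS)])
    event = T <= np.minimum(cens, TRUNCATION_MONTHS)
    return pd.DataFrame({
        "patient_id": [f"T{i + 1:04d}" for i in range(n)],
        "x": x, "time_months": time, "event": event,
    })


def simulate_baseline_cohort(n: int, seed: int,
                             log_hr_per_unit: float = 0.0,
                             hr_decay_per_year: float = 1.0,
                             covariate: str = "log2_crp",
                             lam: float = 0.12, kappa: float = 1.1,
                             censor_rate: float = 0.04) -> pd.DataFrame:
    """Survival data with a (possibly time-decaying) baseline-CRP effect.

    The hazard is h(t|x) = lam*kappa*t^(kappa-1) * exp(x*(b + c*t/12)) with
    b = ``log_hr_per_unit`` and c = ln(``hr_decay_per_year``); x is the
    centered log2 baseline CRP (lognormal marker matched to the printed
    quartiles).  Administrative censoring at 24 months plus independent
    exponential censoring.  Returns a frame with columns baseline_crp,
    log2_crp, x (centered), time_months, event.
    """
    rng = np.random.default_rng(seed)
    crp = lognormal_baseline_crp(n, rng)
    log2crp = np.log2(crp)
    x = log2crp - np.log2(21.6)
    c = np.log(hr_decay_per_year) / 12.0  # per month

    def cumhaz(t, xi):
        # closed form only when c*x == 0; use Gauss-Legendre otherwise
        if c == 0 or xi == 0:
            return lam * t ** kappa * np.exp(log_hr_per_unit * xi)
        nodes, w = _leggauss(60)
        u = 0.5 * t * (nodes + 1.0)
        h = lam * kappa * u ** (kappa - 1.0) * np.exp(xi * (log_hr_per_unit + c * u))
        return 0.5 * t * np.dot(w, h)

    T = np.empty(n)
    for i in range(n):
        target = -np.log(rng.random())
        if cumhaz(400.0, x[i]) < target:
            T[i] = np.inf
        else:
            T[i] = brentq(lambda t: cumhaz(t, x[i]) - target, 1e-9, 400.0)
    cens = rng.exponential(1.0 / censor_rate, n) if censor_rate > 0 else np.full(n, np.inf)
    time = np.minimum.reduce([T, cens, np.full(n, TRUNCATION_MONTHS)])
    event = T <= np.minimum(cens, TRUNCATION_MONTHS)
    return pd.DataFrame({
        "patient_id": [f"S{i + 1:04d}" for i in range(n)],
        "baseline_crp": crp, "log2_crp": log2crp, "x": x,
        "time_months": time, "event": event,
    })
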