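"""Personalized dynamic risk prediction from a fitted joint model.

Given a patient's CRP history up to a landmark time t and survival to t, the
conditional probability of a PFS event within the next Delta months is

    pi(t, Delta) = 1 - E[ S_i(t + Delta | b) / S_i(t | b) | history, T > t ],

with the expectation over the posterior of the patient's random effects b.
The default is the empirical-Bayes plug-in at the posterior mode (fast and
deterministic); a Monte-Carlo average over a normal approximation to the
posterior quantifies the plug-in approximation.  Measurements recorded after
the landmark are ignored, so predictions honestly use only the information
available at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .joint import JointFit, _EXP_CLIP

_GL_X, _GL_W = np.polynomial.legendre.leggauss(31)


@dataclass
class DynamicRisk:
    patient_id: str
    landmark_months: float
    horizon_months: float
    risk: float
    method: str
    posterior_mode: np.ndarray
    posterior_curvature: np.ndarray
    draws: int = 0


def _cumhaz(fit: JointFit, b: np.ndarray, gw: float, t: float) -> float:
    """H(t | b) for one patient under the fitted model (u = t^kappa rule)."""
    if t <= 0:
        return 0.0
    kap, lam = fit.kappa, fit.lam
    U = t ** kap
    u = 0.5 * U * (_GL_X + 1.0)
    w = 0.5 * U * _GL_W
    tt = u ** (1.0 / kap)
    beta = fit.beta
    m = sum(beta[k] * tt ** k for k in range(len(beta))) + b[0]
    arg = gw
    if fit.alpha_value is not None:
        mm = m + (b[1] * tt if len(b) > 1 else 0.0)
        arg = arg + fit.alpha_value * mm
    if fit.alpha_slope is not None:
        mp = sum(k * beta[k] * tt ** (k - 1) for k in range(1, len(beta)))
        if len(b) > 1:
            mp = mp + b[1]
        arg = arg + fit.alpha_slope * mp
    return float(lam * np.dot(w, np.exp(np.clip(arg, -_EXP_CLIP, _EXP_CLIP))))


def _history_arrays(history: pd.DataFrame, t: float) -> tuple[np.ndarray, np.ndarray]:
    h = history[history["time_months"] <= t + 1e-12]
    return (h["time_months"].to_numpy(dtype=float),
            h["crp_mg_per_l"].to_numpy(dtype=float))


def _neg_log_posterior(b, fit, times, values, gw, t):
    beta, s2 = fit.beta, fit.sigma ** 2
    mu = sum(beta[k] * times ** k for k in range(len(beta))) + b[0]
    if len(b) > 1:
        mu = mu + b[1] * times
    ll = -0.5 * np.sum((values - mu) ** 2) / s2
    ll -= _cumhaz(fit, b, gw, t)
    Dinv = np.linalg.inv(fit.D)
    ll -= 0.5 * float(b @ Dinv @ b)
    return -ll


def posterior_effects(fit: JointFit, history: pd.DataFrame, t: float,
                      gw: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and curvature (negative Hessian) of the random effects
    given the CRP history up to t and event-free survival to t.

    ``gw`` is the patient's survival-submodel linear predictor gamma'w.
    With no measurements and a vanishing association this reduces to the
    prior (mode 0, curvature D^-1).
    """
    q = fit.D.shape[0]
    times, values = _history_arrays(history, t) if len(history) else \
        (np.array([]), np.array([]))
    # start at the longitudinal-only closed-form posterior mean
    s2 = fit.sigma ** 2
    Z = (np.ones((len(times), 1)) if q == 1
         else np.column_stack([np.ones_like(times), times]))
    e = values - sum(fit.beta[k] * times ** k for k in range(len(fit.beta))) \
        if len(times) else np.array([])
    P0 = np.linalg.inv(fit.D) + (Z.T @ Z) / s2 if len(times) else np.linalg.inv(fit.D)
    b0 = np.linalg.solve(P0, Z.T @ e / s2) if len(times) else np.zeros(q)

    res = optimize.minimize(_neg_log_posterior, b0,
                            args=(fit, times, values, gw, t),
                            method="BFGS", options={"gtol": 1e-8})
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"posterior mode search failed: {res.message}")
    mode = res.x
    curv = _num_hessian_small(lambda b: _neg_log_posterior(b, fit, times,
                                                           values, gw, t), mode)
    return mode, curv


def predict_risk(fit: JointFit, history: pd.DataFrame, t: float, delta: float,
                 method: str = "empirical_bayes", gw: float = 0.0,
                 n_draws: int = 2000, seed: int = 0,
                 patient_id: str = "") -> DynamicRisk:
    """Conditional risk pi(t, Delta) of an event in (t, t + Delta]."""
    if delta < 0:
        raise ValueError("horizon Delta must be >= 0")
    if method not in ("empirical_bayes", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if t > 24.0:
        import warnings
        warnings.warn("landmark beyond the fitted 24-month support", stacklevel=2)
    mode, curv = posterior_effects(fit, history, t, gw)
    if delta == 0:
        return DynamicRisk(patient_id, t, 0.0, 0.0, method, mode, curv)

    def ratio(b):
        return np.exp(-(_cumhaz(fit, b, gw, t + delta) - _cumhaz(fit, b, gw, t)))

    if method == "empirical_bayes":
        risk = 1.0 - ratio(mode)
        draws = 0
    else:
        rng = np.random.default_rng(seed)
        cov = np.linalg.inv(curv)
        L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(len(mode)))
        bs = mode[None, :] + rng.standard_normal((n_draws, len(mode))) @ L.T
        risk = 1.0 - float(np.mean([ratio(b) for b in bs]))
        draws = n_draws
    return DynamicRisk(patient_id, t, delta, float(np.clip(risk, 0.0, 1.0)),
                       method, mode, curv, draws)


def risk_profile(fit: JointFit, history: pd.DataFrame, t: float,
                 horizons: np.ndarray, method: str = "empirical_bayes",
                 gw: float = 0.0, patient_id: str = "",
                 seed: int = 0) -> pd.DataFrame:
    """pi(t, Delta) over a grid of horizons (months); monotone in Delta."""
    rows = []
    for d in np.asarray(horizons, dtype=float):
        r = predict_risk(fit, history, t, float(d), method=method, gw=gw,
                         seed=seed, patient_id=patient_id)
        rows.append({"patient_id": patient_id, "landmark": t,
                     "horizon": float(d), "risk": r.risk})
    return pd.DataFrame(rows)


def _num_hessian_small(f, x, h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = len(x)
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) \
                / (4 * steps[i] * steps[j])
    return H
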