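"""Flexible parametric survival model on the log cumulative-hazard scale.

The model is

    log H(t | x) = s(log t; gamma) + beta' x + theta * x_tvc * (t / 12),

where s is a restricted cubic spline in log time (Royston-Parmar style basis
with interior knots at quantiles of the uncensored log event times) and the
last term is a covariate-by-linear-time interaction, with t in months so that
theta is a log hazard-ratio change per year of follow-up.  Reported effects
are exp(beta_tvc), the covariate effect at t = 0, and exp(theta), the
multiplicative change in that effect per year.  Full maximum likelihood; the
hazard is obtained by differentiating the spline, and fits whose implied
hazard goes negative on the observed time grid are retried with fewer knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .survival import EffectEstimate, SurvivalInputError, wald_estimate

MONTHS_PER_YEAR = 12.0


class FlexFitError(RuntimeError):
    pass


def rcs_basis(u: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restricted cubic spline basis (and its derivative) in u = log t.

    Returns (B, dB) with columns [1, u, v_1..v_K] where v_j are the
    Durrleman-Simon truncated-cubic terms constrained to be linear beyond the
    boundary knots; knots = [k_min, interior..., k_max].
    """
    u = np.asarray(u, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    interior = knots[1:-1]
    cols = [np.ones_like(u), u]
    dcols = [np.zeros_like(u), np.ones_like(u)]
    span = kmax - kmin
    for kj in interior:
        lj = (kmax - kj) / span
        t1, t2, t3 = (np.maximum(u - kj, 0.0), np.maximum(u - kmin, 0.0),
                      np.maximum(u - kmax, 0.0))
        cols.append(t1 ** 3 - lj * t2 ** 3 - (1 - lj) * t3 ** 3)
        dcols.append(3 * t1 ** 2 - 3 * lj * t2 ** 2 - 3 * (1 - lj) * t3 ** 2)
    return np.column_stack(cols), np.column_stack(dcols)


@dataclass
class FlexSurvFit:
    spline_coef: np.ndarray
    knots: np.ndarray                  # on the log-time (months) scale
    beta: np.ndarray
    beta_names: list[str]
    theta: float | None                # per-year tvc coefficient (None if no tvc)
    tvc_name: str | None
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    estimates: list[EffectEstimate] = field(default_factory=list)

    def _eta(self, t: np.ndarray, x: np.ndarray | None = None,
             x_tvc: np.ndarray | float = 0.0) -> np.ndarray:
        B, _ = rcs_basis(np.log(t), self.knots)
        eta = B @ self.spline_coef
        if x is not None and len(self.beta):
            eta = eta + np.asarray(x, dtype=float) @ self.beta
        if self.theta is not None:
            eta = eta + self.theta * np.asarray(x_tvc) * t / MONTHS_PER_YEAR
        return eta

    def cumhaz(self, t, x=None, x_tvc=0.0) -> np.ndarray:
        return np.exp(self._eta(np.asarray(t, dtype=float), x, x_tvc))

    def survival(self, t, x=None, x_tvc=0.0) -> np.ndarray:
        return np.exp(-self.cumhaz(t, x, x_tvc))


def _knot_vector(log_times_uncensored: np.ndarray, n_interior: int) -> np.ndarray:
    lo, hi = log_times_uncensored.min(), log_times_uncensored.max()
    if n_interior == 0:
        return np.array([lo, hi])
    qs = np.linspace(0, 100, n_interior + 2)[1:-1]
    interior = np.percentile(log_times_uncensored, qs)
    return np.concatenate([[lo], np.atleast_1d(interior), [hi]])


_SOFTPLUS_SHARPNESS = 1000.0


def _softplus(z: np.ndarray, s: float = _SOFTPLUS_SHARPNESS) -> np.ndarray:
    """Smooth positive surrogate for max(z, 0); equals z for z >> 1/s."""
    return np.logaddexp(0.0, s * z) / s


def _log_softplus(z: np.ndarray, s: float = _SOFTPLUS_SHARPNESS) -> np.ndarray:
    """log(softplus(z)) without underflow: for s*z << 0, softplus ~ exp(s z)/s."""
    z = np.asarray(z, dtype=float)
    sz = s * z
    out = np.where(sz < -30.0, sz - np.log(s),
                   np.log(np.maximum(_softplus(np.where(sz < -30.0, 0.0, z), s),
                                     1e-300)))
    return out


def _negloglik(params: np.ndarray, B, dB, t, delta, X, xt_scaled, n_spline, p,
               has_tvc: bool) -> float:
    gam = params[:n_spline]
    beta = params[n_spline:n_spline + p]
    theta = params[-1] if has_tvc else 0.0
    eta = B @ gam
    detadu = dB @ gam                       # d eta / d(log t), spline part
    if p:
        eta = eta + X @ beta
    if has_tvc:
        eta = eta + theta * xt_scaled * t
    # dH/dt = H * (detadu / t + theta * x / 12); the softplus floor keeps the
    # log-hazard term smooth when the optimizer visits a negative hazard
    dterm = detadu / t + (theta * xt_scaled if has_tvc else 0.0)
    eta = np.clip(eta, -200.0, 200.0)
    ll = float(np.sum(delta * (eta + _log_softplus(dterm)))
               - np.sum(np.exp(eta)))
    return -ll


def flexsurv_fit(df: pd.DataFrame, covariates: list[str] | None = None,
                 tvc: str | None = None, n_interior_knots: int = 3,
                 time_col: str = "time_months", event_col: str = "event",
                 min_events: int = 10) -> FlexSurvFit:
    """Maximum-likelihood fit of the spline log-cumulative-hazard model.

    ``tvc`` names the covariate that receives the linear-in-time interaction
    (it must also appear in ``covariates``).  If the implied hazard is
    negative anywhere on the observed-time grid, the fit is retried with
    fewer interior knots, and an error is raised only if that persists.
    """
    covariates = list(covariates or [])
    if tvc is not None and tvc not in covariates:
        raise ValueError(f"tvc covariate {tvc!r} must be among the covariates")
    use = df[[time_col, event_col, *covariates]].dropna()
    t = use[time_col].to_numpy(dtype=float)
    delta = use[event_col].to_numpy(dtype=float)
    if int(delta.sum()) < min_events:
        raise SurvivalInputError(f"need >= {min_events} events for a stable spline fit")
    if (t <= 0).any():
        raise SurvivalInputError("nonpositive survival times")
    X = use[covariates].to_numpy(dtype=float) if covariates else None
    xt = use[tvc].to_numpy(dtype=float) if tvc else None

    last_err = None
    for n_int in range(n_interior_knots, -1, -1):
        try:
            return _fit_once(t, delta, X, xt, covariates, tvc, n_int)
        except FlexFitError as exc:
            last_err = exc
            continue
    raise FlexFitError(f"hazard constraint unsatisfiable at any knot count: {last_err}")


def _fit_once(t, delta, X, xt, covariates, tvc, n_interior) -> FlexSurvFit:
    knots = _knot_vector(np.log(t[delta > 0.5]), n_interior)
    B, dB = rcs_basis(np.log(t), knots)
    n_spline = B.shape[1]
    p = len(covariates)
    has_tvc = tvc is not None
    xt_scaled = (xt / MONTHS_PER_YEAR) if has_tvc else None

    # warm start: Weibull (log H = log lam + kappa log t) via a crude moment
    # fit, covariates at 0
    ev_rate = max(delta.mean(), 0.05)
    x0 = np.zeros(n_spline + p + (1 if has_tvc else 0))
    x0[0] = np.log(-np.log(max(1 - ev_rate, 0.05))) - np.log(np.median(t))
    x0[1] = 1.0

    args = (B, dB, t, delta, X, xt_scaled, n_spline, p, has_tvc)
    res = optimize.minimize(_negloglik, x0, args=args, method="L-BFGS-B",
                            options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-9})
    # polish: BFGS is less sensitive to the mixed scaling of spline and
    # covariate coefficients than L-BFGS-B's stopping rule
    res2 = optimize.minimize(_negloglik, res.x, args=args, method="BFGS",
                             options={"maxiter": 500, "gtol": 1e-6})
    res = res2 if res2.fun <= res.fun else res
    if np.linalg.norm(res.jac) > 0.5:
        raise FlexFitError(f"optimizer failed: |grad| = {np.linalg.norm(res.jac):.3g}")
    params = res.x

    # hazard-positivity check: baseline hazard on the observed-time grid,
    # and the patient-specific hazard at every observed event point (with a
    # time-decaying effect the implied hazard can go negative at covariate /
    # time combinations far outside the data; those are not constrained)
    grid = np.linspace(t.min(), t.max(), 200)
    Bg, dBg = rcs_basis(np.log(grid), knots)
    gam = params[:n_spline]
    theta = params[-1] if has_tvc else None
    if (dBg @ gam / grid <= 0).any():
        raise FlexFitError(
            f"implied baseline hazard negative on the observed grid (knots={n_interior})"
        )
    _, dBt = rcs_basis(np.log(t), knots)
    dterm_obs = dBt @ gam / t + ((theta * xt / MONTHS_PER_YEAR) if has_tvc else 0.0)
    if (dterm_obs[delta > 0.5] <= 0).any():
        raise FlexFitError(
            f"implied hazard negative at an observed event (knots={n_interior})"
        )

    H = _num_hessian(lambda th: _negloglik(th, B, dB, t, delta, X, xt_scaled,
                                           n_spline, p, has_tvc), params)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((len(params), len(params)), np.nan)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))

    beta = params[n_spline:n_spline + p]
    ests = []
    for j, name in enumerate(covariates):
        label = f"{name} (at t=0)" if name == tvc else name
        ests.append(wald_estimate(label, beta[j], ses[n_spline + j], scale="HR"))
    if has_tvc:
        ests.append(wald_estimate(f"{tvc} x time", params[-1], ses[-1],
                                  scale="multiplicative-per-year", unit="per year"))
    return FlexSurvFit(spline_coef=gam, knots=knots, beta=beta,
                       beta_names=covariates, theta=theta, tvc_name=tvc,
                       cov=cov, loglik=-float(res.fun), n=len(t),
                       n_events=int(delta.sum()), estimates=ests)


def _num_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with relative steps."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H
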