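"""Joint model of longitudinal CRP and time-to-event outcome.

The longitudinal submodel is the linear mixed model of :mod:`crptraj.lmm`
(polynomial time, random intercept or intercept + slope); the survival
submodel is a Weibull proportional-hazards model whose hazard at time t
depends on the model-implied current value m_i(t) and/or slope m_i'(t) of
the patient's latent trajectory:

    h_i(t | b_i) = lam * kap * t^(kap-1)
                   * exp(gamma' w_i + a_v * m_i(t|b_i) + a_s * m_i'(t|b_i)).

The marginal likelihood integrates the shared random effects b_i out of the
product of the longitudinal density, the event/censoring contribution and
the N(0, D) prior.  The integral uses pseudo-adaptive Gauss-Hermite
quadrature: the Gaussian longitudinal-posterior factor of each patient is
available in closed form, so nodes are centered at that posterior's mean and
scaled by its Cholesky factor, and quadrature only has to absorb the smooth
survival factor.  At a_v = a_s = 0 the survival factor is constant in b and
the scheme is exact for any node count, which is the factorization identity
the tests assert.

Time is in months throughout; reported hazard ratios are exp(unit * alpha),
e.g. per 10 mg/L of current CRP or per 10 mg/L/month of CRP slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable, DAYS_PER_MONTH
from .lmm import lmm_fit, LmmConvergenceError
from .survival import EffectEstimate, wald_estimate

_SQRT_PI = np.sqrt(np.pi)
_EXP_CLIP = 700.0


class JointFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class JointSpec:
    association: str = "current_value"     # current_value | slope | both
    degree: int = 1
    random_effects: str = "intercept"      # intercept | intercept_slope
    covariates: tuple[str, ...] = ()
    n_quad: int = 9                        # Gauss-Hermite nodes (odd, >= 5)
    n_gl: int = 15                         # Gauss-Legendre points for cum. hazard

    def __post_init__(self) -> None:
        if self.association not in ("current_value", "slope", "both"):
            raise ValueError(f"unknown association {self.association!r}")
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if self.random_effects not in ("intercept", "intercept_slope"):
            raise ValueError(f"unknown random-effects structure {self.random_effects!r}")
        if self.n_quad < 5 or self.n_quad % 2 == 0:
            raise ValueError("n_quad must be odd and >= 5")
        if self.association in ("slope", "both") and self.degree < 1:
            raise ValueError("a slope association needs a time trend (degree >= 1)")

    @property
    def q(self) -> int:
        return 1 if self.random_effects == "intercept" else 2

    @property
    def has_value(self) -> bool:
        return self.association in ("current_value", "both")

    @property
    def has_slope(self) -> bool:
        return self.association in ("slope", "both")


@dataclass
class JointFit:
    spec: JointSpec
    beta: np.ndarray                 # longitudinal fixed effects (poly coefs)
    gamma: np.ndarray                # survival covariate coefficients
    lam: float
    kappa: float
    sigma: float
    D: np.ndarray
    alpha_value: float | None
    alpha_slope: float | None
    loglik: float
    params: np.ndarray               # packed internal parameter vector
    cov: np.ndarray | None           # covariance of packed params (None if not PD)
    se_valid: bool
    n_patients: int
    n_events: int
    n_obs: int
    converged: bool
    grad_norm: float
    model: "JointModel" = field(default=None, repr=False)

    def alpha_se(self, which: str) -> float:
        idx = self.model.alpha_index(which)
        if self.cov is None:
            return float("nan")
        return float(np.sqrt(self.cov[idx, idx]))


class JointModel:
    """Prepared data + likelihood machinery for one cohort and spec."""

    def __init__(self, labs: pd.DataFrame, endpoints: pd.DataFrame,
                 baseline: pd.DataFrame, spec: JointSpec):
        self.spec = spec
        ids = endpoints["patient_id"].tolist()
        self.ids = ids
        index = {pid: i for i, pid in enumerate(ids)}
        self.n = len(ids)

        labs = labs[labs["patient_id"].isin(index)].copy()
        if "time_months" not in labs.columns:
            labs["time_months"] = labs["time_days"] / DAYS_PER_MONTH
        self.pidx = labs["patient_id"].map(index).to_numpy()
        self.t_obs = labs["time_months"].to_numpy(dtype=float)
        self.y = labs["crp_mg_per_l"].to_numpy(dtype=float)
        self.n_i = np.bincount(self.pidx, minlength=self.n).astype(float)

        nb = spec.degree + 1
        self.X_obs = np.column_stack([self.t_obs ** k for k in range(nb)])
        self.T = endpoints["time_months"].to_numpy(dtype=float)
        self.delta = endpoints["event"].to_numpy(dtype=float)
        if spec.covariates:
            bl = baseline.set_index("patient_id").loc[ids]
            cols = []
            for c in spec.covariates:
                v = bl[c]
                cols.append(v.astype(float).to_numpy() if v.dtype != object
                            else pd.get_dummies(v, drop_first=True).iloc[:, 0].to_numpy(float))
            self.W = np.column_stack(cols)
        else:
            self.W = np.zeros((self.n, 0))

        # Gauss-Legendre rule for the cumulative hazard; applied after the
        # substitution u = t^kappa so the Weibull baseline integrates exactly
        # (the t-grid then depends on kappa and is rebuilt per evaluation)
        self.gl_x, self.gl_w = np.polynomial.legendre.leggauss(spec.n_gl)
        self.P_T = np.column_stack([self.T ** k for k in range(nb)])         # (n,nb)
        dTcols = [np.zeros_like(self.T)] + [k * self.T ** (k - 1) for k in range(1, nb)]
        self.dP_T = np.column_stack(dTcols)

        # Gauss-Hermite grid (physicists'), tensorized for q = 2
        z, wz = np.polynomial.hermite.hermgauss(spec.n_quad)
        if spec.q == 1:
            self.gh_z = z[:, None]                      # (K, 1)
            self.gh_logw = np.log(wz / _SQRT_PI)
        else:
            Z0, Z1 = np.meshgrid(z, z, indexing="ij")
            self.gh_z = np.column_stack([Z0.ravel(), Z1.ravel()])   # (K^2, 2)
            self.gh_logw = np.log(np.outer(wz, wz).ravel() / np.pi)

        # per-patient sufficient statistics independent of parameters
        if spec.q == 2:
            self.S1 = np.bincount(self.pidx, weights=self.t_obs, minlength=self.n)
            self.S2 = np.bincount(self.pidx, weights=self.t_obs ** 2, minlength=self.n)

        # parameter layout
        self.nb = nb
        self.p = self.W.shape[1]
        self.q = spec.q
        self.n_chol = 1 if spec.q == 1 else 3
        self.n_alpha = int(spec.has_value) + int(spec.has_slope)
        self.n_params = nb + self.p + 3 + self.n_chol + self.n_alpha

    # -- parameter packing ---------------------------------------------------

    def pack(self, beta, gamma, lam, kappa, sigma, D,
             alpha_value=0.0, alpha_slope=0.0) -> np.ndarray:
        D = np.atleast_2d(np.asarray(D, dtype=float))
        L = np.linalg.cholesky(D + 1e-10 * np.eye(self.q))
        chol = ([np.log(L[0, 0])] if self.q == 1
                else [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
        alphas = []
        if self.spec.has_value:
            alphas.append(alpha_value)
        if self.spec.has_slope:
            alphas.append(alpha_slope)
        return np.concatenate([np.asarray(beta, dtype=float),
                               np.asarray(gamma, dtype=float),
                               [np.log(lam), np.log(kappa), np.log(sigma)],
                               chol, alphas])

    def unpack(self, theta: np.ndarray) -> dict:
        nb, p = self.nb, self.p
        beta = theta[:nb]
        gamma = theta[nb:nb + p]
        lam, kappa, sigma = np.exp(theta[nb + p:nb + p + 3])
        i = nb + p + 3
        if self.q == 1:
            L = np.array([[np.exp(theta[i])]])
            i += 1
        else:
            L = np.array([[np.exp(theta[i]), 0.0],
                          [theta[i + 1], np.exp(theta[i + 2])]])
            i += 3
        D = L @ L.T
        a_v = a_s = 0.0
        if self.spec.has_value:
            a_v = theta[i]; i += 1
        if self.spec.has_slope:
            a_s = theta[i]; i += 1
        return dict(beta=beta, gamma=gamma, lam=lam, kappa=kappa,
                    sigma=sigma, D=D, L=L, alpha_value=a_v, alpha_slope=a_s)

    def alpha_index(self, which: str) -> int:
        base = self.nb + self.p + 3 + self.n_chol
        if which == "value":
            if not self.spec.has_value:
                raise ValueError("no current-value association in this spec")
            return base
        if which == "slope":
            if not self.spec.has_slope:
                raise ValueError("no slope association in this spec")
            return base + int(self.spec.has_value)
        raise ValueError(f"which must be 'value' or 'slope', got {which!r}")

    # -- likelihood ----------------------------------------------------------

    def loglik(self, theta: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = self._loglik_impl(np.asarray(theta, dtype=float))
        # a non-finite value only arises at wild optimizer excursions; map it
        # to a large finite penalty so line searches can recover
        return ll if np.isfinite(ll) else -1e12

    def _loglik_impl(self, theta: np.ndarray) -> float:
        P = self.unpack(theta)
        beta, sigma, D, L = P["beta"], P["sigma"], P["D"], P["L"]
        s2 = sigma ** 2
        e = self.y - self.X_obs @ beta
        se = np.bincount(self.pidx, weights=e, minlength=self.n)
        see = np.bincount(self.pidx, weights=e * e, minlength=self.n)

        if self.q == 1:
            d = D[0, 0]
            denom = s2 + self.n_i * d
            # marginal: y_i ~ N(X beta, s2 I + d 11')
            quad = (see - d * se ** 2 / denom) / s2
            logdet = self.n_i * np.log(s2) + np.log(denom / s2)
            marg = -0.5 * (self.n_i * np.log(2 * np.pi) + logdet + quad)
            # posterior of b | y: mean mu, variance v
            v = np.where(self.n_i > 0, d * s2 / denom, d)
            mu = np.where(self.n_i > 0, d * se / denom, 0.0)
            bnodes = mu[:, None] + np.sqrt(2.0 * v)[:, None] * self.gh_z[:, 0][None, :]
            b0 = bnodes                                    # (n, K)
            b1 = None
        else:
            ste = np.bincount(self.pidx, weights=self.t_obs * e, minlength=self.n)
            # P_i = D^-1 + A_i / s2 with A_i = [[n, S1], [S1, S2]]
            Dinv = np.linalg.inv(D)
            a = Dinv[0, 0] + self.n_i / s2
            bq = Dinv[0, 1] + self.S1 / s2
            c = Dinv[1, 1] + self.S2 / s2
            detP = a * c - bq ** 2
            # posterior mean = P^-1 (Z'e)/s2
            ze0, ze1 = se / s2, ste / s2
            mu0 = (c * ze0 - bq * ze1) / detP
            mu1 = (-bq * ze0 + a * ze1) / detP
            # marginal loglik via Woodbury + matrix determinant lemma
            detI = (1 + (D[0, 0] * self.n_i + 2 * D[0, 1] * self.S1
                         + D[1, 1] * self.S2) / s2
                    + np.linalg.det(D) * (self.n_i * self.S2 - self.S1 ** 2) / s2 ** 2)
            quad = see / s2 - (ze0 * mu0 + ze1 * mu1)
            marg = -0.5 * (self.n_i * np.log(2 * np.pi)
                           + self.n_i * np.log(s2) + np.log(detI) + quad)
            # posterior Cholesky: Sigma = P^-1
            s00 = c / detP; s01 = -bq / detP; s11 = a / detP
            l00 = np.sqrt(s00)
            l10 = s01 / l00
            l11 = np.sqrt(np.maximum(s11 - l10 ** 2, 1e-300))
            z0 = self.gh_z[:, 0][None, :]
            z1 = self.gh_z[:, 1][None, :]
            b0 = mu0[:, None] + np.sqrt(2.0) * l00[:, None] * z0
            b1 = (mu1[:, None] + np.sqrt(2.0)
                  * (l10[:, None] * z0 + l11[:, None] * z1))

        surv = self._surv_logpart(P, b0, b1)               # (n, K)
        integ = _logsumexp(self.gh_logw[None, :] + surv, axis=1)
        return float(np.sum(marg) + np.sum(integ))

    def _surv_logpart(self, P: dict, b0: np.ndarray, b1: np.ndarray | None) -> np.ndarray:
        """delta * log h(T|b) - H(T|b) for each patient x quadrature node."""
        beta, gamma = P["beta"], P["gamma"]
        lam, kappa = P["lam"], P["kappa"]
        a_v, a_s = P["alpha_value"], P["alpha_slope"]
        gw = self.W @ gamma if self.p else np.zeros(self.n)

        mT = (self.P_T @ beta)[:, None] + b0               # (n, K)
        mpT = (self.dP_T @ beta)[:, None] + (b1 if b1 is not None else 0.0)
        with np.errstate(divide="ignore"):
            logT = np.where(self.T > 0, np.log(self.T), -np.inf)
        logh = (np.log(lam) + np.log(kappa) + (kappa - 1.0) * logT[:, None]
                + gw[:, None] + a_v * mT + a_s * mpT)

        # H(T|b) = integral of lam*kap*t^(kap-1) exp(arg(t)); with u = t^kap
        # this is lam * integral_0^{T^kap} exp(arg(u^(1/kap))) du, which
        # Gauss-Legendre handles exactly when arg is constant (alpha = 0)
        U = self.T ** kappa
        u_gl = 0.5 * U[:, None] * (self.gl_x[None, :] + 1.0)      # (n, Q)
        w_u = 0.5 * U[:, None] * self.gl_w[None, :]
        t_gl = u_gl ** (1.0 / kappa)
        m_gl = np.zeros_like(t_gl)
        tp = np.ones_like(t_gl)
        for k in range(len(beta)):
            m_gl += beta[k] * tp
            tp = tp * t_gl
        arg = gw[:, None, None] + a_v * (m_gl[:, :, None] + b0[:, None, :])
        if a_s != 0.0:
            mp_gl = np.zeros_like(t_gl)
            tp = np.ones_like(t_gl)
            for k in range(1, len(beta)):
                mp_gl += k * beta[k] * tp
                tp = tp * t_gl
            mp_gl = mp_gl[:, :, None] + (b1[:, None, :] if b1 is not None else 0.0)
            arg = arg + a_s * mp_gl
        H = lam * np.einsum("nq,nqk->nk",
                            w_u, np.exp(np.clip(arg, -_EXP_CLIP, _EXP_CLIP)))
        return self.delta[:, None] * logh - H

    # -- survival-only loglik (warm start / factorization) --------------------

    def weibull_loglik(self, gamma, lam, kappa) -> float:
        gw = self.W @ np.asarray(gamma, dtype=float) if self.p else np.zeros(self.n)
        with np.errstate(divide="ignore"):
            logT = np.where(self.T > 0, np.log(self.T), -np.inf)
        ll = np.sum(self.delta * (np.log(lam) + np.log(kappa)
                                  + (kappa - 1.0) * logT + gw))
        ll -= np.sum(lam * self.T ** kappa * np.exp(gw))
        return float(ll)

    def weibull_fit(self) -> tuple[np.ndarray, float, float]:
        def nll(th):
            return -self.weibull_loglik(th[2:], np.exp(th[0]), np.exp(th[1]))
        ev = max(self.delta.mean(), 0.02)
        x0 = np.concatenate([[np.log(ev / max(np.mean(self.T), 1e-6)), 0.0],
                             np.zeros(self.p)])
        res = optimize.minimize(nll, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        return res.x[2:], float(np.exp(res.x[0])), float(np.exp(res.x[1]))


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    amax = np.max(a, axis=axis, keepdims=True)
    return (amax + np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True))).squeeze(axis)


def joint_loglik(theta: np.ndarray, cohort_or_model, spec: JointSpec | None = None,
                 endpoint: str = "PFS") -> float:
    """Joint log-likelihood at a packed parameter vector.

    ``cohort_or_model`` is either a prepared :class:`JointModel` or a
    :class:`CohortTable` (then ``spec`` is required).
    """
    model = (cohort_or_model if isinstance(cohort_or_model, JointModel)
             else build_model(cohort_or_model, spec, endpoint))
    return model.loglik(np.asarray(theta, dtype=float))


def build_model(cohort: CohortTable, spec: JointSpec,
                endpoint: str = "PFS") -> JointModel:
    return JointModel(cohort.labs, cohort.endpoints(endpoint),
                      cohort.baseline, spec)


def fit_joint(cohort_or_model, spec: JointSpec | None = None,
              endpoint: str = "PFS", min_events_warn: int = 20,
              gtol: float = 1e-4) -> JointFit:
    """Maximum-likelihood joint fit.

    Warm start from separate LMM and Weibull fits with the association at 0,
    then quasi-Newton maximization of the full likelihood; standard errors
    from the numerically differentiated observed information.  Convergence
    requires a scaled gradient norm below ``gtol``; a non-positive-definite
    Hessian withholds SEs (``se_valid=False``) rather than failing.
    """
    model = (cohort_or_model if isinstance(cohort_or_model, JointModel)
             else build_model(cohort_or_model, spec, endpoint))
    spec = model.spec
    n_events = int(model.delta.sum())
    if n_events < min_events_warn:
        warnings.warn(f"only {n_events} events; joint fit may be unstable",
                      stacklevel=2)

    # warm start
    labs = pd.DataFrame({"patient_id": np.asarray(model.ids)[model.pidx],
                         "time_months": model.t_obs,
                         "crp_mg_per_l": model.y})
    re = spec.random_effects
    try:
        lmm = lmm_fit(labs, degree=spec.degree, re_structure=re)
        beta0, D0, s0 = lmm.beta[:spec.degree + 1], lmm.D, np.sqrt(lmm.sigma2)
    except LmmConvergenceError:
        beta0 = np.zeros(spec.degree + 1)
        beta0[0] = model.y.mean()
        D0 = np.eye(spec.q) * np.var(model.y) / 2
        s0 = np.std(model.y) / np.sqrt(2)
    if spec.q == 2 and D0.shape[0] == 1:
        D0 = np.diag([D0[0, 0], 0.1])
    gamma0, lam0, kap0 = model.weibull_fit()

    x0 = model.pack(beta0, gamma0, lam0, kap0, s0, D0, 0.0, 0.0)
    nll = lambda th: -model.loglik(th)
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
    res2 = optimize.minimize(nll, res.x, method="BFGS",
                             options={"maxiter": 300, "gtol": 1e-6})
    if res2.fun <= res.fun:
        res = res2
    scale = 1.0 + abs(res.fun)
    grad_norm = float(np.linalg.norm(res.jac) / scale)
    if grad_norm > gtol:
        raise JointFitError(
            f"joint fit did not converge: scaled |grad| = {grad_norm:.2e} "
            f"(message: {res.message})")

    H = _num_hessian(nll, res.x)
    cov, se_valid = None, False
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() > 0:
            cov = np.linalg.inv(H)
            se_valid = True
    except np.linalg.LinAlgError:
        pass

    P = model.unpack(res.x)
    return JointFit(spec=spec, beta=P["beta"], gamma=P["gamma"], lam=P["lam"],
                    kappa=P["kappa"], sigma=P["sigma"], D=P["D"],
                    alpha_value=P["alpha_value"] if spec.has_value else None,
                    alpha_slope=P["alpha_slope"] if spec.has_slope else None,
                    loglik=-float(res.fun), params=res.x, cov=cov,
                    se_valid=se_valid, n_patients=model.n, n_events=n_events,
                    n_obs=len(model.y), converged=True, grad_norm=grad_norm,
                    model=model)


def hr_per_unit(fit: JointFit, which: str = "value", unit: float = 10.0,
                level: float = 0.95) -> EffectEstimate:
    """Hazard ratio per ``unit`` of the association: exp(unit * alpha) with a
    Wald CI from the observed information."""
    alpha = fit.alpha_value if which == "value" else fit.alpha_slope
    if alpha is None:
        raise ValueError(f"fit has no {which!r} association")
    se = fit.alpha_se(which)
    unit_label = "per %g mg/L" % unit if which == "value" else "per %g mg/L/month" % unit
    return wald_estimate(f"CRP {which} association", unit * alpha,
                         abs(unit) * se, scale="HR", unit=unit_label,
                         level=level)


def _num_hessian(f, x, h: float = 5e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = len(x)
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k); ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) \
                / (4 * steps[i] * steps[j])
    return H
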