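"""Linear mixed models for CRP trajectories and AIC time-specification choice.

The longitudinal submodel is

    y_ij = beta0 + beta1 t_ij (+ beta2 t^2 + beta3 t^3) + z_ij' b_i + e_ij,

with t in months since ICI start, random effects b_i ~ N(0, D) (random
intercept, optionally intercept + slope with unstructured D), and
e_ij ~ N(0, sigma^2).  Estimation is maximum likelihood (not REML) so that
AIC comparisons across fixed-effect time specifications are valid; fitting
delegates to statsmodels MixedLM, and an independent closed-form evaluator of
the marginal (random-effects-integrated) log-likelihood is exposed both as a
cross-check and for reuse by the joint model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


class LmmConvergenceError(RuntimeError):
    pass


@dataclass
class LmmFit:
    degree: int
    re_structure: str                 # "intercept" | "intercept_slope"
    beta: np.ndarray                  # fixed effects: poly coefs then covariates
    beta_names: list[str]
    D: np.ndarray                     # random-effect covariance (q x q)
    sigma2: float
    loglik: float
    n_params: int
    converged: bool
    boundary: bool = False            # D singular / on boundary
    result: object = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _design(time: np.ndarray, degree: int,
            covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(time)] + [time ** k for k in range(1, degree + 1)]
    names = ["intercept"] + [f"time^{k}" for k in range(1, degree + 1)]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def lmm_fit(data: pd.DataFrame, degree: int = 1,
            re_structure: str = "intercept",
            covariates: list[str] | None = None,
            value_col: str = "crp_mg_per_l",
            time_col: str = "time_months") -> LmmFit:
    """ML fit of the polynomial-time mixed model.

    ``data`` is long format with columns patient_id, ``time_col`` (months) and
    ``value_col``.  Raises :class:`LmmConvergenceError` on optimizer failure;
    a singular random-effect covariance is flagged (``boundary``) but the fit
    is returned.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if re_structure not in ("intercept", "intercept_slope"):
        raise ValueError(f"unknown random-effects structure {re_structure!r}")
    if data["patient_id"].nunique() < 2:
        raise ValueError("need >= 2 patients")

    time = data[time_col].to_numpy(dtype=float)
    y = data[value_col].to_numpy(dtype=float)
    cov_df = data[covariates] if covariates else None
    X, names = _design(time, degree, cov_df)
    groups = data["patient_id"].to_numpy()
    if re_structure == "intercept":
        exog_re = np.ones((len(y), 1))
        q = 1
    else:
        exog_re = np.column_stack([np.ones_like(time), time])
        q = 2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        res = None
        last = None
        # lbfgs can hit a singular profiled Hessian when a variance component
        # sits on the boundary; powell is derivative-free and robust there
        for method in (["lbfgs", "bfgs"], ["powell"], ["nm"]):
            try:
                res = model.fit(reml=False, method=method, maxiter=500)
                if res.converged:
                    break
            except Exception as exc:  # noqa: BLE001
                last = exc
                res = None
        if res is None:
            raise LmmConvergenceError(f"MixedLM failed: {last}")
    if not res.converged:
        raise LmmConvergenceError(
            f"MixedLM did not converge (degree={degree}, re={re_structure})"
        )
    D = np.atleast_2d(np.asarray(res.cov_re))
    sigma2 = float(res.scale)
    boundary = bool(np.linalg.eigvalsh(D).min() < 1e-8 * max(1.0, np.trace(D)))
    n_params = X.shape[1] + q * (q + 1) // 2 + 1
    return LmmFit(degree=degree, re_structure=re_structure,
                  beta=np.asarray(res.fe_params, dtype=float), beta_names=names,
                  D=D, sigma2=sigma2, loglik=float(res.llf),
                  n_params=n_params, converged=True, boundary=boundary,
                  result=res)


def marginal_loglik(data: pd.DataFrame, beta: np.ndarray, D: np.ndarray,
                    sigma2: float, degree: int = 1,
                    re_structure: str = "intercept",
                    covariates: list[str] | None = None,
                    value_col: str = "crp_mg_per_l",
                    time_col: str = "time_months") -> float:
    """Closed-form marginal log-likelihood: per patient, the density of the
    stacked observations y_i ~ N(X_i beta, sigma^2 I + Z_i D Z_i')."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    total = 0.0
    for _, grp in data.groupby("patient_id"):
        t = grp[time_col].to_numpy(dtype=float)
        yv = grp[value_col].to_numpy(dtype=float)
        cov_df = grp[covariates] if covariates else None
        X, _ = _design(t, degree, cov_df)
        Z = (np.ones((len(t), 1)) if re_structure == "intercept"
             else np.column_stack([np.ones_like(t), t]))
        V = sigma2 * np.eye(len(t)) + Z @ D @ Z.T
        e = yv - X @ np.asarray(beta, dtype=float)
        sign, logdet = np.linalg.slogdet(V)
        total += -0.5 * (len(t) * np.log(2 * np.pi) + logdet
                         + e @ np.linalg.solve(V, e))
    return float(total)


def select_time_spec(data: pd.DataFrame, re_structure: str = "intercept",
                     covariates: list[str] | None = None,
                     degrees: tuple[int, ...] = (1, 2, 3),
                     **kwargs) -> tuple[int, pd.DataFrame]:
    """Fit the candidate polynomial degrees with a common random-effects
    structure and return (argmin-AIC degree, AIC table)."""
    rows, fits = [], {}
    for d in degrees:
        try:
            fit = lmm_fit(data, degree=d, re_structure=re_structure,
                          covariates=covariates, **kwargs)
            fits[d] = fit
            rows.append({"degree": d, "loglik": fit.loglik,
                         "n_params": fit.n_params, "aic": fit.aic})
        except (LmmConvergenceError, np.linalg.LinAlgError) as exc:
            rows.append({"degree": d, "loglik": np.nan, "n_params": np.nan,
                         "aic": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    if not fits:
        raise LmmConvergenceError("all candidate degrees failed to fit")
    best = int(table.loc[table["aic"].idxmin(), "degree"])
    return best, table


def lowess_trajectory(time: np.ndarray, value: np.ndarray,
                      bandwidth: float = 0.5,
                      invert_time: bool = False) -> pd.DataFrame:
    """Tricube-weighted local-linear (LOWESS) smoother for trajectory
    displays.  ``invert_time=True`` flips the axis to time-before-endpoint
    (the spaghetti-plot convention).  Returns a two-column frame sorted by
    the (possibly inverted) time axis."""
    if not (0 < bandwidth <= 1):
        raise ValueError("bandwidth fraction must be in (0, 1]")
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    if len(time) < 5:
        raise ValueError("need at least 5 points to smooth")
    x = -time if invert_time else time
    sm_out = _sm_lowess(value, x, frac=bandwidth, it=0, return_sorted=True)
    return pd.DataFrame({"time": sm_out[:, 0], "smoothed": sm_out[:, 1]})
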