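"""Nonparametric and semiparametric survival machinery.

Kaplan-Meier estimation (with Greenwood variance and a Brookmeyer-Crowley
median CI), reverse-KM median follow-up, log-rank tests, Cox proportional
hazards regression (Efron or Breslow ties) and Schoenfeld-residual tests of
the proportional-hazards assumption.  Standard fits delegate to lifelines /
statsmodels; this module adds the containers, the effect-estimate reporting
convention (exponentiated coefficient with Wald CI) and the Grambsch-Therneau
global PH statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times


class SurvivalInputError(ValueError):
    pass


class CoxDivergenceError(RuntimeError):
    pass


@dataclass
class EffectEstimate:
    """A point estimate with Wald CI on the reported (exponentiated) scale."""

    name: str
    scale: str                  # "HR" | "OR" | "multiplicative-per-year"
    point: float
    ci_low: float
    ci_high: float
    p: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(f"CI [{self.ci_low}, {self.ci_high}] does not "
                             f"contain the point estimate {self.point}")


def wald_estimate(name: str, coef: float, se: float, scale: str = "HR",
                  unit: str = "", level: float = 0.95) -> EffectEstimate:
    z = stats.norm.ppf(0.5 + level / 2.0)
    pval = 2.0 * stats.norm.sf(abs(coef) / se) if se > 0 else np.nan
    return EffectEstimate(name=name, scale=scale, point=float(np.exp(coef)),
                          ci_low=float(np.exp(coef - z * se)),
                          ci_high=float(np.exp(coef + z * se)),
                          p=float(pval), unit=unit)


@dataclass
class KmCurve:
    times: np.ndarray            # distinct event times
    survival: np.ndarray         # S(t) at those times
    variance: np.ndarray         # Greenwood variance of S(t)
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float                # nan when S never reaches 0.5
    median_ci: tuple[float, float]
    kmf: KaplanMeierFitter = field(default=None, repr=False)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(time: np.ndarray, event: np.ndarray) -> KmCurve:
    """Product-limit estimate with Greenwood variance; median and its CI from
    the log(-log) confidence band (Brookmeyer-Crowley style inversion)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(time) == 0:
        raise SurvivalInputError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tab = kmf.event_table
    mask = tab["observed"].to_numpy() > 0
    t_ev = tab.index.to_numpy()[mask]
    d = tab["observed"].to_numpy()[mask].astype(float)
    n = tab["at_risk"].to_numpy()[mask].astype(float)
    surv = np.array([kmf.predict(t) for t in t_ev], dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_j<=t} d_j / (n_j (n_j - d_j));
    # at a time where the whole risk set fails S = 0 and the variance is 0
    terms = np.where(n > d, d / (n * np.maximum(n - d, 1)), 0.0)
    var = np.where(surv > 0, surv ** 2 * np.cumsum(terms), 0.0)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KmCurve(times=t_ev, survival=surv, variance=var, at_risk=n,
                   n_events=d, median=median, median_ci=(lo, hi), kmf=kmf)


def reverse_km_followup(time: np.ndarray, event: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Median potential follow-up: KM with the event indicator inverted so
    censorings are the 'events'."""
    curve = km_fit(time, ~np.asarray(event, dtype=bool))
    return curve.median, curve.median_ci


def logrank_test(time: np.ndarray, event: np.ndarray,
                 group: np.ndarray) -> tuple[float, int, float]:
    """K-sample log-rank test: (chi-square, df, p)."""
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if len(labels) < 2:
        raise SurvivalInputError("need >= 2 groups")
    if (counts == 0).any():
        raise SurvivalInputError("empty group")
    res = multivariate_logrank_test(np.asarray(time, dtype=float),
                                    group, np.asarray(event, dtype=bool))
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    estimates: list[EffectEstimate]
    data: pd.DataFrame = field(default=None, repr=False)
    cph: CoxPHFitter = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def cox_fit(df: pd.DataFrame, covariates: list[str],
            time_col: str = "time_months", event_col: str = "event",
            ties: str = "efron", scale: str = "HR") -> CoxFit:
    """Cox PH regression on the complete cases of ``covariates``.

    Efron tie handling (default) runs through lifelines; Breslow through
    statsmodels PHReg.  A monotone/degenerate likelihood raises
    :class:`CoxDivergenceError` naming the covariate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    use = df[[time_col, event_col, *covariates]].dropna().copy()
    use[event_col] = use[event_col].astype(bool)
    n_events = int(use[event_col].sum())
    if n_events < 1:
        raise SurvivalInputError("no events in the data")
    for c in covariates:
        if use[c].nunique() <= 1:
            raise CoxDivergenceError(f"covariate {c!r} is constant on the complete cases")

    if ties == "efron":
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(use, duration_col=time_col, event_col=event_col,
                        fit_options={"precision": 1e-12})
            except ConvergenceError as exc:
                raise CoxDivergenceError(
                    f"partial likelihood did not converge for {covariates}: {exc}"
                ) from exc
        coef = cph.params_.to_numpy()
        cov = cph.variance_matrix_.to_numpy()
        loglik = float(cph.log_likelihood_)
    else:
        import statsmodels.duration.hazard_regression as hz
        model = hz.PHReg(use[time_col].to_numpy(),
                         use[covariates].to_numpy(dtype=float),
                         status=use[event_col].to_numpy().astype(int),
                         ties="breslow")
        try:
            res = model.fit()
        except Exception as exc:  # noqa: BLE001
            raise CoxDivergenceError(str(exc)) from exc
        coef = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        loglik = float(model.loglike(res.params))
        cph = None
    ses = np.sqrt(np.diag(cov))
    if np.any(np.abs(coef) > 10) or np.any(ses > 50):
        j = int(np.argmax(np.abs(coef) / (1.0 + ses)))
        raise CoxDivergenceError(
            f"monotone likelihood: no finite MLE for covariate {covariates[j]!r}"
        )
    ests = [wald_estimate(c, b, s, scale=scale)
            for c, b, s in zip(covariates, coef, ses)]
    return CoxFit(names=list(covariates), coef=coef, cov=cov, loglik=loglik,
                  n=len(use), n_events=n_events, ties=ties, estimates=ests,
                  data=use.rename(columns={time_col: "time_months",
                                           event_col: "event"}),
                  cph=cph)


def schoenfeld_ph_test(fit: CoxFit, transform: str = "identity") -> pd.DataFrame:
    """Grambsch-Therneau test of proportional hazards from scaled Schoenfeld
    residuals regressed on a transform of event time.

    ``transform``: 'identity' (analysis time, the default here) or 'km'
    (1 - KM estimate at the event time).  Returns one row per covariate plus
    a 'GLOBAL' row (chi-square, df, p).  With one covariate the global test
    coincides with the covariate test.
    """
    if transform not in ("identity", "km"):
        raise ValueError("transform must be 'identity' or 'km'")
    p = len(fit.names)
    if fit.n_events <= p:
        raise SurvivalInputError("fewer events than covariates")
    if fit.cph is None:
        # refit with Efron ties to obtain residuals
        fit = cox_fit(fit.data, fit.names, ties="efron")
    resid = fit.cph.compute_residuals(fit.data, kind="schoenfeld")
    # rows are the event subjects, indexed by their row label in fit.data
    times = fit.data.loc[resid.index, "time_months"].to_numpy(dtype=float)
    order = np.argsort(times)
    R = resid[fit.names].to_numpy(dtype=float)[order]
    times = times[order]
    m = R.shape[0]

    if transform == "identity":
        g = times.copy()
    else:
        km = km_fit(fit.data["time_months"].to_numpy(),
                    fit.data["event"].to_numpy())
        g = np.array([1.0 - km.survival_at(t - 1e-12) for t in times])
    gc = g - g.mean()
    gss = float(gc @ gc)
    V = fit.cov                      # ~ (sum of per-event information)^{-1}
    U = R.T @ gc                     # score for a linear-in-g(t) coefficient

    rows = []
    Vinv = np.linalg.inv(V)
    for j, name in enumerate(fit.names):
        chi2 = m * U[j] ** 2 / (gss * Vinv[j, j])
        rows.append({"covariate": name, "chi2": float(chi2), "df": 1,
                     "p": float(stats.chi2.sf(chi2, 1))})
    chi2_g = float(m / gss * U @ V @ U)
    rows.append({"covariate": "GLOBAL", "chi2": chi2_g, "df": p,
                 "p": float(stats.chi2.sf(chi2_g, p))})
    return pd.DataFrame(rows)
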