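"""Objective-response and early-CRP-decline analyses.

Covers the ORR estimate with exact (Clopper-Pearson) confidence interval,
Fisher's exact test for 2xK response-by-quartile tables, logistic per-doubling
models, the early-decline statistic (maximum percent CRP decrease from
baseline within the first 8 weeks of treatment, floored at 0 for patients
whose CRP only rises), Youden-index cutoff selection, and the Cox model of
PFS on the decline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .survival import (CoxDivergenceError, CoxFit, EffectEstimate, cox_fit,
                       km_fit, logrank_test, wald_estimate)

#: early-decline window: measurements strictly after baseline, within 8 weeks
DECLINE_WINDOW_DAYS = 56


@dataclass(frozen=True)
class ResponseCounts:
    responders: int
    evaluable_n: int

    def __post_init__(self) -> None:
        if not (0 <= self.responders <= self.evaluable_n):
            raise ValueError("need 0 <= responders <= evaluable_n")


@dataclass(frozen=True)
class OrrResult:
    percent: float
    ci_low: float
    ci_high: float
    level: float

    def rounded(self) -> tuple[int, int, int]:
        return (round(self.percent), round(self.ci_low), round(self.ci_high))


def orr_with_ci(counts: ResponseCounts, level: float = 0.95) -> OrrResult:
    """Objective response rate in percent with the Clopper-Pearson exact CI
    (the interval that reproduces the binomial tail probabilities)."""
    if counts.evaluable_n < 1:
        raise ValueError("evaluable_n must be >= 1")
    res = stats.binomtest(counts.responders, counts.evaluable_n)
    ci = res.proportion_ci(confidence_level=level, method="exact")
    return OrrResult(percent=100.0 * counts.responders / counts.evaluable_n,
                     ci_low=100.0 * ci.low, ci_high=100.0 * ci.high,
                     level=level)


def fisher_exact(table: np.ndarray, n_mc: int = 200_000, seed: int = 0,
                 max_exact_n: int = 200) -> float:
    """Exact conditional p for a 2xK contingency table.

    Enumerates all tables with the observed margins and sums the (multivariate
    hypergeometric) probabilities not exceeding the observed table's, with a
    relative tolerance for ties.  For totals above ``max_exact_n`` a fixed-seed
    Monte-Carlo estimate over margin-preserving permutations is used.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2 or not (2 <= table.shape[1] <= 4):
        raise ValueError("table must be 2xK with K in {2, 3, 4}")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        return 1.0

    def logp(first_row: np.ndarray) -> float:
        # P(table | margins) = prod_j C(c_j, a_j) / C(n, r1)
        lp = -_lchoose(n, row[0])
        for cj, aj in zip(col, first_row):
            lp += _lchoose(cj, aj)
        return lp

    lp_obs = logp(table[0])
    if n <= max_exact_n:
        total = 0.0
        ranges = [range(0, cj + 1) for cj in col[:-1]]
        for combo in itertools.product(*ranges):
            last = row[0] - sum(combo)
            if last < 0 or last > col[-1]:
                continue
            a = np.array([*combo, last])
            lp = logp(a)
            if lp <= lp_obs + 1e-9:
                total += np.exp(lp)
        return float(min(total, 1.0))

    # Monte-Carlo: permute group labels, recompute the table probability
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(len(col)), col)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(n) < row[0]
        a = np.bincount(groups[perm], minlength=len(col))
        if logp(a) <= lp_obs + 1e-9:
            hits += 1
    return float(hits / n_mc)


def _lchoose(n: int, k: int) -> float:
    from scipy.special import gammaln
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


class LogisticSeparationError(RuntimeError):
    pass


def logistic_fit(df: pd.DataFrame, outcome_col: str,
                 covariates: list[str], scale: str = "OR") -> tuple[list[EffectEstimate], object]:
    """ML logistic regression on the complete cases; Wald CIs on the OR scale.

    Raises :class:`LogisticSeparationError` when the likelihood has no finite
    maximum (complete or quasi-complete separation), naming the covariate.
    """
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    use = df[[outcome_col, *covariates]].dropna()
    y = use[outcome_col].to_numpy(dtype=float)
    X = sm.add_constant(use[covariates].to_numpy(dtype=float))
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # noqa: BLE001 - statsmodels raises PerfectSeparation*
        j = int(np.argmax([use[c].std() for c in covariates]))
        raise LogisticSeparationError(
            f"logistic likelihood diverged (suspect covariate {covariates[j]!r}): {exc}"
        ) from exc
    coefs = np.asarray(res.params)[1:]
    ses = np.asarray(res.bse)[1:]
    if np.any(np.abs(coefs) > 15):
        j = int(np.argmax(np.abs(coefs)))
        raise LogisticSeparationError(
            f"separation: no finite MLE for covariate {covariates[j]!r}")
    ests = [wald_estimate(c, b, s, scale=scale)
            for c, b, s in zip(covariates, coefs, ses)]
    return ests, res


@dataclass(frozen=True)
class EarlyDecline:
    patient_id: str
    baseline_crp: float
    decline_pct: float          # max percent decline in (0, 56] days, >= 0
    evaluable: bool


def early_decline(time_days: np.ndarray, values: np.ndarray,
                  baseline_crp: float, patient_id: str = "") -> EarlyDecline:
    """Maximum percent CRP decline from baseline within the first 8 weeks.

    A patient is evaluable iff at least one measurement falls in (0, 56]
    days; patients whose windowed CRP never drops below baseline get 0.
    Invariant to measurement order and to values outside the window.
    """
    if not (baseline_crp > 0):
        raise ValueError("baseline CRP must be positive")
    time_days = np.asarray(time_days)
    values = np.asarray(values, dtype=float)
    mask = (time_days > 0) & (time_days <= DECLINE_WINDOW_DAYS)
    if not mask.any():
        return EarlyDecline(patient_id, baseline_crp, float("nan"), False)
    drop = 100.0 * (baseline_crp - values[mask]) / baseline_crp
    return EarlyDecline(patient_id, baseline_crp,
                        float(max(drop.max(), 0.0)), True)


def early_decline_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-patient early-decline export: patient_id, baseline_crp,
    decline_pct, evaluable."""
    crp = cohort.baseline_crp()
    rows = []
    for pid in cohort.baseline["patient_id"]:
        b = crp.loc[pid]
        if not np.isfinite(b):
            rows.append((pid, np.nan, np.nan, False))
            continue
        grp = cohort.patient_measurements(pid)
        ed = early_decline(grp["time_days"].to_numpy(),
                           grp["crp_mg_per_l"].to_numpy(), float(b), pid)
        rows.append((pid, ed.baseline_crp, ed.decline_pct, ed.evaluable))
    return pd.DataFrame(rows, columns=["patient_id", "baseline_crp",
                                       "decline_pct", "evaluable"])


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


def youden_cutoff(marker: np.ndarray, outcome: np.ndarray) -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct marker values;
    classification is marker >= cutoff -> positive.  Ties in J break toward
    the smaller cutoff.
    """
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or (~outcome).all():
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(marker)
    if len(uniq) < 2:
        raise ValueError("marker is constant")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = outcome.sum()
    n_neg = (~outcome).sum()
    best = None
    for c in candidates:
        pred = marker >= c
        sens = np.sum(pred & outcome) / n_pos
        spec = np.sum(~pred & ~outcome) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(c), float(sens), float(spec), float(j))
    return best


def decline_cox(decline_table: pd.DataFrame, endpoints: pd.DataFrame,
                landmark_weeks: float | None = None) -> tuple[EffectEstimate, CoxFit]:
    """Cox model of PFS on early decline, reported per 10% decline.

    Only evaluable patients enter.  Without a landmark, PFS time starts at
    ICI initiation (guarantee-time bias: the decline is measured over the
    first 8 weeks while follow-up begins at week 0 — interpret with care).
    With ``landmark_weeks`` set, patients event-free at the landmark are
    analyzed from that point onward.
    """
    df = decline_table.merge(endpoints, on="patient_id")
    df = df[df["evaluable"].astype(bool)].copy()
    df["decline_per10"] = df["decline_pct"] / 10.0
    if df["decline_per10"].nunique() <= 1:
        raise CoxDivergenceError("early decline is degenerate (constant); no effect estimable")
    if landmark_weeks is not None:
        lm = landmark_weeks * 7.0 / 30.4375
        df = df[df["time_months"] > lm].copy()
        df["time_months"] = df["time_months"] - lm
    fit = cox_fit(df, ["decline_per10"])
    return fit.estimates[0], fit


def decline_km_display(decline_table: pd.DataFrame, endpoints: pd.DataFrame,
                       cutoff_pct: float) -> dict:
    """Cutoff-dichotomized KM curves plus log-rank, for the display that
    accompanies the early-decline analysis."""
    df = decline_table.merge(endpoints, on="patient_id")
    df = df[df["evaluable"].astype(bool)]
    group = np.where(df["decline_pct"] >= cutoff_pct, "decline>=cutoff", "decline<cutoff")
    chi2, dfree, p = logrank_test(df["time_months"].to_numpy(),
                                  df["event"].to_numpy(), group)
    curves = {g: km_fit(df.loc[group == g, "time_months"].to_numpy(),
                        df.loc[group == g, "event"].to_numpy())
              for g in np.unique(group)}
    return {"curves": curves, "logrank_chi2": chi2, "df": dfree, "p": p}
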