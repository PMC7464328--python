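"""Cohort data model: baseline table, long-format CRP series, derived endpoints.

Time convention: all raw times are integer day indices relative to the start
of immune-checkpoint-inhibitor (ICI) therapy (day 0).  Survival analyses work
in months using a fixed divisor of 30.4375 days/month so that conversions are
reproducible.  CRP is in mg/L throughout; the assay quantification range is
[0.3, 350] mg/L and values outside it are rejected at load time rather than
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375
#: administrative truncation of both PFS and OS, in months
TRUNCATION_MONTHS = 24.0
#: assay limits of quantification, mg/L
CRP_LOWER, CRP_UPPER = 0.3, 350.0
#: baseline window: closest measurement within 14 days prior to (and
#: including) the start date
BASELINE_WINDOW_DAYS = 14

VALID_SEX = {"female", "male"}
VALID_RESPONSE = {"CR", "PR", "SD", "PD", "NE"}
VALID_TREATMENT_LINE = {"1", "2", "3+"}

BASELINE_COLUMNS = [
    "patient_id", "start_day", "age_years", "sex", "stage_iv_at_dx",
    "treatment_line", "response", "nlr", "ldh", "lipi",
]
OUTCOME_COLUMNS = ["progression_months", "death_months", "last_contact_months"]
LABS_COLUMNS = ["patient_id", "time_days", "crp_mg_per_l"]


class CohortError(ValueError):
    """Base class for cohort construction failures."""


class SchemaError(CohortError):
    """A mandatory column is missing or a file cannot be parsed."""


class IntegrityError(CohortError):
    """Cross-table consistency violated (unknown patient, duplicate row...)."""


class ValidationError(CohortError):
    """A cell value violates a type invariant."""


@dataclass(frozen=True)
class QuartileScheme:
    """CRP quartile cutoffs with closed upper bounds (value <= cutoff -> lower
    category).  Defaults are the discovery-cohort cutoffs in mg/L."""

    cutoffs: tuple[float, float, float] = (7.7, 21.6, 66.1)
    labels: tuple[str, str, str, str] = ("Q1", "Q2", "Q3", "Q4")

    def __post_init__(self) -> None:
        c = self.cutoffs
        if not (0 < c[0] < c[1] < c[2]):
            raise ValueError("quartile cutoffs must be strictly ascending and positive")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    endpoint: str  # "PFS" | "OS"
    time_months: float
    event: bool


@dataclass
class CohortTable:
    """One study cohort: baseline table (one row per patient, indexed by
    patient_id), long-format labs table, and a provenance note."""

    baseline: pd.DataFrame
    labs: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        unknown = set(self.labs["patient_id"]) - set(self.baseline["patient_id"])
        if unknown:
            raise IntegrityError(f"labs reference unknown patient_id(s): {sorted(unknown)[:5]}")
        dup = self.labs.duplicated(subset=["patient_id", "time_days"])
        if dup.any():
            row = self.labs[dup].iloc[0]
            raise IntegrityError(
                f"duplicate (patient, time) lab row: patient {row['patient_id']} "
                f"at day {row['time_days']}"
            )
        self.labs = self.labs.sort_values(["patient_id", "time_days"]).reset_index(drop=True)

    @property
    def n_patients(self) -> int:
        return len(self.baseline)

    def patient_measurements(self, patient_id: str) -> pd.DataFrame:
        return self.labs[self.labs["patient_id"] == patient_id]

    def baseline_crp(self) -> pd.Series:
        """Baseline CRP per patient: the measurement in [-14, 0] days closest
        to the start date; NaN when no draw falls in the window."""
        out = {}
        for pid, grp in self.labs.groupby("patient_id"):
            out[pid] = select_baseline_crp(grp["time_days"].to_numpy(),
                                           grp["crp_mg_per_l"].to_numpy())
        s = pd.Series(out, dtype=float).reindex(self.baseline["patient_id"])
        s.index.name = "patient_id"
        return s

    def endpoints(self, endpoint: str) -> pd.DataFrame:
        """Survival records for 'PFS' or 'OS', truncated at 24 months.

        Requires the outcome columns (progression_months, death_months,
        last_contact_months) on the baseline table.
        """
        missing = [c for c in OUTCOME_COLUMNS if c not in self.baseline.columns]
        if missing:
            raise SchemaError(f"baseline table lacks outcome columns: {missing}")
        recs = []
        for _, row in self.baseline.iterrows():
            rec = derive_endpoint(
                progression_time_months=_nan_to_none(row["progression_months"]),
                death_time_months=_nan_to_none(row["death_months"]),
                last_contact_months=float(row["last_contact_months"]),
                endpoint=endpoint,
                patient_id=str(row["patient_id"]),
            )
            recs.append(rec)
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in recs],
                "endpoint": [r.endpoint for r in recs],
                "time_months": [r.time_months for r in recs],
                "event": [r.event for r in recs],
            }
        )

    def analysis_frame(self, endpoint: str = "PFS",
                       scheme: QuartileScheme | None = None) -> pd.DataFrame:
        """Per-patient frame joining baseline covariates, derived baseline CRP
        (with log2 transform and quartile), and the requested endpoint.
        Rows are not dropped here; complete-case filtering is per-analysis."""
        scheme = scheme or QuartileScheme()
        ep = self.endpoints(endpoint).set_index("patient_id")
        df = self.baseline.set_index("patient_id").copy()
        crp = self.baseline_crp()
        df["baseline_crp"] = crp
        df["log2_crp"] = [log2_dose(v) if np.isfinite(v) and v > 0 else np.nan for v in crp]
        df["crp_quartile"] = [
            assign_quartile(v, scheme) if np.isfinite(v) else None for v in crp
        ]
        df["time_months"] = ep["time_months"]
        df["event"] = ep["event"]
        return df.reset_index()


def _nan_to_none(x) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x):
        return None
    return float(x)


def select_baseline_crp(time_days: np.ndarray, values: np.ndarray) -> float:
    """Baseline CRP: the value whose draw time lies in [-14, 0] days and is
    closest to the start date.  Returns NaN when no draw falls in the window.
    Order-invariant; ties at equal times are excluded upstream."""
    time_days = np.asarray(time_days)
    values = np.asarray(values, dtype=float)
    mask = (time_days >= -BASELINE_WINDOW_DAYS) & (time_days <= 0)
    if not mask.any():
        return float("nan")
    t, v = time_days[mask], values[mask]
    return float(v[np.argmax(t)])


def derive_endpoint(progression_time_months: float | None,
                    death_time_months: float | None,
                    last_contact_months: float,
                    endpoint: str,
                    patient_id: str = "") -> SurvivalRecord:
    """Construct a PFS or OS record with administrative truncation at 24 months.

    PFS event = progression or death, whichever comes first; OS event = death.
    Otherwise censored at the last-contact date.
    """
    if endpoint not in ("PFS", "OS"):
        raise ValueError(f"endpoint must be PFS or OS, got {endpoint!r}")
    for name, t in (("progression", progression_time_months),
                    ("death", death_time_months)):
        if t is not None and t <= 0:
            raise ValidationError(f"{name} time must be positive (patient {patient_id})")
        if t is not None and t > last_contact_months + 1e-9:
            raise IntegrityError(
                f"{name} at {t} months after last contact {last_contact_months} "
                f"(patient {patient_id})"
            )
    if last_contact_months <= 0:
        raise ValidationError(f"last_contact_months must be positive (patient {patient_id})")

    if endpoint == "PFS":
        candidates = [t for t in (progression_time_months, death_time_months) if t is not None]
        event_time = min(candidates) if candidates else None
    else:
        event_time = death_time_months

    if event_time is not None:
        time, event = event_time, True
    else:
        time, event = last_contact_months, False
    if time > TRUNCATION_MONTHS:
        time, event = TRUNCATION_MONTHS, False
    return SurvivalRecord(patient_id=patient_id, endpoint=endpoint,
                          time_months=float(time), event=bool(event))


def assign_quartile(crp: float, scheme: QuartileScheme | None = None) -> str:
    """Quartile category under the closed-upper-bound rule: value <= cutoff
    falls in the lower category; above the top cutoff is Q4."""
    scheme = scheme or QuartileScheme()
    if not (crp > 0):
        raise ValueError(f"CRP must be positive, got {crp}")
    for cutoff, label in zip(scheme.cutoffs, scheme.labels[:3]):
        if crp <= cutoff:
            return label
    return scheme.labels[3]


def log2_dose(crp: float) -> float:
    """log2-transformed CRP: one unit of the regression covariate is one
    doubling of the marker."""
    if not (crp > 0):
        raise ValueError(f"log2_dose requires a positive value, got {crp}")
    return float(np.log2(crp))


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def load_cohort(baseline_path, labs_path, provenance: str | None = None) -> CohortTable:
    """Read and validate the two delimited inputs into a :class:`CohortTable`.

    Rows violating type invariants are rejected with row-addressed messages;
    nothing is silently coerced or clamped.
    """
    base = _read_delimited(baseline_path)
    labs = _read_delimited(labs_path)

    missing = [c for c in BASELINE_COLUMNS if c not in base.columns]
    if missing:
        raise SchemaError(f"baseline file missing column(s): {missing}")
    missing = [c for c in LABS_COLUMNS if c not in labs.columns]
    if missing:
        raise SchemaError(f"labs file missing column(s): {missing}")

    if base["patient_id"].duplicated().any():
        dup = base.loc[base["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise IntegrityError(f"duplicate patient_id in baseline file: {dup}")

    base = base.copy()
    base["patient_id"] = base["patient_id"].astype(str)
    for i, row in base.iterrows():
        rowno = i + 2  # header + 1-based
        if not (float(row["age_years"]) > 0):
            raise ValidationError(f"baseline row {rowno}: age_years must be > 0")
        if row["sex"] not in VALID_SEX:
            raise ValidationError(f"baseline row {rowno}: sex {row['sex']!r} invalid")
        if str(row["treatment_line"]) not in VALID_TREATMENT_LINE:
            raise ValidationError(
                f"baseline row {rowno}: treatment_line {row['treatment_line']!r} invalid"
            )
        resp = row["response"]
        if not pd.isna(resp) and resp not in VALID_RESPONSE:
            raise ValidationError(f"baseline row {rowno}: response {resp!r} invalid")
        for col in ("nlr", "ldh"):
            v = row[col]
            if not pd.isna(v) and not (float(v) > 0):
                raise ValidationError(f"baseline row {rowno}: {col} must be positive")
        lipi = row["lipi"]
        if not pd.isna(lipi) and int(lipi) not in (0, 1, 2):
            raise ValidationError(f"baseline row {rowno}: lipi must be 0, 1 or 2")

    labs = labs.copy()
    labs["patient_id"] = labs["patient_id"].astype(str)
    bad = ~labs["crp_mg_per_l"].between(CRP_LOWER, CRP_UPPER)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"labs row {i + 2}: CRP {labs['crp_mg_per_l'].iloc[i]} outside the "
            f"quantification range [{CRP_LOWER}, {CRP_UPPER}] mg/L"
        )
    unknown = ~labs["patient_id"].isin(set(base["patient_id"]))
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise IntegrityError(
            f"labs row {i + 2}: unknown patient_id {labs['patient_id'].iloc[i]!r}"
        )

    return CohortTable(baseline=base, labs=labs,
                       provenance=provenance or f"files:{baseline_path},{labs_path}")


def write_cohort(cohort: CohortTable, baseline_path, labs_path) -> None:
    """Write the two delimited files read back by :func:`load_cohort`."""
    cohort.baseline.to_csv(baseline_path, index=False)
    cohort.labs.to_csv(labs_path, index=False)


def write_endpoints(cohort: CohortTable, path, endpoint: str = "PFS") -> None:
    cohort.endpoints(endpoint).to_csv(path, index=False)
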