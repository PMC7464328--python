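import numpy as np
import pandas as pd
import pytest

from crptraj.cohort import DAYS_PER_MONTH
from crptraj.joint import JointSpec, build_model, fit_joint
from crptraj.simulate import SimTruth, simulate_cohort, simulate_response


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort from the joint-model generator, reused across
    read-only tests."""
    truth = SimTruth(n_patients=150, seed=11, kappa=1.1)
    cohort = simulate_cohort(truth)
    simulate_response(cohort, truth)
    return truth, cohort


@pytest.fixture(scope="session")
def fitted_joint(default_cohort):
    """A converged current-value joint fit on the session cohort."""
    _, cohort = default_cohort
    return fit_joint(build_model(cohort, JointSpec()))


@pytest.fixture(scope="session")
def labs_months(default_cohort):
    _, cohort = default_cohort
    labs = cohort.labs.copy()
    labs["time_months"] = labs["time_days"] / DAYS_PER_MONTH
    return labs


@pytest.fixture
def cohort_files(tmp_path):
    """A small well-formed pair of baseline/labs CSV files."""
    baseline = pd.DataFrame({
        "patient_id": ["A", "B", "C"],
        "start_day": [0, 0, 0],
        "age_years": [67.0, 59.0, 74.0],
        "sex": ["female", "male", "male"],
        "stage_iv_at_dx": [True, False, True],
        "treatment_line": ["1", "2", "3+"],
        "response": ["PR", "PD", "NE"],
        "nlr": [4.7, np.nan, 8.9],
        "ldh": [263.0, 199.0, np.nan],
        "lipi": [0, 1, 2],
        "progression_months": [5.0, np.nan, np.nan],
        "death_months": [8.0, np.nan, 30.0],
        "last_contact_months": [8.0, 10.0, 30.0],
    })
    labs = pd.DataFrame({
        "patient_id": ["A", "A", "A", "B", "C"],
        "time_days": [-10, 14, 30, -3, 0],
        "crp_mg_per_l": [50.0, 40.0, 60.0, 7.7, 120.0],
    })
    bpath, lpath = tmp_path / "baseline.csv", tmp_path / "labs.csv"
    baseline.to_csv(bpath, index=False)
    labs.to_csv(lpath, index=False)
    return bpath, lpath
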