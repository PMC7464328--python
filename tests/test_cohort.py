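import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crptraj.cohort import (CohortTable, IntegrityError, QuartileScheme,
                            SchemaError, ValidationError, assign_quartile,
                            derive_endpoint, load_cohort, log2_dose,
                            select_baseline_crp, write_cohort)


class TestLoadCohort:
    def test_round_trip(self, cohort_files, tmp_path):
        cohort = load_cohort(*cohort_files)
        assert cohort.n_patients == 3
        b2, l2 = tmp_path / "b2.csv", tmp_path / "l2.csv"
        write_cohort(cohort, b2, l2)
        again = load_cohort(b2, l2)
        pd.testing.assert_frame_equal(cohort.labs, again.labs)
        assert list(again.baseline["patient_id"]) == ["A", "B", "C"]

    def test_unknown_patient_in_labs_names_row(self, cohort_files, tmp_path):
        _, lpath = cohort_files
        labs = pd.read_csv(lpath)
        labs.loc[len(labs)] = ["ZZ", 5, 10.0]
        labs.to_csv(lpath, index=False)
        with pytest.raises(IntegrityError, match="row 7.*ZZ"):
            load_cohort(cohort_files[0], lpath)

    def test_crp_outside_quantification_range(self, cohort_files, tmp_path):
        _, lpath = cohort_files
        labs = pd.read_csv(lpath)
        labs.loc[0, "crp_mg_per_l"] = 400.0
        labs.to_csv(lpath, index=False)
        with pytest.raises(ValidationError, match="400.*0.3, 350"):
            load_cohort(cohort_files[0], lpath)

    def test_missing_column_is_schema_error(self, cohort_files, tmp_path):
        bpath, _ = cohort_files
        base = pd.read_csv(bpath).drop(columns=["sex"])
        base.to_csv(bpath, index=False)
        with pytest.raises(SchemaError, match="sex"):
            load_cohort(bpath, cohort_files[1])

    def test_duplicate_lab_row_rejected(self, cohort_files):
        baseline = pd.read_csv(cohort_files[0])
        labs = pd.read_csv(cohort_files[1])
        labs = pd.concat([labs, labs.iloc[[0]]])
        with pytest.raises(IntegrityError, match="duplicate"):
            CohortTable(baseline=baseline, labs=labs)


class TestBaselineCrp:
    @pytest.mark.parametrize("times,values,expected", [
        ([-20, -10, -3], [5.0, 9.0, 12.0], 12.0),   # closest-to-start rule
        ([-16], [5.0], math.nan),                   # outside the 14-day window
        ([0], [7.7], 7.7),                          # day 0 qualifies
        ([-14], [3.0], 3.0),                        # window boundary included
        ([3, 10], [5.0, 9.0], math.nan),            # only post-start draws
    ])
    def test_window_rule(self, times, values, expected):
        got = select_baseline_crp(np.array(times), np.array(values))
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == expected

    @given(st.lists(st.tuples(st.integers(-60, 60),
                              st.floats(0.3, 350.0)),
                    min_size=1, max_size=20,
                    unique_by=lambda tv: tv[0]))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, pairs):
        t = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        ref = select_baseline_crp(t, v)
        perm = np.random.default_rng(0).permutation(len(t))
        got = select_baseline_crp(t[perm], v[perm])
        assert (math.isnan(ref) and math.isnan(got)) or ref == got


class TestDeriveEndpoint:
    def test_truncation_at_two_years(self):
        rec = derive_endpoint(30.0, None, 31.0, "PFS")
        assert rec.time_months == 24.0 and not rec.event

    def test_death_without_progression_is_pfs_event(self):
        rec = derive_endpoint(None, 5.0, 5.0, "PFS")
        assert rec.time_months == 5.0 and rec.event

    def test_alive_censored_at_last_contact(self):
        rec = derive_endpoint(None, None, 10.0, "PFS")
        assert rec.time_months == 10.0 and not rec.event

    def test_os_ignores_progression(self):
        rec = derive_endpoint(3.0, None, 10.0, "OS")
        assert rec.time_months == 10.0 and not rec.event

    def test_event_after_last_contact_is_inconsistent(self):
        with pytest.raises(IntegrityError):
            derive_endpoint(12.0, None, 10.0, "PFS")

    @given(prog=st.one_of(st.none(), st.floats(0.1, 40.0)),
           death=st.one_of(st.none(), st.floats(0.1, 40.0)),
           extra=st.floats(0.0, 10.0), bump=st.floats(0.0, 5.0))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_all_times(self, prog, death, extra, bump):
        last = max([t for t in (prog, death) if t is not None], default=1.0) + extra
        base = derive_endpoint(prog, death, last, "PFS").time_months
        bumped = derive_endpoint(None if prog is None else prog + bump,
                                 None if death is None else death + bump,
                                 last + bump, "PFS").time_months
        assert bumped >= base - 1e-12


class TestQuartiles:
    @pytest.mark.parametrize("crp,expected", [
        (7.7, "Q1"), (7.71, "Q2"), (21.6, "Q2"), (66.1, "Q3"),
        (66.2, "Q4"), (0.3, "Q1"), (350.0, "Q4"),
    ])
    def test_closed_upper_bounds(self, crp, expected):
        assert assign_quartile(crp) == expected

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, crp):
        scheme = QuartileScheme()
        label = assign_quartile(crp, scheme)
        assert label in scheme.labels

    def test_cutoffs_must_ascend(self):
        with pytest.raises(ValueError):
            QuartileScheme(cutoffs=(10.0, 5.0, 66.1))


class TestLog2Dose:
    @pytest.mark.parametrize("crp,expected", [(8.0, 3.0), (1.0, 0.0)])
    def test_exact_values(self, crp, expected):
        assert log2_dose(crp) == expected

    def test_derived_value(self):
        # one unit of the covariate is one doubling: 2**log2(66.1) == 66.1
        got = log2_dose(66.1)
        assert abs(got - 6.0466) < 5e-4
        assert abs(2.0 ** got - 66.1) < 1e-9

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_dose(0.0)


def test_endpoints_from_outcome_columns(cohort_files):
    cohort = load_cohort(*cohort_files)
    pfs = cohort.endpoints("PFS").set_index("patient_id")
    assert pfs.loc["A", "time_months"] == 5.0 and pfs.loc["A", "event"]
    assert pfs.loc["B", "time_months"] == 10.0 and not pfs.loc["B", "event"]
    # death at 30 months is truncated to a censoring at 24
    assert pfs.loc["C", "time_months"] == 24.0 and not pfs.loc["C", "event"]
    os_ = cohort.endpoints("OS").set_index("patient_id")
    assert os_.loc["A", "time_months"] == 8.0 and os_.loc["A", "event"]


def test_analysis_frame_derivations(cohort_files):
    cohort = load_cohort(*cohort_files)
    af = cohort.analysis_frame("PFS").set_index("patient_id")
    assert af.loc["A", "baseline_crp"] == 50.0
    assert af.loc["B", "crp_quartile"] == "Q1"       # 7.7 is a closed bound
    assert af.loc["C", "crp_quartile"] == "Q4"
    assert abs(af.loc["A", "log2_crp"] - np.log2(50.0)) < 1e-12
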