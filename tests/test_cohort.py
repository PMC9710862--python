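"""Cohort construction: selection, eligibility, linkage, outcomes, follow-up."""

import numpy as np
import pandas as pd
import pytest

from cvdval import cohort as coh
from cvdval import synthetic
from cvdval.cohort import (
    BASELINE_DATE,
    ELIGIBILITY,
    apply_eligibility,
    build_followup,
    build_followups,
    classify_outcome,
    determine_smoking_status,
    incidence_rate,
    link_cause_of_death,
    load_outcome_definitions,
    select_risk_assessed,
    baseline_values,
)

OUTDEFS = load_outcome_definitions()


def _meas(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "code", "value", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def _patients(rows):
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "sex", "birth_date", "postal4", "registration_start", "registration_end"],
    )
    for c in ("birth_date", "registration_start", "registration_end"):
        df[c] = pd.to_datetime(df[c])
    return df


def _diag(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "code_system", "code", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


EMPTY_DIAG = _diag([])


# ---------------------------------------------------------------------------
# smoking status
# ---------------------------------------------------------------------------


class TestSmokingStatus:
    def test_single_current_record(self):
        m = _meas([("p1", "smoking", "current", "2008-10-01")])
        assert determine_smoking_status(m, "p1").current_smoker is True

    def test_nearest_record_to_baseline_wins(self):
        # 2008-06-01 is 214 days before baseline; 2010-02-01 is 396 days
        # after: the earlier record is nearer, so the patient is a smoker
        m = _meas(
            [
                ("p1", "smoking", "current", "2008-06-01"),
                ("p1", "smoking", "never", "2010-02-01"),
            ]
        )
        d1 = abs((pd.Timestamp("2008-06-01") - BASELINE_DATE).days)
        d2 = abs((pd.Timestamp("2010-02-01") - BASELINE_DATE).days)
        assert d1 < d2  # the oracle: hand-computed day distances
        assert determine_smoking_status(m, "p1").current_smoker is True

    def test_equidistant_tie_breaks_to_earlier_record(self):
        m = _meas(
            [
                ("p1", "smoking", "current", "2008-12-31"),
                ("p1", "smoking", "never", "2009-01-02"),
            ]
        )
        s = determine_smoking_status(m, "p1")
        assert s.current_smoker is True
        assert s.date == pd.Timestamp("2008-12-31")

    def test_former_and_never_are_non_smokers(self):
        m = _meas([("p1", "smoking", "former", "2008-12-01")])
        assert determine_smoking_status(m, "p1").current_smoker is False

    def test_no_records_is_undeterminable(self):
        assert determine_smoking_status(_meas([]), "p1").current_smoker is None

    def test_only_unknown_records_is_undeterminable(self):
        m = _meas([("p1", "smoking", "unknown", "2008-12-01")])
        assert determine_smoking_status(m, "p1").current_smoker is None

    def test_records_outside_window_ignored(self):
        m = _meas([("p1", "smoking", "current", "2007-12-31")])
        assert determine_smoking_status(m, "p1").current_smoker is None


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


class TestSelection:
    SPEC = ELIGIBILITY["SCORE"]  # needs SBP, TC, HDL, smoking

    def test_fully_measured_patient_selected(self):
        m = _meas(
            [
                ("p1", "SBP", 140, "2008-09-01"),
                ("p1", "TC", 5.0, "2008-12-15"),
                ("p1", "HDL", 1.2, "2008-12-15"),
                ("p1", "smoking", "never", "2008-12-15"),
            ]
        )
        pats = _patients([("p1", "male", "1960-01-01", "1234", "2000-01-01", None)])
        assert select_risk_assessed(pats, m, self.SPEC) == {"p1"}

    def test_measurement_before_window_not_counted(self):
        m = _meas(
            [
                ("p1", "SBP", 140, "2008-06-30"),  # one day before the window
                ("p1", "TC", 5.0, "2008-12-15"),
                ("p1", "HDL", 1.2, "2008-12-15"),
                ("p1", "smoking", "never", "2008-12-15"),
            ]
        )
        pats = _patients([("p1", "male", "1960-01-01", "1234", "2000-01-01", None)])
        assert select_risk_assessed(pats, m, self.SPEC) == set()

    def test_window_is_half_open_at_end(self):
        m = _meas(
            [
                ("p1", "SBP", 140, "2009-01-01"),  # on baseline: outside
                ("p1", "TC", 5.0, "2008-12-15"),
                ("p1", "HDL", 1.2, "2008-12-15"),
                ("p1", "smoking", "never", "2008-12-15"),
            ]
        )
        pats = _patients([("p1", "male", "1960-01-01", "1234", "2000-01-01", None)])
        assert select_risk_assessed(pats, m, self.SPEC) == set()

    def test_ten_patient_fixture_selects_exactly_the_measured_four(self):
        # hand-enumerated: p0..p3 fully measured in-window; p4 misses HDL;
        # p5 SBP out of window; p6 no smoking record; p7-p9 nothing at all
        rows = []
        for i in range(4):
            rows += [
                (f"p{i}", "SBP", 140, "2008-08-01"),
                (f"p{i}", "TC", 5.0, "2008-08-01"),
                (f"p{i}", "HDL", 1.2, "2008-08-01"),
                (f"p{i}", "smoking", "never", "2008-08-01"),
            ]
        rows += [
            ("p4", "SBP", 140, "2008-08-01"),
            ("p4", "TC", 5.0, "2008-08-01"),
            ("p4", "smoking", "never", "2008-08-01"),
            ("p5", "SBP", 140, "2008-05-01"),
            ("p5", "TC", 5.0, "2008-08-01"),
            ("p5", "HDL", 1.2, "2008-08-01"),
            ("p5", "smoking", "never", "2008-08-01"),
            ("p6", "SBP", 140, "2008-08-01"),
            ("p6", "TC", 5.0, "2008-08-01"),
            ("p6", "HDL", 1.2, "2008-08-01"),
        ]
        pats = _patients(
            [(f"p{i}", "male", "1960-01-01", "1234", "2000-01-01", None) for i in range(10)]
        )
        assert select_risk_assessed(pats, _meas(rows), self.SPEC) == {
            "p0", "p1", "p2", "p3"
        }

    def test_empty_measurements_select_nothing(self):
        pats = _patients([("p1", "male", "1960-01-01", "1234", "2000-01-01", None)])
        assert select_risk_assessed(pats, _meas([]), self.SPEC) == set()

    def test_latest_measurement_wins_and_same_date_ties_average(self):
        m = _meas(
            [
                ("p1", "SBP", 120, "2008-08-01"),
                ("p1", "SBP", 150, "2008-12-01"),
                ("p1", "SBP", 160, "2008-12-01"),
            ]
        )
        vals = baseline_values(m, ["SBP"])
        assert vals.loc["p1", "SBP"] == 155.0  # mean of the two latest-date readings


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


class TestEligibility:
    def _pats(self, birth):
        return _patients([("p1", "male", birth, "1234", "2000-01-01", None)])

    def test_age_boundaries_by_model(self):
        cases = [
            # (birth date, completed age at 2009-01-01, SCORE?, Globorisk?)
            ("1969-06-01", 39, False, False),
            ("1968-12-31", 40, True, True),
            ("1938-06-01", 70, True, True),
            ("1937-06-01", 71, False, True),
            ("1936-06-01", 72, False, True),
            ("1934-06-01", 74, False, True),
            ("1933-06-01", 75, False, False),
        ]
        for birth, age, score_in, globo_in in cases:
            pats = self._pats(birth)
            assert coh.completed_age(pats["birth_date"], BASELINE_DATE).iloc[0] == age
            got_score = len(apply_eligibility(pats, EMPTY_DIAG, ELIGIBILITY["SCORE"])) == 1
            got_globo = len(apply_eligibility(pats, EMPTY_DIAG, ELIGIBILITY["GLOBO_LAB"])) == 1
            assert got_score == score_in, (birth, age)
            assert got_globo == globo_in, (birth, age)

    def test_diabetes_history_excludes_score_not_globorisk(self):
        pats = self._pats("1955-06-01")
        dm = _diag([("p1", "ICPC-2", "T90", "2005-03-01")])
        assert len(apply_eligibility(pats, dm, ELIGIBILITY["SCORE"])) == 0
        assert len(apply_eligibility(pats, dm, ELIGIBILITY["GLOBO_LAB"])) == 1

    def test_stroke_history_excludes_all_models(self):
        pats = self._pats("1955-06-01")
        stroke = _diag([("p1", "ICD-10", "I63.9", "2007-03-01")])
        for model in ("SCORE", "SCORE_FNF", "GLOBO_LAB", "GLOBO_OFFICE"):
            assert len(apply_eligibility(pats, stroke, ELIGIBILITY[model])) == 0

    def test_diagnosis_on_or_after_baseline_does_not_exclude(self):
        pats = self._pats("1955-06-01")
        post = _diag([("p1", "ICPC-2", "T90", "2009-01-01")])
        assert len(apply_eligibility(pats, post, ELIGIBILITY["SCORE"])) == 1

    def test_missing_birth_date_dropped_with_warning(self, caplog):
        pats = _patients(
            [
                ("p1", "male", None, "1234", "2000-01-01", None),
                ("p2", "male", "1955-06-01", "1234", "2000-01-01", None),
            ]
        )
        with caplog.at_level("WARNING"):
            out = apply_eligibility(pats, EMPTY_DIAG, ELIGIBILITY["SCORE"])
        assert list(out["patient_id"]) == ["p2"]
        assert "missing birth_date" in caplog.text

    def test_selection_and_eligibility_commute(self):
        tabs = synthetic.simulate_tables(synthetic.SimulationConfig(n=2000, seed=7))
        spec = ELIGIBILITY["SCORE_FNF"]
        sel = select_risk_assessed(tabs["patients"], tabs["measurements"], spec)
        elig_first = apply_eligibility(tabs["patients"], tabs["diagnoses"], spec)
        a = set(elig_first["patient_id"]) & sel
        sel_first = tabs["patients"][tabs["patients"]["patient_id"].isin(sel)]
        b = set(apply_eligibility(sel_first, tabs["diagnoses"], spec)["patient_id"])
        assert a == b


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


def _registry(rows):
    df = pd.DataFrame(rows, columns=["sex", "birth_date", "postal4", "death_date", "cause_icd10"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


class TestLinkage:
    def test_unique_triple_links(self):
        pats = _patients([("p1", "male", "1950-01-01", "1234", "2000-01-01", None)])
        reg = _registry([("male", "1950-01-01", "1234", "2015-06-01", "I21")])
        res = link_cause_of_death(pats, reg)
        assert res.n_linked == 1 and res.n_ambiguous == 0
        assert res.links["p1"].cause_icd10 == "I21"

    def test_duplicate_registry_key_is_ambiguous_and_unlinked(self):
        pats = _patients([("p1", "male", "1950-01-01", "1234", "2000-01-01", None)])
        reg = _registry(
            [
                ("male", "1950-01-01", "1234", "2015-06-01", "I21"),
                ("male", "1950-01-01", "1234", "2016-06-01", "C80"),
            ]
        )
        res = link_cause_of_death(pats, reg)
        assert res.n_linked == 0 and res.n_ambiguous == 1
        assert "p1" not in res.links

    def test_two_patients_sharing_a_key_are_ambiguous(self):
        pats = _patients(
            [
                ("p1", "male", "1950-01-01", "1234", "2000-01-01", None),
                ("p2", "male", "1950-01-01", "1234", "2000-01-01", None),
            ]
        )
        reg = _registry([("male", "1950-01-01", "1234", "2015-06-01", "I21")])
        res = link_cause_of_death(pats, reg)
        assert res.n_linked == 0 and res.n_ambiguous == 2

    def test_hundred_registry_rows_with_five_planted_duplicates(self):
        rng = np.random.default_rng(3)
        births = pd.Timestamp("1940-01-01") + pd.to_timedelta(
            rng.choice(20000, 100, replace=False), unit="D"
        )
        pats = _patients(
            [
                (f"p{i}", "female", births[i], f"{1000 + i}", "2000-01-01", None)
                for i in range(100)
            ]
        )
        rows = [
            ("female", births[i], f"{1000 + i}", "2015-01-01", "I21") for i in range(100)
        ]
        rows += [rows[i] for i in range(5)]  # plant 5 duplicate keys
        res = link_cause_of_death(pats, _registry(rows))
        assert res.n_linked == 95
        assert res.n_ambiguous == 5

    def test_unique_keys_recover_all_true_matches(self):
        tabs = synthetic.simulate_tables(synthetic.SimulationConfig(n=3000, seed=11))
        reg = tabs["death_registry"].drop_duplicates(subset=["sex", "birth_date", "postal4"], keep=False)
        pats = tabs["patients"]
        keys = pats[["sex", "birth_date", "postal4"]].apply(tuple, axis=1)
        unique_pat = pats[~keys.duplicated(keep=False)]
        res = link_cause_of_death(unique_pat, reg)
        # every registry row whose key matches exactly one patient must link
        merged = unique_pat.merge(reg, on=["sex", "birth_date", "postal4"])
        assert res.n_linked == merged["patient_id"].nunique()


# ---------------------------------------------------------------------------
# outcomes and follow-up
# ---------------------------------------------------------------------------


class TestClassifyOutcome:
    def test_aortic_aneurysm_death_is_score_event(self):
        death = {"cause_icd10": "I71.4"}
        assert classify_outcome(death, OUTDEFS["SCORE"]) == (True, "fatal")

    def test_heart_failure_admission_counts_for_fnf_not_globorisk(self):
        hf = {"code_system": "ICPC-2", "code": "K77", "cause_icd10": None}
        assert classify_outcome(hf, OUTDEFS["SCORE_FNF"]) == (True, "nonfatal")
        assert classify_outcome(hf, OUTDEFS["GLOBO_LAB"])[0] is False

    def test_cancer_death_is_competing(self):
        death = {"cause_icd10": "C80"}
        assert classify_outcome(death, OUTDEFS["SCORE"]) == (False, "competing_death")

    def test_unknown_code_system_errors(self):
        with pytest.raises(ValueError, match="code system"):
            classify_outcome({"code_system": "SNOMED", "code": "x", "cause_icd10": None}, OUTDEFS["SCORE"])

    def test_globorisk_definitions_are_shared(self):
        assert OUTDEFS["GLOBO_LAB"] == OUTDEFS["GLOBO_OFFICE"].__class__(
            model_id="GLOBO_LAB",
            fatal_codes=OUTDEFS["GLOBO_OFFICE"].fatal_codes,
            nonfatal_codes=OUTDEFS["GLOBO_OFFICE"].nonfatal_codes,
        )


class TestFollowUp:
    PAT = {"patient_id": "p1", "registration_end": None}

    def test_event_before_deregistration(self):
        # MI 1169 days after baseline (3.2 y), deregistration at 8 y
        diag = _diag([("p1", "ICPC-2", "K75", "2012-03-15")])
        pat = {"patient_id": "p1", "registration_end": pd.Timestamp("2017-01-01")}
        rec = build_followup(pat, diag, None, OUTDEFS["SCORE_FNF"])
        days = (pd.Timestamp("2012-03-15") - BASELINE_DATE).days
        assert rec.event and rec.censor_reason == "none"
        assert rec.time_years == pytest.approx(days / 365.25)

    def test_no_events_censors_at_horizon(self):
        rec = build_followup(self.PAT, EMPTY_DIAG, None, OUTDEFS["SCORE_FNF"])
        assert rec == coh.FollowUpRecord("p1", BASELINE_DATE, 10.0, False, "horizon_10y")

    def test_non_cvd_death_censors(self):
        death = {"cause_icd10": "C80", "death_date": BASELINE_DATE + pd.Timedelta(days=2191)}
        rec = build_followup(self.PAT, EMPTY_DIAG, death, OUTDEFS["SCORE_FNF"])
        assert not rec.event
        assert rec.censor_reason == "non_cvd_death"
        assert rec.time_years == pytest.approx(2191 / 365.25)

    def test_fatal_cvd_death_is_event(self):
        death = {"cause_icd10": "I21", "death_date": BASELINE_DATE + pd.Timedelta(days=730)}
        rec = build_followup(self.PAT, EMPTY_DIAG, death, OUTDEFS["SCORE"])
        assert rec.event and rec.time_years == pytest.approx(730 / 365.25)

    def test_event_after_horizon_ignored(self):
        diag = _diag([("p1", "ICPC-2", "K75", "2020-06-01")])
        rec = build_followup(self.PAT, diag, None, OUTDEFS["SCORE_FNF"])
        assert not rec.event and rec.censor_reason == "horizon_10y"

    def test_prevalent_event_raises(self):
        diag = _diag([("p1", "ICPC-2", "K75", "2008-06-01")])
        with pytest.raises(ValueError, match="precedes baseline"):
            build_followup(self.PAT, diag, None, OUTDEFS["SCORE_FNF"])

    def test_deregistration_censors_before_admin_end(self):
        pat = {"patient_id": "p1", "registration_end": pd.Timestamp("2014-01-01")}
        rec = build_followup(pat, EMPTY_DIAG, None, OUTDEFS["SCORE_FNF"])
        assert rec.censor_reason == "deregistered"
        assert rec.time_years == pytest.approx((pd.Timestamp("2014-01-01") - BASELINE_DATE).days / 365.25)

    def test_batch_matches_scalar(self):
        tabs = synthetic.simulate_tables(
            synthetic.SimulationConfig(n=400, seed=5, duplicate_key_rate=0.05)
        )
        spec = ELIGIBILITY["SCORE_FNF"]
        eligible = apply_eligibility(tabs["patients"], tabs["diagnoses"], spec)
        linkage = link_cause_of_death(eligible, tabs["death_registry"])
        batch = build_followups(eligible, tabs["diagnoses"], linkage, OUTDEFS["SCORE_FNF"])
        for row in eligible.itertuples(index=False):
            rec = build_followup(
                row, tabs["diagnoses"], linkage.links.get(row.patient_id), OUTDEFS["SCORE_FNF"]
            )
            got = batch[batch["patient_id"] == row.patient_id].iloc[0]
            assert got["time_years"] == pytest.approx(rec.time_years)
            assert bool(got["event"]) == rec.event
            assert got["censor_reason"] == rec.censor_reason

    def test_followup_bookkeeping_conserves_cohort(self):
        tabs = synthetic.simulate_tables(synthetic.SimulationConfig(n=2000, seed=9))
        spec = ELIGIBILITY["GLOBO_LAB"]
        eligible = apply_eligibility(tabs["patients"], tabs["diagnoses"], spec)
        linkage = link_cause_of_death(eligible, tabs["death_registry"])
        fu = build_followups(eligible, tabs["diagnoses"], linkage, OUTDEFS["GLOBO_LAB"])
        assert len(fu) == len(eligible)
        assert ((fu["time_years"] > 0) & (fu["time_years"] <= 10)).all()
        assert (fu["event"] == (fu["censor_reason"] == "none")).all()
        counts = fu["censor_reason"].value_counts()
        assert counts.sum() == len(eligible)


class TestIncidenceRate:
    def test_simple_arithmetic(self):
        fu = pd.DataFrame({"time_years": [200.0] * 10, "event": [True] * 10})
        assert incidence_rate(fu) == 5.0

    def test_no_events_is_zero(self):
        fu = pd.DataFrame({"time_years": [1.0, 2.0], "event": [False, False]})
        assert incidence_rate(fu) == 0.0

    def test_zero_person_time_errors(self):
        with pytest.raises(ValueError):
            incidence_rate(pd.DataFrame({"time_years": [], "event": []}))

    def test_constant_hazard_recovered(self, rng):
        # exponential events censored administratively at 10 years: the
        # events-per-person-time estimator recovers the hazard
        h = 0.01
        n = 50_000
        t = rng.exponential(1 / h, n)
        event = t <= 10
        time = np.minimum(t, 10.0)
        fu = pd.DataFrame({"time_years": time, "event": event})
        rate = incidence_rate(fu)
        se = 1000 * np.sqrt(event.sum()) / time.sum()
        assert rate == pytest.approx(1000 * h, abs=3 * se)
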