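"""Cohort construction from routine general-practice tables.

Input is four tabular sources (CSV, ISO-8601 dates):

``patients``
    patient_id, sex (male/female), birth_date, postal4, registration_start,
    registration_end (empty when the patient remained registered).
``measurements``
    patient_id, code (SBP | TC | HDL | BMI | smoking), value, date.  Smoking
    values are categorical: current / former / never / unknown.
``diagnoses``
    patient_id, code_system (ICPC-1 | ICPC-2 | ICD-10), code, date.
``death_registry``
    sex, birth_date, postal4, death_date, cause_icd10 — the national
    cause-of-death registry, linkable only on the (sex, birth_date, postal4)
    key triple.

The pipeline mirrors how a risk-validation cohort is assembled from such
records: patients are considered "risk assessed" when every predictor the
target model needs was measured in the half-open window [2008-07-01,
2009-01-01); model eligibility applies age bands and history exclusions at
the 2009-01-01 baseline; deaths are linked deterministically; outcomes are
classified per model (ICD-10 fatal causes by 3-character prefix, ICPC
non-fatal diagnoses by exact code); and follow-up runs to the earliest of
first event, deregistration, non-CVD death, administrative end (2019-01-01)
or the 10-year horizon.  Non-CVD death is treated as censoring (plain
Kaplan-Meier follow-up, not a competing-risk analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BASELINE_DATE",
    "MEASUREMENT_WINDOW",
    "SMOKING_WINDOW",
    "ADMIN_END",
    "HORIZON_YEARS",
    "DAYS_PER_YEAR",
    "EligibilitySpec",
    "OutcomeDefinition",
    "SmokingStatus",
    "FollowUpRecord",
    "LinkageResult",
    "ELIGIBILITY",
    "load_outcome_definitions",
    "read_tables",
    "determine_smoking_status",
    "select_risk_assessed",
    "baseline_values",
    "apply_eligibility",
    "link_cause_of_death",
    "classify_outcome",
    "build_followup",
    "build_followups",
    "incidence_rate",
    "build_profiles",
    "build_cohort",
]

BASELINE_DATE = pd.Timestamp("2009-01-01")
MEASUREMENT_WINDOW = (pd.Timestamp("2008-07-01"), pd.Timestamp("2009-01-01"))
SMOKING_WINDOW = (pd.Timestamp("2008-01-01"), pd.Timestamp("2019-01-01"))
ADMIN_END = pd.Timestamp("2019-01-01")
HORIZON_YEARS = 10.0
DAYS_PER_YEAR = 365.25

_ICPC_SYSTEMS = {"ICPC", "ICPC-1", "ICPC-2"}

_CENSOR_PRIORITY = ("horizon_10y", "non_cvd_death", "deregistered", "admin_end")


@dataclass(frozen=True)
class EligibilitySpec:
    model_id: str
    age_min: int
    age_max: int
    exclusion_icpc: frozenset  # exact ICPC codes
    exclusion_icd10: frozenset  # 3-character ICD-10 prefixes
    required_predictors: frozenset  # measurement kinds, may include "smoking"


@dataclass(frozen=True)
class OutcomeDefinition:
    model_id: str
    fatal_codes: frozenset  # ICD-10 3-character prefixes
    nonfatal_codes: frozenset  # exact ICPC codes


@dataclass(frozen=True)
class SmokingStatus:
    current_smoker: bool | None  # None = undeterminable
    date: pd.Timestamp | None = None


@dataclass(frozen=True)
class FollowUpRecord:
    patient_id: object
    baseline_date: pd.Timestamp
    time_years: float
    event: bool
    censor_reason: str  # horizon_10y / admin_end / deregistered / non_cvd_death / none

    def __post_init__(self):
        if not 0.0 < self.time_years <= HORIZON_YEARS + 1e-9:
            raise ValueError(f"time_years out of (0, 10]: {self.time_years}")
        if self.event != (self.censor_reason == "none"):
            raise ValueError("event records must have censor_reason='none' and vice versa")


@dataclass
class LinkageResult:
    links: dict  # patient_id -> registry row (pd.Series)
    n_linked: int
    n_ambiguous: int
    n_unlinked: int
    ambiguous_patient_ids: frozenset = field(default_factory=frozenset)


# history exclusions: diabetes and/or prior CVD, coded in either system
_DM_ICPC = frozenset({"T90"})
_DM_ICD10 = frozenset({"E10", "E11", "E12", "E13", "E14"})
_CVD_ICPC = frozenset({"K74", "K75", "K76", "K77", "K89", "K90", "K92"})
_CVD_ICD10 = frozenset(
    {"I20", "I21", "I22", "I23", "I24", "I25", "I60", "I61", "I62", "I63", "I64",
     "I70", "I71", "I72", "I73", "I74"}
)
# Globorisk excludes prior stroke or coronary heart disease only
_STROKE_CHD_ICPC = frozenset({"K74", "K75", "K76", "K89", "K90"})
_STROKE_CHD_ICD10 = frozenset(
    {"I20", "I21", "I22", "I23", "I24", "I25", "I60", "I61", "I62", "I63", "I64"}
)

_SCORE_SPEC = EligibilitySpec(
    model_id="SCORE",
    age_min=40,
    age_max=70,
    exclusion_icpc=_DM_ICPC | _CVD_ICPC,
    exclusion_icd10=_DM_ICD10 | _CVD_ICD10,
    required_predictors=frozenset({"SBP", "TC", "HDL", "smoking"}),
)

ELIGIBILITY: dict[str, EligibilitySpec] = {
    "SCORE": _SCORE_SPEC,
    "SCORE_FNF": EligibilitySpec(**{**_SCORE_SPEC.__dict__, "model_id": "SCORE_FNF"}),
    "GLOBO_LAB": EligibilitySpec(
        model_id="GLOBO_LAB",
        age_min=40,
        age_max=74,
        exclusion_icpc=_STROKE_CHD_ICPC,
        exclusion_icd10=_STROKE_CHD_ICD10,
        required_predictors=frozenset({"SBP", "TC", "smoking"}),
    ),
    "GLOBO_OFFICE": EligibilitySpec(
        model_id="GLOBO_OFFICE",
        age_min=40,
        age_max=74,
        exclusion_icpc=_STROKE_CHD_ICPC,
        exclusion_icd10=_STROKE_CHD_ICD10,
        required_predictors=frozenset({"SBP", "BMI", "smoking"}),
    ),
}


def load_outcome_definitions(path=None) -> dict[str, OutcomeDefinition]:
    """Load the model/code mapping (CSV: model_id, code_system, code, role)."""
    if path is None:
        path = resources.files("cvdval").joinpath("data", "outcome_codes.csv")
    table = pd.read_csv(str(path))
    out = {}
    for model_id, sub in table.groupby("model_id"):
        fatal = sub.loc[sub["role"] == "fatal", "code"]
        nonfatal = sub.loc[sub["role"] == "nonfatal", "code"]
        out[model_id] = OutcomeDefinition(
            model_id=model_id,
            fatal_codes=frozenset(fatal.str.slice(0, 3)),
            nonfatal_codes=frozenset(nonfatal),
        )
    # structural invariants of the mapping
    if out["SCORE"].nonfatal_codes:
        raise ValueError("SCORE outcome must be fatal-only")
    if not out["SCORE_FNF"].fatal_codes >= out["SCORE"].fatal_codes:
        raise ValueError("SCORE_FNF fatal codes must contain the SCORE fatal codes")
    if (out["GLOBO_LAB"].fatal_codes, out["GLOBO_LAB"].nonfatal_codes) != (
        out["GLOBO_OFFICE"].fatal_codes,
        out["GLOBO_OFFICE"].nonfatal_codes,
    ):
        raise ValueError("the two Globorisk variants must share one outcome definition")
    return out


def read_tables(directory) -> dict[str, pd.DataFrame]:
    """Read the four input CSVs from ``directory``, parsing all date columns."""
    directory = Path(directory)
    date_cols = {
        "patients": ["birth_date", "registration_start", "registration_end"],
        "measurements": ["date"],
        "diagnoses": ["date"],
        "death_registry": ["birth_date", "death_date"],
    }
    out = {}
    for name, cols in date_cols.items():
        df = pd.read_csv(directory / f"{name}.csv")
        for c in cols:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
        out[name] = df
    out["patients"]["postal4"] = out["patients"]["postal4"].astype(str)
    out["death_registry"]["postal4"] = out["death_registry"]["postal4"].astype(str)
    return out


# ---------------------------------------------------------------------------
# smoking status
# ---------------------------------------------------------------------------


def determine_smoking_status(
    measurements: pd.DataFrame,
    patient_id,
    baseline_date: pd.Timestamp = BASELINE_DATE,
    window: tuple[pd.Timestamp, pd.Timestamp] = SMOKING_WINDOW,
) -> SmokingStatus:
    """Resolve current-smoker status from the record nearest to baseline.

    Records valued ``unknown`` are ignored; ``former`` and ``never`` count as
    non-smoker.  Ties in distance to baseline break toward the earlier
    record.  With no usable record the status is undeterminable
    (``current_smoker is None``) and the patient cannot enter cohorts whose
    model requires smoking.
    """
    rows = measurements[
        (measurements["patient_id"] == patient_id)
        & (measurements["code"] == "smoking")
        & (measurements["date"] >= window[0])
        & (measurements["date"] < window[1])
        & (measurements["value"] != "unknown")
    ]
    if rows.empty:
        return SmokingStatus(None)
    dist = (rows["date"] - baseline_date).abs()
    best = rows.loc[dist == dist.min()].sort_values("date").iloc[0]
    return SmokingStatus(best["value"] == "current", best["date"])


def _smoking_status_frame(
    measurements: pd.DataFrame,
    baseline_date: pd.Timestamp = BASELINE_DATE,
    window=SMOKING_WINDOW,
) -> pd.DataFrame:
    """Vectorised nearest-record smoking status for all patients."""
    rows = measurements[
        (measurements["code"] == "smoking")
        & (measurements["date"] >= window[0])
        & (measurements["date"] < window[1])
        & (measurements["value"] != "unknown")
    ].copy()
    if rows.empty:
        return pd.DataFrame(columns=["patient_id", "smoker"]).set_index("patient_id")
    rows["dist"] = (rows["date"] - baseline_date).abs()
    rows = rows.sort_values(["patient_id", "dist", "date"])
    best = rows.groupby("patient_id", sort=False).first()
    return pd.DataFrame({"smoker": best["value"] == "current"})


# ---------------------------------------------------------------------------
# selection and eligibility
# ---------------------------------------------------------------------------


def select_risk_assessed(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    spec: EligibilitySpec,
    window=MEASUREMENT_WINDOW,
    baseline_date: pd.Timestamp = BASELINE_DATE,
) -> set:
    """Patients with every required predictor measured in the half-open window.

    The smoking predictor follows its own (wider) record window and counts
    only when a determinable status exists.
    """
    ids = set(patients["patient_id"])
    numeric = spec.required_predictors - {"smoking"}
    inwin = measurements[
        (measurements["date"] >= window[0])
        & (measurements["date"] < window[1])
        & measurements["code"].isin(numeric)
    ]
    counts = inwin.groupby("patient_id")["code"].nunique()
    ids &= set(counts.index[counts == len(numeric)])
    if "smoking" in spec.required_predictors:
        status = _smoking_status_frame(measurements, baseline_date)
        ids &= set(status.index)
    return ids


def baseline_values(
    measurements: pd.DataFrame,
    kinds: Iterable[str],
    window=MEASUREMENT_WINDOW,
) -> pd.DataFrame:
    """Most recent in-window value per patient and kind (same-date ties: mean).

    Returns a frame indexed by patient_id with one column per kind.
    """
    kinds = [k for k in kinds if k != "smoking"]
    rows = measurements[
        (measurements["date"] >= window[0])
        & (measurements["date"] < window[1])
        & measurements["code"].isin(kinds)
    ].copy()
    rows["value"] = pd.to_numeric(rows["value"])
    latest = rows.groupby(["patient_id", "code"])["date"].transform("max")
    rows = rows[rows["date"] == latest]
    wide = rows.groupby(["patient_id", "code"])["value"].mean().unstack("code")
    return wide.reindex(columns=kinds)


def completed_age(birth_date, at: pd.Timestamp) -> pd.Series:
    """Age in completed years at ``at`` (integer floor, birthday-exact)."""
    birth = pd.to_datetime(birth_date)
    years = at.year - birth.dt.year
    before_birthday = (birth.dt.month > at.month) | (
        (birth.dt.month == at.month) & (birth.dt.day > at.day)
    )
    return years - before_birthday.astype(int)


def _exclusion_mask(diagnoses: pd.DataFrame, spec: EligibilitySpec, baseline_date) -> pd.Series:
    prior = diagnoses[diagnoses["date"] < baseline_date]
    icpc = prior["code_system"].isin(_ICPC_SYSTEMS) & prior["code"].isin(spec.exclusion_icpc)
    icd = (prior["code_system"] == "ICD-10") & prior["code"].str.slice(0, 3).isin(
        spec.exclusion_icd10
    )
    return prior.loc[icpc | icd, "patient_id"]


def apply_eligibility(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    spec: EligibilitySpec,
    baseline_date: pd.Timestamp = BASELINE_DATE,
) -> pd.DataFrame:
    """Retain patients in the model's age band with no prior exclusion diagnosis.

    Age is completed years at baseline; exclusion diagnoses must be dated
    strictly before baseline (diagnoses on or after baseline do not count —
    no look-ahead).  Patients with a missing birth date are dropped with a
    logged warning.
    """
    pts = patients.copy()
    missing = pts["birth_date"].isna()
    if missing.any():
        logger.warning("dropping %d patients with missing birth_date", missing.sum())
        pts = pts[~missing]
    pts["age"] = completed_age(pts["birth_date"], baseline_date)
    pts = pts[(pts["age"] >= spec.age_min) & (pts["age"] <= spec.age_max)]
    excluded = set(_exclusion_mask(diagnoses, spec, baseline_date))
    return pts[~pts["patient_id"].isin(excluded)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# registry linkage
# ---------------------------------------------------------------------------

_KEY = ["sex", "birth_date", "postal4"]


def link_cause_of_death(patients: pd.DataFrame, registry: pd.DataFrame) -> LinkageResult:
    """Deterministic linkage on the exact (sex, birth_date, postal4) triple.

    A key occurring more than once — on either side — is ambiguous; all
    patients carrying an ambiguous key are left unlinked.  Patients whose key
    matches no registry row are simply unlinked (most patients are alive).
    """
    reg = registry.copy()
    reg_dup = reg.duplicated(subset=_KEY, keep=False)
    pat_keys = patients[["patient_id", *_KEY]].copy()
    pat_dup = pat_keys.duplicated(subset=_KEY, keep=False)

    unique_reg = reg[~reg_dup]
    merged = pat_keys[~pat_dup].merge(unique_reg, on=_KEY, how="inner")

    ambiguous_keys = set(map(tuple, reg.loc[reg_dup, _KEY].itertuples(index=False)))
    pat_tuples = list(map(tuple, pat_keys[_KEY].itertuples(index=False)))
    amb_ids = {
        pid
        for pid, key, dup in zip(pat_keys["patient_id"], pat_tuples, pat_dup)
        if dup or key in ambiguous_keys
    }
    links = {row.patient_id: row for row in merged.itertuples(index=False)}
    n_linked = len(links)
    n_amb = len(amb_ids & set(patients["patient_id"]))
    return LinkageResult(
        links=links,
        n_linked=n_linked,
        n_ambiguous=n_amb,
        n_unlinked=len(patients) - n_linked,
        ambiguous_patient_ids=frozenset(amb_ids),
    )


# ---------------------------------------------------------------------------
# outcome classification and follow-up
# ---------------------------------------------------------------------------


def classify_outcome(event, outdef: OutcomeDefinition) -> tuple[bool, str]:
    """Classify a diagnosis row or a death-registry row under one definition.

    Returns ``(is_event, kind)`` with kind in fatal / nonfatal /
    competing_death / none.  Death records (anything exposing
    ``cause_icd10``) match fatal ICD-10 prefixes; a death with a cause
    outside the fatal set is a competing (non-CVD) death.  Diagnosis rows
    match exact ICPC codes (ICD-10-coded diagnoses match the fatal prefix
    list, as the mapping carries non-fatal concepts in ICPC only).
    """
    get = event.get if hasattr(event, "get") else lambda k, d=None: getattr(event, k, d)
    cause = get("cause_icd10")
    if cause is not None and not pd.isna(cause):
        if str(cause)[:3] in outdef.fatal_codes:
            return True, "fatal"
        return False, "competing_death"
    system = get("code_system")
    code = str(get("code"))
    if system in _ICPC_SYSTEMS:
        if code in outdef.nonfatal_codes:
            return True, "nonfatal"
        return False, "none"
    if system == "ICD-10":
        if code[:3] in outdef.fatal_codes:
            return True, "nonfatal"
        return False, "none"
    raise ValueError(f"unknown code system {system!r}")


def _years(delta_days: float) -> float:
    return delta_days / DAYS_PER_YEAR


def build_followup(
    patient,
    diagnoses: pd.DataFrame,
    linked_death,
    outdef: OutcomeDefinition,
    baseline_date: pd.Timestamp = BASELINE_DATE,
    admin_end: pd.Timestamp = ADMIN_END,
    horizon: float = HORIZON_YEARS,
) -> FollowUpRecord:
    """Follow one patient from baseline to first event or earliest censoring.

    ``patient`` is a mapping/Series with patient_id and registration_end;
    ``linked_death`` is the linked registry row or None.  A qualifying event
    dated before baseline raises (it should have been excluded as prevalent);
    an event on the baseline date counts at half a day of follow-up.
    """
    get = patient.get if hasattr(patient, "get") else lambda k, d=None: getattr(patient, k, d)
    pid = get("patient_id")

    event_time = np.inf
    rows = diagnoses[diagnoses["patient_id"] == pid]
    for row in rows.itertuples(index=False):
        is_event, kind = classify_outcome(row, outdef)
        if is_event:
            if row.date < baseline_date:
                raise ValueError(
                    f"patient {pid}: qualifying event dated {row.date.date()} "
                    "precedes baseline (prevalent disease)"
                )
            event_time = min(event_time, _years((row.date - baseline_date).days))

    censors: list[tuple[float, str]] = [(horizon, "horizon_10y")]
    # the administrative end only censors when it falls inside the horizon
    # (calendar years, so 2009-01-01 + 10 y -> 2019-01-01 counts as horizon)
    if admin_end < baseline_date + pd.DateOffset(years=round(horizon)):
        censors.append((_years((admin_end - baseline_date).days), "admin_end"))
    reg_end = get("registration_end")
    if reg_end is not None and not pd.isna(reg_end):
        censors.append((_years((reg_end - baseline_date).days), "deregistered"))
    if linked_death is not None:
        dget = (
            linked_death.get
            if hasattr(linked_death, "get")
            else lambda k, d=None: getattr(linked_death, k, d)
        )
        is_ev, kind = classify_outcome(linked_death, outdef)
        dtime = _years((dget("death_date") - baseline_date).days)
        if is_ev:
            if dget("death_date") < baseline_date:
                raise ValueError(f"patient {pid}: fatal event precedes baseline")
            event_time = min(event_time, dtime)
        else:
            censors.append((dtime, "non_cvd_death"))

    censor_time, censor_reason = min(
        censors, key=lambda c: (c[0], _CENSOR_PRIORITY.index(c[1]))
    )
    if event_time <= censor_time:
        t = max(event_time, 0.5 / DAYS_PER_YEAR)  # same-day events: half a day
        return FollowUpRecord(pid, baseline_date, t, True, "none")
    t = max(censor_time, 0.5 / DAYS_PER_YEAR)
    return FollowUpRecord(pid, baseline_date, t, False, censor_reason)


def build_followups(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    linkage: LinkageResult,
    outdef: OutcomeDefinition,
    baseline_date: pd.Timestamp = BASELINE_DATE,
    admin_end: pd.Timestamp = ADMIN_END,
    horizon: float = HORIZON_YEARS,
) -> pd.DataFrame:
    """Vectorised follow-up for a cohort; one row per patient.

    Same rules as :func:`build_followup`; returns columns patient_id,
    time_years, event, censor_reason.
    """
    pids = patients["patient_id"].to_numpy()
    n = len(pids)
    pos = pd.Series(np.arange(n), index=pids)

    # first qualifying non-fatal diagnosis on/after baseline
    diag = diagnoses[diagnoses["patient_id"].isin(pos.index)]
    icpc = diag["code_system"].isin(_ICPC_SYSTEMS) & diag["code"].isin(outdef.nonfatal_codes)
    icd = (diag["code_system"] == "ICD-10") & diag["code"].str.slice(0, 3).isin(
        outdef.fatal_codes
    )
    qual = diag[icpc | icd]
    if (qual["date"] < baseline_date).any():
        bad = qual.loc[qual["date"] < baseline_date, "patient_id"].iloc[0]
        raise ValueError(f"patient {bad}: qualifying event precedes baseline")
    first = qual.groupby("patient_id")["date"].min()

    event_time = np.full(n, np.inf)
    idx = pos[first.index].to_numpy()
    event_time[idx] = (first.to_numpy() - baseline_date.to_numpy()).astype(
        "timedelta64[D]"
    ).astype(float) / DAYS_PER_YEAR

    # deaths: fatal CVD -> event; otherwise censoring
    death_time = np.full(n, np.inf)
    for pid, row in linkage.links.items():
        if pid not in pos.index:
            continue
        i = pos[pid]
        is_ev, _ = classify_outcome(row, outdef)
        t = _years((row.death_date - baseline_date).days)
        if is_ev:
            if t < 0:
                raise ValueError(f"patient {pid}: fatal event precedes baseline")
            event_time[i] = min(event_time[i], t)
        else:
            death_time[i] = t

    dereg = np.full(n, np.inf)
    has_end = patients["registration_end"].notna().to_numpy()
    dereg[has_end] = (
        patients.loc[has_end, "registration_end"].to_numpy() - baseline_date.to_numpy()
    ).astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR

    if admin_end < baseline_date + pd.DateOffset(years=round(horizon)):
        admin = _years((admin_end - baseline_date).days)
    else:
        admin = np.inf
    cens_stack = np.stack(
        [
            np.full(n, horizon),
            death_time,
            dereg,
            np.full(n, admin),
        ]
    )  # row order == _CENSOR_PRIORITY; argmin takes the first on ties
    which = cens_stack.argmin(axis=0)
    censor_time = cens_stack.min(axis=0)
    reasons = np.array(_CENSOR_PRIORITY)[which]

    is_event = event_time <= censor_time
    time = np.where(is_event, event_time, censor_time)
    time = np.maximum(time, 0.5 / DAYS_PER_YEAR)
    return pd.DataFrame(
        {
            "patient_id": pids,
            "time_years": time,
            "event": is_event,
            "censor_reason": np.where(is_event, "none", reasons),
        }
    )


def incidence_rate(followups: pd.DataFrame) -> float:
    """Events per 1000 patient-years of follow-up."""
    total_time = followups["time_years"].sum()
    if len(followups) == 0 or total_time <= 0:
        raise ValueError("incidence rate requires positive total person-time")
    return 1000.0 * followups["event"].sum() / total_time


# ---------------------------------------------------------------------------
# profiles and the per-model cohort
# ---------------------------------------------------------------------------


def build_profiles(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    baseline_date: pd.Timestamp = BASELINE_DATE,
    window=MEASUREMENT_WINDOW,
) -> pd.DataFrame:
    """Assemble baseline risk profiles (one row per patient).

    Columns: patient_id, age, sex, sbp, tc, hdl, ratio, bmi, smoker,
    diabetes, rheumatoid_arthritis.  Diabetes and rheumatoid arthritis come
    from diagnoses strictly before baseline.
    """
    vals = baseline_values(measurements, ["SBP", "TC", "HDL", "BMI"], window)
    vals = vals.rename(columns={"SBP": "sbp", "TC": "tc", "HDL": "hdl", "BMI": "bmi"})
    smoking = _smoking_status_frame(measurements, baseline_date)

    prior = diagnoses[diagnoses["date"] < baseline_date]
    dm_ids = set(
        prior.loc[
            (prior["code_system"].isin(_ICPC_SYSTEMS) & prior["code"].isin(_DM_ICPC))
            | (
                (prior["code_system"] == "ICD-10")
                & prior["code"].str.slice(0, 3).isin(_DM_ICD10)
            ),
            "patient_id",
        ]
    )
    ra_ids = set(
        prior.loc[
            (prior["code_system"].isin(_ICPC_SYSTEMS) & (prior["code"] == "L88"))
            | (
                (prior["code_system"] == "ICD-10")
                & prior["code"].str.slice(0, 3).isin({"M05", "M06"})
            ),
            "patient_id",
        ]
    )

    out = patients[["patient_id", "sex", "birth_date"]].copy()
    out["age"] = completed_age(out["birth_date"], baseline_date)
    out = out.drop(columns="birth_date").set_index("patient_id")
    out = out.join(vals).join(smoking)
    out["ratio"] = out["tc"] / out["hdl"]
    out["smoker"] = out["smoker"].astype("boolean").fillna(False).astype(float)
    out["diabetes"] = out.index.isin(dm_ids).astype(float)
    out["rheumatoid_arthritis"] = out.index.isin(ra_ids)
    return out.reset_index()


def build_cohort(
    tables: Mapping[str, pd.DataFrame],
    model_id: str,
    outcome_definitions: Mapping[str, OutcomeDefinition] | None = None,
    baseline_date: pd.Timestamp = BASELINE_DATE,
    admin_end: pd.Timestamp = ADMIN_END,
    horizon: float = HORIZON_YEARS,
) -> tuple[pd.DataFrame, dict]:
    """Full per-model cohort: selection, eligibility, linkage, follow-up.

    Returns ``(cohort, flowchart)`` where cohort has one row per included
    patient (profile + time_years/event/censor_reason) and flowchart records
    the patient counts at each stage.
    """
    spec = ELIGIBILITY[model_id]
    outdefs = outcome_definitions or load_outcome_definitions()
    outdef = outdefs[model_id]
    patients = tables["patients"]
    measurements = tables["measurements"]
    diagnoses = tables["diagnoses"]
    registry = tables["death_registry"]

    assessed = select_risk_assessed(patients, measurements, spec, baseline_date=baseline_date)
    measured = patients[patients["patient_id"].isin(assessed)]
    eligible = apply_eligibility(measured, diagnoses, spec, baseline_date)

    linkage = link_cause_of_death(eligible, registry)
    followups = build_followups(
        eligible, diagnoses, linkage, outdef, baseline_date, admin_end, horizon
    )
    profiles = build_profiles(eligible, measurements, diagnoses, baseline_date)
    cohort = profiles.merge(followups, on="patient_id")
    cohort.insert(1, "model_id", model_id)

    flowchart = {
        "initial": int(len(patients)),
        "risk_assessed": int(len(measured)),
        "eligible": int(len(eligible)),
        "final": int(len(cohort)),
        "linked": int(linkage.n_linked),
        "ambiguous_links": int(linkage.n_ambiguous),
        "events": int(cohort["event"].sum()),
    }
    return cohort, flowchart
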