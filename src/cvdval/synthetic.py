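"""Synthetic routine-care data with a known ground-truth event model.

Routine GP databases are not publicly deposited, so the pipeline is
exercised on simulated data whose statistical structure matches what the
analysis assumes: baseline risk-factor marginals resembling the published
cohort characteristics, one GP visit date per patient (so the
measurement-window selection stage has something to select on), a Weibull
proportional-hazards time-to-event model over the 10-year horizon with
administrative censoring at 2019-01-01, independent deregistration and
non-CVD-death censoring, and a cause-of-death registry keyed on
(sex, birth_date, postal4) with configurable planted duplicate and
unlinkable keys.

The true event model is Weibull PH — cumulative hazard
``H(t | x) = lam * t^shape * exp(lp(x))`` — so every patient's true 10-year
risk has the closed form ``1 - exp(-lam * 10^shape * exp(lp))``, giving
exact ground truth for calibration-recovery tests.

Everything is driven by one seed; identical configs give byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from cvdval.cohort import ADMIN_END, BASELINE_DATE, DAYS_PER_YEAR, MEASUREMENT_WINDOW

__all__ = [
    "TrueModel",
    "SimulationConfig",
    "generate_cohort",
    "generate_outcomes",
    "simulate_tables",
    "simulate_pairs",
    "miscalibrate",
    "true_risk",
    "true_survival",
]


@dataclass(frozen=True)
class TrueModel:
    """Weibull proportional-hazards generator of CVD event times.

    ``lam`` and ``shape`` give the baseline cumulative hazard
    ``lam * t^shape`` (time in years); the linear predictor centres each
    covariate near its population mean so the baseline corresponds to a
    typical patient.
    """

    lam: float = 0.0066
    shape: float = 1.1
    beta_age: float = 0.07
    beta_sbp: float = 0.012
    beta_smoker: float = 0.55
    beta_tc: float = 0.12
    beta_diabetes: float = 0.65
    beta_male: float = 0.45
    c_age: float = 58.0
    c_sbp: float = 141.0
    c_tc: float = 5.4

    def linear_predictor(self, profiles: pd.DataFrame) -> np.ndarray:
        return (
            self.beta_age * (profiles["age"].to_numpy(dtype=float) - self.c_age)
            + self.beta_sbp * (profiles["sbp"].to_numpy(dtype=float) - self.c_sbp)
            + self.beta_smoker * profiles["smoker"].to_numpy(dtype=float)
            + self.beta_tc * (profiles["tc"].to_numpy(dtype=float) - self.c_tc)
            + self.beta_diabetes * profiles["diabetes"].to_numpy(dtype=float)
            + self.beta_male * (profiles["sex"].to_numpy() == "male")
        )


def true_survival(model: TrueModel, lp: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Closed-form survival of the generating model, S(t | lp)."""
    return np.exp(-model.lam * np.asarray(t, dtype=float) ** model.shape * np.exp(lp))


def true_risk(model: TrueModel, lp: np.ndarray, horizon: float = 10.0) -> np.ndarray:
    return 1.0 - true_survival(model, lp, horizon)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Risk-factor defaults mirror the published baseline characteristics of a
    GP population selected for risk assessment (age around 58 +/- 8, SBP
    141 +/- 16 mmHg, TC 5.4 +/- 1.2 mmol/L, TC/HDL ratio 4.6 +/- 1.1, BMI
    29 +/- 5, smoking ~14%, diabetes ~29%); presets for the three study
    cohorts are available through :meth:`table1`.  Annual deregistration and
    non-CVD-death hazards default to values giving a mean follow-up of
    roughly 8.5-9 years; 3% of events are fatal.
    """

    n: int = 10_000
    seed: int = 0
    female_frac: float = 0.55
    age_range: tuple[float, float] = (40.0, 75.0)  # completed ages 40-74
    age_mean: float = 58.9
    age_sd: float = 8.6
    sbp_mean: float = 141.0
    sbp_sd: float = 16.0
    tc_mean: float = 5.4
    tc_sd: float = 1.2
    ratio_mean: float = 4.6
    ratio_sd: float = 1.1
    bmi_mean: float = 29.1
    bmi_sd: float = 5.1
    sbp_bmi_corr: float = 0.3
    smoking_prev: float = 0.14
    diabetes_prev: float = 0.291
    ra_prev: float = 0.013
    true_model: TrueModel = field(default_factory=TrueModel)
    fatal_fraction: float = 0.03
    dereg_rate: float = 0.03  # annual hazard
    noncvd_death_rate: float = 0.002  # annual hazard
    in_window_fraction: float | None = 0.8  # None = visit dates uniform over range
    visit_date_range: tuple[str, str] = ("2008-01-01", "2011-01-01")
    extra_visit_fraction: float = 0.2  # second, earlier measurement of SBP
    prior_cvd_rate: float = 0.04  # fraction with a CVD history diagnosis before baseline
    duplicate_key_rate: float = 0.0
    unlinkable_rate: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("age_sd", "sbp_sd", "tc_sd", "ratio_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "female_frac",
            "smoking_prev",
            "diabetes_prev",
            "ra_prev",
            "prior_cvd_rate",
            "fatal_fraction",
            "duplicate_key_rate",
            "unlinkable_rate",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("infeasible age truncation bounds")

    @classmethod
    def table1(cls, cohort: str, **overrides) -> "SimulationConfig":
        """Presets mirroring the baseline table of each study cohort."""
        presets = {
            "score": dict(
                age_range=(40.0, 71.0),
                age_mean=57.4,
                age_sd=7.7,
                sbp_mean=142.0,
                sbp_sd=14.0,
                ratio_mean=4.6,
                ratio_sd=1.1,
                smoking_prev=0.121,
                diabetes_prev=0.0,
                female_frac=0.518,
            ),
            "globo_lab": dict(
                age_range=(40.0, 75.0),
                age_mean=58.9,
                age_sd=8.6,
                sbp_mean=141.0,
                sbp_sd=17.0,
                tc_mean=5.4,
                tc_sd=1.2,
                smoking_prev=0.14,
                diabetes_prev=0.291,
                female_frac=0.562,
            ),
            "globo_office": dict(
                age_range=(40.0, 75.0),
                age_mean=59.7,
                age_sd=8.6,
                sbp_mean=140.0,
                sbp_sd=16.0,
                bmi_mean=29.1,
                bmi_sd=5.1,
                smoking_prev=0.159,
                female_frac=0.548,
            ),
        }
        if cohort not in presets:
            raise ValueError(f"unknown cohort preset {cohort!r}")
        return cls(**{**presets[cohort], **overrides})

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tm = raw.pop("true_model", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if tm:
            cfg = replace(cfg, true_model=TrueModel(**tm))
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["age_range"] = list(raw["age_range"])
        raw["visit_date_range"] = list(raw["visit_date_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated normal by rejection (bounds are many SDs out in practice)."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out >= hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise ValueError(f"infeasible truncation bounds ({lo}, {hi}) for N({mean}, {sd})")


def generate_cohort(config: SimulationConfig):
    """Draw the baseline population: (patients, measurements, profiles).

    ``profiles`` carries the latent true covariate values (the measurement
    table is the observed, dated view of the same quantities).  Each patient
    has one GP visit at which all predictors are recorded; a configurable
    fraction gets an additional earlier SBP measurement so the
    most-recent-wins rule is exercised.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    pid = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_frac, "female", "male")
    age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_range, n)

    # SBP and BMI share a configurable correlation; other factors independent
    z = rng.standard_normal((n, 2))
    z2 = config.sbp_bmi_corr * z[:, 0] + np.sqrt(1 - config.sbp_bmi_corr**2) * z[:, 1]
    sbp = np.clip(config.sbp_mean + config.sbp_sd * z[:, 0], 51.0, 299.0)
    bmi = np.clip(config.bmi_mean + config.bmi_sd * z2, 11.0, 79.0)
    tc = _truncnorm(rng, config.tc_mean, config.tc_sd, 1.1, 19.9, n)
    ratio = _truncnorm(rng, config.ratio_mean, config.ratio_sd, 1.2, 15.0, n)
    hdl = np.clip(tc / ratio, 0.31, 4.99)
    smoker = rng.random(n) < config.smoking_prev
    diabetes = rng.random(n) < config.diabetes_prev
    ra = rng.random(n) < config.ra_prev

    birth = BASELINE_DATE - pd.to_timedelta(np.floor(age * DAYS_PER_YEAR) + 1, unit="D")
    postal4 = np.char.mod("%04d", rng.integers(1000, 10000, n))
    reg_start = pd.Timestamp("2000-01-01") + pd.to_timedelta(
        rng.integers(0, 2500, n), unit="D"
    )
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "birth_date": birth,
            "postal4": postal4,
            "registration_start": reg_start,
            "registration_end": pd.NaT,
        }
    )

    lo = pd.Timestamp(config.visit_date_range[0])
    hi = pd.Timestamp(config.visit_date_range[1])
    if config.in_window_fraction is None:
        offs = rng.integers(0, (hi - lo).days, n)
        visit = lo + pd.to_timedelta(offs, unit="D")
    else:
        w0, w1 = MEASUREMENT_WINDOW
        in_win = rng.random(n) < config.in_window_fraction
        offs_win = rng.integers(0, (w1 - w0).days, n)
        offs_out = rng.integers(0, (hi - lo).days, n)
        visit = pd.Series(lo + pd.to_timedelta(offs_out, unit="D"))
        visit[in_win] = (w0 + pd.to_timedelta(offs_win, unit="D"))[in_win]
        visit = pd.DatetimeIndex(visit)

    smoking_value = np.where(
        smoker, "current", np.where(rng.random(n) < 0.4, "former", "never")
    )
    frames = []
    for code, values in [
        ("SBP", np.round(sbp, 0)),
        ("TC", np.round(tc, 2)),
        ("HDL", np.round(hdl, 2)),
        ("BMI", np.round(bmi, 1)),
        ("smoking", smoking_value),
    ]:
        frames.append(
            pd.DataFrame(
                {"patient_id": pid, "code": code, "value": values, "date": visit}
            )
        )
    # an older, superseded SBP reading for a fraction of patients
    extra = rng.random(n) < config.extra_visit_fraction
    if extra.any():
        old_date = visit[extra] - pd.to_timedelta(
            rng.integers(30, 150, int(extra.sum())), unit="D"
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[extra],
                    "code": "SBP",
                    "value": np.round(sbp[extra] + rng.normal(0, 5, int(extra.sum())), 0),
                    "date": old_date,
                }
            )
        )
    measurements = pd.concat(frames, ignore_index=True)

    profiles = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "age": age,
            "sbp": sbp,
            "tc": tc,
            "hdl": hdl,
            "ratio": tc / hdl,
            "bmi": bmi,
            "smoker": smoker.astype(float),
            "diabetes": diabetes.astype(float),
            "rheumatoid_arthritis": ra,
        }
    )
    return patients, measurements, profiles


_FATAL_CODES = np.array(["I21", "I63", "I71"])
_FATAL_P = np.array([0.5, 0.35, 0.15])
# non-fatal mix: MI and stroke dominate; heart failure and peripheral
# vascular disease are captured by the broader fatal+non-fatal definition only
_NONFATAL_CODES = np.array(["K75", "K90", "K77", "K92"])
_NONFATAL_P = np.array([0.35, 0.30, 0.25, 0.10])
_NONCVD_CAUSES = np.array(["C80", "J44", "A41"])
_HISTORY_CVD_CODES = np.array(["K74", "K75", "K76", "K77", "K89", "K90", "K92"])


def generate_outcomes(patients: pd.DataFrame, profiles: pd.DataFrame, config: SimulationConfig):
    """Realise event times, censoring, diagnosis rows and the death registry.

    Event times come from the Weibull PH truth by inverse-transform
    sampling; deregistration and non-CVD death are independent exponential
    censorings; everything is truncated administratively at 2019-01-01.
    Returns ``(patients, diagnoses, death_registry, truth)`` where patients
    has registration_end filled for deregistered subjects.

    The registry carries the (sex, birth_date, postal4) linkage key; at the
    configured rates, registry rows are duplicated (ambiguous keys) or get a
    perturbed postal code (unlinkable).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(profiles)
    model = config.true_model
    lp = model.linear_predictor(profiles)
    u = rng.random(n)
    t_event = (-np.log(u) / (model.lam * np.exp(lp))) ** (1.0 / model.shape)
    t_dereg = (
        rng.exponential(1.0 / config.dereg_rate, n) if config.dereg_rate > 0 else np.full(n, np.inf)
    )
    t_ncd = (
        rng.exponential(1.0 / config.noncvd_death_rate, n)
        if config.noncvd_death_rate > 0
        else np.full(n, np.inf)
    )
    t_admin = (ADMIN_END - BASELINE_DATE).days / DAYS_PER_YEAR

    t_censor = np.minimum(np.minimum(t_dereg, t_ncd), t_admin)
    has_event = t_event <= t_censor
    fatal = has_event & (rng.random(n) < config.fatal_fraction)

    days = np.floor(t_event * DAYS_PER_YEAR).astype(int)
    pid = profiles["patient_id"].to_numpy()
    sex = profiles["sex"].to_numpy()

    # pre-baseline history: diabetes (T90) and rheumatoid arthritis (L88)
    # diagnoses for the latently affected, plus a fraction with prior CVD —
    # these drive eligibility exclusions and the diagnosis-derived profile flags
    hist_frames = []
    for mask, codes in [
        (profiles["diabetes"].to_numpy() > 0, np.array(["T90"])),
        (profiles["rheumatoid_arthritis"].to_numpy().astype(bool), np.array(["L88"])),
        (rng.random(n) < config.prior_cvd_rate, _HISTORY_CVD_CODES),
    ]:
        m = int(mask.sum())
        if m == 0:
            continue
        hist_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[mask],
                    "code_system": "ICPC-2",
                    "code": rng.choice(codes, m),
                    "date": pd.Timestamp("1995-01-01")
                    + pd.to_timedelta(rng.integers(0, 4700, m), unit="D"),
                }
            )
        )

    nonfatal = has_event & ~fatal
    event_diagnoses = pd.DataFrame(
        {
            "patient_id": pid[nonfatal],
            "code_system": "ICPC-2",
            "code": rng.choice(_NONFATAL_CODES, int(nonfatal.sum()), p=_NONFATAL_P),
            "date": BASELINE_DATE + pd.to_timedelta(days[nonfatal], unit="D"),
        }
    )
    diagnoses = pd.concat([*hist_frames, event_diagnoses], ignore_index=True)

    # deaths: fatal CVD events plus non-CVD deaths that occur first
    ncd = ~has_event & (t_ncd <= np.minimum(t_dereg, t_admin))
    patients = patients.copy()
    dereg = ~has_event & ~ncd & (t_dereg < t_admin)
    patients.loc[dereg, "registration_end"] = BASELINE_DATE + pd.to_timedelta(
        np.floor(t_dereg[dereg] * DAYS_PER_YEAR).astype(int), unit="D"
    )

    reg_rows = []
    for mask, causes, pvals, times in [
        (fatal, _FATAL_CODES, _FATAL_P, t_event),
        (ncd, _NONCVD_CAUSES, np.array([0.6, 0.25, 0.15]), t_ncd),
    ]:
        if not mask.any():
            continue
        m = int(mask.sum())
        reg_rows.append(
            pd.DataFrame(
                {
                    "sex": sex[mask],
                    "birth_date": patients.loc[mask, "birth_date"].to_numpy(),
                    "postal4": patients.loc[mask, "postal4"].to_numpy(),
                    "death_date": BASELINE_DATE
                    + pd.to_timedelta(np.floor(times[mask] * DAYS_PER_YEAR).astype(int), unit="D"),
                    "cause_icd10": rng.choice(causes, m, p=pvals),
                    "_patient_id": pid[mask],
                }
            )
        )
    registry = (
        pd.concat(reg_rows, ignore_index=True)
        if reg_rows
        else pd.DataFrame(
            columns=["sex", "birth_date", "postal4", "death_date", "cause_icd10", "_patient_id"]
        )
    )

    # linkage noise
    if len(registry) and config.unlinkable_rate > 0:
        bad = rng.random(len(registry)) < config.unlinkable_rate
        registry.loc[bad, "postal4"] = "0000"
    if len(registry) and config.duplicate_key_rate > 0:
        dup = registry[rng.random(len(registry)) < config.duplicate_key_rate].copy()
        dup["cause_icd10"] = "R99"
        registry = pd.concat([registry, dup], ignore_index=True)
    registry = registry.drop(columns="_patient_id")

    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "true_lp": lp,
            "true_risk10": true_risk(model, lp),
            "true_event_time": np.where(has_event, t_event, np.nan),
        }
    )
    return patients, diagnoses, registry, truth


def simulate_tables(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """End-to-end simulation of the four input tables plus ground truth."""
    patients, measurements, profiles = generate_cohort(config)
    patients, diagnoses, registry, truth = generate_outcomes(patients, profiles, config)
    return {
        "patients": patients,
        "measurements": measurements,
        "diagnoses": diagnoses,
        "death_registry": registry,
        "truth": truth,
        "profiles": profiles,
    }


def simulate_pairs(
    n: int,
    seed: int,
    config: SimulationConfig | None = None,
    censoring: bool = True,
    horizon: float = 10.0,
) -> pd.DataFrame:
    """Prediction-outcome pairs straight from the ground truth.

    Scores each simulated subject with their *true* 10-year risk, so the
    resulting pairs are perfectly calibrated by construction — the reference
    input for calibration-recovery and discrimination tests.  Columns:
    risk10, time_years, event, true_risk10.
    """
    config = replace(config or SimulationConfig(), n=n, seed=seed)
    if not censoring:
        config = replace(config, dereg_rate=0.0, noncvd_death_rate=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    _, _, profiles = generate_cohort(config)
    model = config.true_model
    lp = model.linear_predictor(profiles)
    t_event = (-np.log(rng.random(n)) / (model.lam * np.exp(lp))) ** (1.0 / model.shape)
    t_cens = np.full(n, horizon)
    if config.dereg_rate > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / config.dereg_rate, n))
    if config.noncvd_death_rate > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / config.noncvd_death_rate, n))
    event = t_event <= t_cens
    time = np.where(event, t_event, t_cens)
    r = true_risk(model, lp, horizon)
    return pd.DataFrame(
        {
            "risk10": r,
            "time_years": np.maximum(time, 1e-4),
            "event": event,
            "true_risk10": r,
        }
    )


def miscalibrate(predictions, factor: float):
    """Scale predicted risks by ``factor``, clipping at 1 (miscalibration probe)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if isinstance(predictions, pd.DataFrame):
        out = predictions.copy()
        out["risk10"] = np.minimum(1.0, out["risk10"] * factor)
        return out
    return np.minimum(1.0, np.asarray(predictions, dtype=float) * factor)
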