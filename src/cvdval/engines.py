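"""Risk engines: 10-year CVD risk under SCORE, SCORE-FNF and Globorisk.

All model parameters live in human-readable, versioned data files under
``cvdval/data`` (JSON for SCORE and the fatal-to-total multipliers, CSV for
the Globorisk per-age recalibration tables); nothing numeric is hard-coded
here.  Each loader validates its file against the expected schema before any
risk is computed, so a corrupted or hand-edited file fails loudly at load
time rather than silently shifting predictions.

Model forms
-----------
SCORE estimates the 10-year risk of *fatal* atherosclerotic CVD as the sum of
two cause-specific Weibull relative-risk models (coronary heart disease and
non-coronary CVD).  For one cause, baseline survival to age ``a`` is

    S0(a) = exp(-exp(alpha) * (a - 20)^p)

and the conditional 10-year risk for a patient with linear predictor
``w = b_ratio*(ratio - c_ratio) + b_sbp*(sbp - c_sbp) + b_smoker*smoker`` is

    risk = 1 - (S0(a + 10) / S0(a))^exp(w).

The two cause-specific risks are summed, optionally multiplied by a
rheumatoid-arthritis factor, and clipped to [0, 1].

SCORE-FNF multiplies the SCORE fatal risk by an age- and sex-specific
multiplier (derived from the Dutch EPIC-NL cohort in the source guideline) to
approximate fatal-plus-non-fatal risk, clipping at 1.

Globorisk (laboratory and office variants) computes 10-year fatal plus
non-fatal CVD risk by a recursion over ten one-year intervals.  At attained
age ``a_t = age + t`` the linear predictor centres each risk factor on the
national age/sex-specific mean level m_j(a_t, sex), with age-interaction
terms on the coefficients, and the annual survival uses the nationally
recalibrated baseline hazard lambda0(a_t, sex):

    s_t = exp(-lambda0(a_t, sex) * exp(LP_t)),   risk10 = 1 - prod_t s_t.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODELS",
    "RiskProfile",
    "RiskPrediction",
    "ScoreCauseParams",
    "ScoreCoefficients",
    "FnfMultiplierTable",
    "GloboriskCoefficients",
    "CoefficientSchemaError",
    "load_score_coefficients",
    "load_fnf_multipliers",
    "load_globorisk_coefficients",
    "score_fatal_risk",
    "score_fnf_risk",
    "globorisk_risk",
    "recalibrate_baseline",
    "predict_batch",
]

MODELS = ("SCORE", "SCORE_FNF", "GLOBO_LAB", "GLOBO_OFFICE")

SEXES = ("male", "female")
_CAUSES = ("chd", "non_chd")

#: risk factors entering each Globorisk variant, in file column order
GLOBORISK_VARIABLES = {
    "lab": ("sbp", "tc", "smoker", "diabetes"),
    "office": ("sbp", "bmi", "smoker"),
}


class CoefficientSchemaError(ValueError):
    """A coefficient file does not conform to its documented schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskProfile:
    """One patient's predictor values at baseline.

    ``smoker``, ``diabetes`` and ``rheumatoid_arthritis`` accept floats so
    that population mean levels (prevalences) can be scored, e.g. during
    recalibration.
    """

    age: float
    sex: str
    sbp: float
    smoker: float
    ratio: float | None = None  # total cholesterol / HDL cholesterol
    tc: float | None = None  # total cholesterol, mmol/L
    diabetes: float | None = None
    bmi: float | None = None  # kg/m^2
    rheumatoid_arthritis: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class RiskPrediction:
    model_id: str
    risk10: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk10 <= 1.0:
            raise ValueError(f"risk10 outside [0, 1]: {self.risk10}")


@dataclass(frozen=True)
class ScoreCauseParams:
    """Weibull baseline and log-hazard coefficients for one (sex, cause)."""

    p: float
    alpha: float
    beta_ratio: float
    beta_sbp: float
    beta_smoker: float


@dataclass(frozen=True)
class ScoreCoefficients:
    version: str
    source: str
    params: Mapping[tuple[str, str], ScoreCauseParams]
    c_ratio: float  # centering constant, TC/HDL ratio
    c_sbp: float  # centering constant, mmHg
    ra_multiplier: float = 1.0


@dataclass(frozen=True)
class FnfMultiplierTable:
    """Age-band and sex specific fatal-to-total multipliers.

    Bands are inclusive on both ends and must partition 40-70 per sex.
    """

    version: str
    source: str
    rows: tuple[tuple[str, int, int, float], ...]  # (sex, lo, hi, multiplier)

    def multiplier(self, sex: str, age: float) -> float:
        a = math.floor(age)  # bands are in completed years
        for row_sex, lo, hi, mult in self.rows:
            if row_sex == sex and lo <= a <= hi:
                return mult
        raise ValueError(f"no multiplier band covers sex={sex!r}, age={age}")


@dataclass(frozen=True)
class GloboriskCoefficients:
    """Log-hazard coefficients plus the national recalibration table.

    ``betas[var] = (main, age_interaction)``: the effect at attained age *a*
    is ``main + age_interaction * (a - age_center)``.  ``table`` is indexed by
    (sex, age) and carries the recalibrated baseline annual hazard
    ``lambda0``, the national mean level ``mean_<var>`` for every variable of
    the variant, and (for the ages used to anchor the recalibration) the
    national target 10-year risk ``target_risk10``.
    """

    variant: str
    version: str
    source: str
    age_center: float
    betas: Mapping[str, tuple[float, float]]
    table: pd.DataFrame = field(repr=False)

    @property
    def variables(self) -> tuple[str, ...]:
        return GLOBORISK_VARIABLES[self.variant]

    def beta_at(self, var: str, age: float | np.ndarray) -> float | np.ndarray:
        main, inter = self.betas[var]
        return main + inter * (np.asarray(age, dtype=float) - self.age_center)

    def _dense(self, column: str) -> dict[str, np.ndarray]:
        """Per-sex dense array of ``column`` over the covered age range."""
        out = {}
        for sex in SEXES:
            sub = self.table.xs(sex, level="sex").sort_index()
            ages = sub.index.to_numpy()
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise CoefficientSchemaError(
                    f"{self.variant}: ages for {sex} not contiguous"
                )
            out[sex] = sub[column].to_numpy(dtype=float)
        return out

    @property
    def age_range(self) -> tuple[int, int]:
        ages = self.table.index.get_level_values("age")
        return int(ages.min()), int(ages.max())


# ---------------------------------------------------------------------------
# loaders and schema validation
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("cvdval").joinpath("data", name)


def load_score_coefficients(path=None) -> ScoreCoefficients:
    """Load and validate the SCORE coefficient file (JSON)."""
    src = _data_path("score_low_risk.json") if path is None else path
    with open(str(src)) as fh:
        raw = json.load(fh)
    try:
        params = {}
        for sex in SEXES:
            for cause in _CAUSES:
                cell = raw["params"][sex][cause]
                params[(sex, cause)] = ScoreCauseParams(
                    p=float(cell["p"]),
                    alpha=float(cell["alpha"]),
                    beta_ratio=float(cell["beta_ratio"]),
                    beta_sbp=float(cell["beta_sbp"]),
                    beta_smoker=float(cell["beta_smoker"]),
                )
        coeffs = ScoreCoefficients(
            version=str(raw["version"]),
            source=str(raw["source"]),
            params=params,
            c_ratio=float(raw["centering"]["ratio"]),
            c_sbp=float(raw["centering"]["sbp"]),
            ra_multiplier=float(raw.get("ra_multiplier", 1.0)),
        )
    except (KeyError, TypeError) as exc:
        raise CoefficientSchemaError(f"malformed SCORE coefficient file: {exc}")
    for key, cell in coeffs.params.items():
        if cell.p <= 0:
            raise CoefficientSchemaError(f"Weibull shape p must be > 0 for {key}")
    if not (1.0 <= coeffs.c_ratio <= 20.0 and 50.0 <= coeffs.c_sbp <= 300.0):
        raise CoefficientSchemaError("centering constants outside physiologic range")
    if coeffs.ra_multiplier < 1.0:
        raise CoefficientSchemaError("ra_multiplier must be >= 1")
    return coeffs


def load_fnf_multipliers(path=None) -> FnfMultiplierTable:
    """Load and validate the SCORE-FNF multiplier table (JSON)."""
    src = _data_path("fnf_multipliers.json") if path is None else path
    with open(str(src)) as fh:
        raw = json.load(fh)
    try:
        rows = tuple(
            (str(r["sex"]), int(r["age_lo"]), int(r["age_hi"]), float(r["multiplier"]))
            for r in raw["bands"]
        )
        table = FnfMultiplierTable(
            version=str(raw["version"]), source=str(raw["source"]), rows=rows
        )
    except (KeyError, TypeError) as exc:
        raise CoefficientSchemaError(f"malformed FNF multiplier file: {exc}")
    for sex in SEXES:
        bands = sorted((lo, hi) for s, lo, hi, _ in rows if s == sex)
        if not bands or bands[0][0] != 40 or bands[-1][1] != 70:
            raise CoefficientSchemaError(f"{sex}: bands must span ages 40-70")
        for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
            if lo2 != hi1 + 1:
                raise CoefficientSchemaError(f"{sex}: bands overlap or leave a gap")
    if any(m < 1.0 for *_, m in rows):
        raise CoefficientSchemaError("multipliers must be >= 1")
    return table


def load_globorisk_coefficients(variant: str, betas_path=None, table_path=None) -> GloboriskCoefficients:
    """Load and validate one Globorisk variant ('lab' or 'office')."""
    if variant not in GLOBORISK_VARIABLES:
        raise ValueError(f"variant must be 'lab' or 'office', got {variant!r}")
    bsrc = _data_path("globorisk_betas.json") if betas_path is None else betas_path
    tsrc = _data_path(f"globorisk_{variant}_table.csv") if table_path is None else table_path
    with open(str(bsrc)) as fh:
        raw = json.load(fh)
    try:
        block = raw[variant]
        betas = {
            var: (float(b["main"]), float(b["age_interaction"]))
            for var, b in block["betas"].items()
        }
        coeffs = GloboriskCoefficients(
            variant=variant,
            version=str(raw["version"]),
            source=str(raw["source"]),
            age_center=float(block["age_center"]),
            betas=betas,
            table=_read_globorisk_table(tsrc, GLOBORISK_VARIABLES[variant]),
        )
    except (KeyError, TypeError) as exc:
        raise CoefficientSchemaError(f"malformed Globorisk coefficient file: {exc}")
    if set(coeffs.betas) != set(coeffs.variables):
        raise CoefficientSchemaError(
            f"{variant}: betas {set(coeffs.betas)} != required {set(coeffs.variables)}"
        )
    lo, hi = coeffs.age_range
    if lo > 40 or hi < 84:
        raise CoefficientSchemaError(
            f"{variant}: recalibration table must cover ages 40-84, has {lo}-{hi}"
        )
    return coeffs


def _read_globorisk_table(path, variables: Sequence[str]) -> pd.DataFrame:
    table = pd.read_csv(str(path))
    need = {"sex", "age", "lambda0"} | {f"mean_{v}" for v in variables}
    missing = need - set(table.columns)
    if missing:
        raise CoefficientSchemaError(f"Globorisk table missing columns {missing}")
    if (table["lambda0"] < 0).any():
        raise CoefficientSchemaError("lambda0 must be nonnegative")
    table = table.set_index(["sex", "age"]).sort_index()
    if table.index.duplicated().any():
        raise CoefficientSchemaError("duplicate (sex, age) rows in Globorisk table")
    return table


# ---------------------------------------------------------------------------
# SCORE
# ---------------------------------------------------------------------------


def _score_fatal_array(
    age: np.ndarray,
    sex: np.ndarray,
    ratio: np.ndarray,
    sbp: np.ndarray,
    smoker: np.ndarray,
    ra: np.ndarray,
    coeffs: ScoreCoefficients,
) -> np.ndarray:
    if np.any(np.isnan(ratio)) or np.any(np.isnan(sbp)) or np.any(np.isnan(smoker)):
        raise ValueError("SCORE requires ratio, sbp and smoker for every profile")
    if np.any((age < 40) | (age > 70)):
        raise ValueError("SCORE is defined for ages 40-70 only")
    total = np.zeros_like(age, dtype=float)
    for s in SEXES:
        mask = sex == s
        if not mask.any():
            continue
        for cause in _CAUSES:
            cp = coeffs.params[(s, cause)]
            a = age[mask]
            # conditional baseline 10-year survival, in log space for accuracy
            log_s_ratio = -math.exp(cp.alpha) * (
                (a - 20.0 + 10.0) ** cp.p - (a - 20.0) ** cp.p
            )
            w = (
                cp.beta_ratio * (ratio[mask] - coeffs.c_ratio)
                + cp.beta_sbp * (sbp[mask] - coeffs.c_sbp)
                + cp.beta_smoker * smoker[mask]
            )
            total[mask] += 1.0 - np.exp(log_s_ratio * np.exp(w))
    total = np.where(ra.astype(bool), total * coeffs.ra_multiplier, total)
    return np.clip(total, 0.0, 1.0)


def score_fatal_risk(profile: RiskProfile, coeffs: ScoreCoefficients) -> RiskPrediction:
    """10-year fatal CVD risk under SCORE for one patient."""
    if profile.ratio is None:
        raise ValueError("SCORE requires the TC/HDL ratio")
    risk = _score_fatal_array(
        np.array([float(profile.age)]),
        np.array([profile.sex]),
        np.array([float(profile.ratio)]),
        np.array([float(profile.sbp)]),
        np.array([float(profile.smoker)]),
        np.array([bool(profile.rheumatoid_arthritis)]),
        coeffs,
    )[0]
    return RiskPrediction("SCORE", float(risk))


def score_fnf_risk(
    profile: RiskProfile,
    coeffs: ScoreCoefficients,
    multipliers: FnfMultiplierTable,
) -> RiskPrediction:
    """10-year fatal plus non-fatal CVD risk: SCORE times the EPIC-NL-style multiplier."""
    fatal = score_fatal_risk(profile, coeffs).risk10
    mult = multipliers.multiplier(profile.sex, profile.age)
    return RiskPrediction("SCORE_FNF", min(1.0, fatal * mult))


# ---------------------------------------------------------------------------
# Globorisk
# ---------------------------------------------------------------------------


def _globorisk_array(
    age: np.ndarray,
    sex: np.ndarray,
    values: Mapping[str, np.ndarray],
    coeffs: GloboriskCoefficients,
    check_age: bool = True,
) -> np.ndarray:
    for var in coeffs.variables:
        if np.any(np.isnan(values[var])):
            raise ValueError(f"Globorisk-{coeffs.variant} requires {var} for every profile")
    if check_age and np.any((age < 40) | (age > 74)):
        raise ValueError("Globorisk is defined for baseline ages 40-74")
    lo, hi = coeffs.age_range
    if np.any(age + 9 > hi) or np.any(age < lo):
        raise ValueError("recalibration table does not cover all attained ages")
    lam = coeffs._dense("lambda0")
    means = {v: coeffs._dense(f"mean_{v}") for v in coeffs.variables}
    cumhaz = np.zeros_like(age, dtype=float)
    age_idx = np.round(age).astype(int) - lo
    for s in SEXES:
        mask = sex == s
        if not mask.any():
            continue
        idx = age_idx[mask]
        a0 = age[mask]
        ch = np.zeros(mask.sum())
        for t in range(10):
            a_t = a0 + t
            lp = np.zeros_like(ch)
            for var in coeffs.variables:
                lp += coeffs.beta_at(var, a_t) * (
                    values[var][mask] - means[var][s][idx + t]
                )
            ch += lam[s][idx + t] * np.exp(lp)
        cumhaz[mask] = ch
    return np.clip(1.0 - np.exp(-cumhaz), 0.0, 1.0)


def globorisk_risk(
    profile: RiskProfile, coeffs: GloboriskCoefficients, variant: str | None = None
) -> RiskPrediction:
    """10-year CVD risk under Globorisk by the annual recalibrated recursion."""
    if variant is not None and variant != coeffs.variant:
        raise ValueError(
            f"requested variant {variant!r} but coefficients are {coeffs.variant!r}"
        )
    values = {}
    for var in coeffs.variables:
        v = getattr(profile, var)
        values[var] = np.array([np.nan if v is None else float(v)])
    risk = _globorisk_array(
        np.array([float(profile.age)]),
        np.array([profile.sex]),
        values,
        coeffs,
    )[0]
    return RiskPrediction(f"GLOBO_{coeffs.variant.upper()}", float(risk))


def recalibrate_baseline(
    coeffs: GloboriskCoefficients,
    targets: pd.Series | None = None,
    population_means: pd.DataFrame | None = None,
) -> GloboriskCoefficients:
    """Solve the baseline annual hazards lambda0(age, sex) from national targets.

    For every (baseline age, sex) cell with a target 10-year risk, the
    recalibrated model must assign exactly that risk to a profile sitting at
    the national mean risk-factor levels of that baseline age.  Because the
    baseline hazard enters the log-survival linearly, each cell reduces to a
    linear equation once earlier ages are solved: proceeding from the
    youngest target age (whose ten attained-age hazards are taken constant),
    every subsequent age contributes exactly one new attained-age hazard,
    solved in closed form.  Hazards above the oldest attained age covered by
    a target keep their prior value.

    Parameters
    ----------
    targets
        Series indexed by (sex, age) with 10-year risks in [0, 1).  Defaults
        to the ``target_risk10`` column of the coefficient table.
    population_means
        Optional replacement for the ``mean_<var>`` columns (same index).

    Returns
    -------
    A new :class:`GloboriskCoefficients` whose table has the solved
    ``lambda0`` (and the targets recorded in ``target_risk10``).
    """
    table = coeffs.table.copy()
    if population_means is not None:
        for var in coeffs.variables:
            table[f"mean_{var}"] = population_means[f"mean_{var}"]
    if targets is None:
        if "target_risk10" not in table.columns:
            raise ValueError("no targets supplied and table has no target_risk10")
        targets = table["target_risk10"].dropna()
    targets = targets.dropna().sort_index()
    if ((targets < 0) | (targets >= 1)).any():
        raise ValueError("target 10-year risks must lie in [0, 1)")

    lo, hi = coeffs.age_range
    for sex in SEXES:
        if sex not in targets.index.get_level_values("sex"):
            continue
        tgt = targets.xs(sex, level="sex")
        ages = tgt.index.to_numpy(dtype=int)
        if len(ages) == 0:
            continue
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise ValueError(f"{sex}: target ages must be contiguous")
        if ages[-1] + 9 > hi:
            raise ValueError(f"{sex}: targets need lambda0 beyond table age {hi}")
        lam = table.xs(sex, level="sex")["lambda0"].sort_index().to_numpy(dtype=float)
        mean_cols = {
            v: table.xs(sex, level="sex")[f"mean_{v}"].sort_index().to_numpy(dtype=float)
            for v in coeffs.variables
        }
        for k, a0 in enumerate(ages):
            # relative hazard of the mean-level age-a0 profile in year t
            rel = np.empty(10)
            for t in range(10):
                a_t = float(a0 + t)
                lp = 0.0
                for var in coeffs.variables:
                    lp += float(coeffs.beta_at(var, a_t)) * (
                        mean_cols[var][a0 - lo] - mean_cols[var][a0 - lo + t]
                    )
                rel[t] = math.exp(lp)
            need = -math.log1p(-float(tgt.loc[a0]))
            i0 = a0 - lo
            if k == 0:
                # first target age: one common hazard over its ten years
                lam[i0 : i0 + 10] = need / rel.sum()
            else:
                have = float(np.dot(lam[i0 : i0 + 9], rel[:9]))
                residual = need - have
                if residual < 0:
                    raise ValueError(
                        f"{sex}, age {a0}: target risk {tgt.loc[a0]:.4g} below the "
                        "risk already implied by younger ages (non-monotone targets)"
                    )
                lam[i0 + 9] = residual / rel[9]
        idx = pd.MultiIndex.from_product(
            [[sex], np.arange(lo, hi + 1)], names=["sex", "age"]
        )
        table.loc[idx, "lambda0"] = lam
        full = pd.Series(np.nan, index=idx.get_level_values("age"), dtype=float)
        full.loc[ages] = tgt.to_numpy(dtype=float)
        table.loc[idx, "target_risk10"] = full.to_numpy()
    return replace(coeffs, table=table)


# ---------------------------------------------------------------------------
# batch API
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = {
    "SCORE": ("age", "sex", "ratio", "sbp", "smoker", "rheumatoid_arthritis"),
    "SCORE_FNF": ("age", "sex", "ratio", "sbp", "smoker", "rheumatoid_arthritis"),
    "GLOBO_LAB": ("age", "sex", "sbp", "tc", "smoker", "diabetes"),
    "GLOBO_OFFICE": ("age", "sex", "sbp", "bmi", "smoker"),
}


def predict_batch(
    profiles: pd.DataFrame,
    model_id: str,
    score_coeffs: ScoreCoefficients | None = None,
    fnf_multipliers: FnfMultiplierTable | None = None,
    globorisk_coeffs: GloboriskCoefficients | None = None,
) -> pd.DataFrame:
    """Vectorised cohort prediction: profiles in, (patient_id, model_id, risk10) out.

    ``profiles`` needs a ``patient_id`` column plus the predictor columns of
    the requested model (see the module docstring).  Missing coefficient
    bundles are loaded from the shipped data files.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    cols = _PROFILE_COLUMNS[model_id]
    missing = set(cols) - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing columns {sorted(missing)}")
    age = profiles["age"].to_numpy(dtype=float)
    sex = profiles["sex"].to_numpy()

    if model_id in ("SCORE", "SCORE_FNF"):
        coeffs = score_coeffs or load_score_coefficients()
        risk = _score_fatal_array(
            age,
            sex,
            profiles["ratio"].to_numpy(dtype=float),
            profiles["sbp"].to_numpy(dtype=float),
            profiles["smoker"].to_numpy(dtype=float),
            profiles["rheumatoid_arthritis"].to_numpy(dtype=bool),
            coeffs,
        )
        if model_id == "SCORE_FNF":
            table = fnf_multipliers or load_fnf_multipliers()
            mult = np.array([table.multiplier(s, a) for s, a in zip(sex, age)])
            risk = np.minimum(1.0, risk * mult)
    else:
        variant = "lab" if model_id == "GLOBO_LAB" else "office"
        coeffs = globorisk_coeffs or load_globorisk_coefficients(variant)
        values = {v: profiles[v].to_numpy(dtype=float) for v in coeffs.variables}
        risk = _globorisk_array(age, sex, values, coeffs)

    return pd.DataFrame(
        {
            "patient_id": profiles["patient_id"].to_numpy(),
            "model_id": model_id,
            "risk10": risk,
        }
    )
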