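"""Regenerate the versioned coefficient/data files shipped under cvdval/data.

The SCORE and multiplier files are written verbatim from the dictionaries
below.  The Globorisk per-age tables are built by defining national mean
risk-factor levels and target 10-year risks per (sex, age) and solving the
baseline annual hazards with ``cvdval.engines.recalibrate_baseline``, so the
shipped lambda0 column is exactly reproducible from the targets in the file.

Run from the repository root:  python scripts/build_coefficient_files.py
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cvdval.engines import GLOBORISK_VARIABLES, GloboriskCoefficients, recalibrate_baseline

DATA = Path(__file__).resolve().parents[1] / "src" / "cvdval" / "data"

SCORE = {
    "model": "SCORE (low-risk European regions), TC/HDL-ratio variant",
    "version": "2024.1",
    "source": (
        "Weibull baseline parameters and log-hazard coefficients transcribed "
        "from the 2003 SCORE project publication (low-risk equations, "
        "cholesterol-ratio variant). Verify against the original before any "
        "clinical use."
    ),
    "centering": {"ratio": 5.0, "sbp": 120.0},
    "ra_multiplier": 1.0,
    "params": {
        "male": {
            "chd": {"p": 4.71, "alpha": -22.1, "beta_ratio": 0.088, "beta_sbp": 0.018, "beta_smoker": 0.71},
            "non_chd": {"p": 5.64, "alpha": -26.7, "beta_ratio": 0.095, "beta_sbp": 0.022, "beta_smoker": 0.63},
        },
        "female": {
            "chd": {"p": 6.36, "alpha": -29.8, "beta_ratio": 0.088, "beta_sbp": 0.018, "beta_smoker": 0.71},
            "non_chd": {"p": 6.62, "alpha": -31.0, "beta_ratio": 0.095, "beta_sbp": 0.022, "beta_smoker": 0.63},
        },
    },
}

FNF = {
    "model": "SCORE-FNF fatal-to-total multipliers (EPIC-NL style)",
    "version": "2024.1",
    "source": (
        "PLACEHOLDER PROVENANCE: age/sex multipliers of this structure are "
        "defined in the Dutch CVRM guideline from EPIC-NL data; the exact "
        "published values were not available for transcription, so these are "
        "representative values (non-fatal burden relative to fatal falls "
        "with age and is larger in women). Replace from the guideline before "
        "any clinical use."
    ),
    "bands": [
        {"sex": "male", "age_lo": 40, "age_hi": 49, "multiplier": 4.0},
        {"sex": "male", "age_lo": 50, "age_hi": 59, "multiplier": 3.0},
        {"sex": "male", "age_lo": 60, "age_hi": 70, "multiplier": 2.3},
        {"sex": "female", "age_lo": 40, "age_hi": 49, "multiplier": 6.0},
        {"sex": "female", "age_lo": 50, "age_hi": 59, "multiplier": 4.0},
        {"sex": "female", "age_lo": 60, "age_hi": 70, "multiplier": 3.0},
    ],
}

GLOBO_BETAS = {
    "model": "Globorisk fatal+non-fatal CVD, laboratory and office variants",
    "version": "2024.1",
    "source": (
        "PLACEHOLDER PROVENANCE: coefficient structure (main effects with "
        "age interactions) follows the Globorisk publications; values are "
        "representative transcriptions pending verification against the "
        "originals. Recalibration targets and mean levels below are "
        "synthetic Netherlands-like inputs, as the national tables are not "
        "redistributable."
    ),
    "lab": {
        "age_center": 60.0,
        "betas": {
            "sbp": {"main": 0.022, "age_interaction": -0.0002},
            "tc": {"main": 0.22, "age_interaction": -0.004},
            "smoker": {"main": 0.60, "age_interaction": -0.012},
            "diabetes": {"main": 0.70, "age_interaction": -0.010},
        },
    },
    "office": {
        "age_center": 60.0,
        "betas": {
            "sbp": {"main": 0.022, "age_interaction": -0.0002},
            "bmi": {"main": 0.045, "age_interaction": -0.0006},
            "smoker": {"main": 0.65, "age_interaction": -0.012},
        },
    },
}

# model-specific outcome code lists: fatal causes as ICD-10 3-character
# prefixes, non-fatal diagnoses as exact ICPC codes
OUTCOME_CODES = []


def _add(model, system, codes, role):
    for c in codes:
        OUTCOME_CODES.append({"model_id": model, "code_system": system, "code": c, "role": role})


SCORE_FATAL = [
    # ischaemic heart disease, cerebrovascular disease, aortic aneurysm and
    # other atherosclerotic arterial disease
    "I20", "I21", "I22", "I23", "I24", "I25",
    "I60", "I61", "I62", "I63", "I64", "I65", "I66",
    "I70", "I71", "I72", "I73", "I74",
]
GLOBO_FATAL = [
    # fatal ischaemic heart disease, stroke, sudden cardiac death
    "I20", "I21", "I22", "I23", "I24", "I25",
    "I60", "I61", "I62", "I63", "I64", "I46",
]
_add("SCORE", "ICD-10", SCORE_FATAL, "fatal")
_add("SCORE_FNF", "ICD-10", SCORE_FATAL, "fatal")
# MI, heart failure, stroke/CVA, peripheral vascular disease
_add("SCORE_FNF", "ICPC", ["K75", "K77", "K90", "K92"], "nonfatal")
for model in ("GLOBO_LAB", "GLOBO_OFFICE"):
    _add(model, "ICD-10", GLOBO_FATAL, "fatal")
    _add(model, "ICPC", ["K75", "K90"], "nonfatal")  # non-fatal MI or stroke


def national_means(sex: str, age: np.ndarray) -> dict[str, np.ndarray]:
    """Smooth Netherlands-like mean risk-factor levels by sex and age."""
    d = age - 40.0
    if sex == "male":
        return {
            "sbp": 122.0 + 0.50 * d,
            "tc": 5.2 + 0.030 * d - 0.0009 * d**2,
            "smoker": 0.30 - 0.0040 * d,
            "diabetes": 0.04 + 0.0035 * d,
            "bmi": 25.5 + 0.050 * d - 0.0010 * d**2,
        }
    return {
        "sbp": 118.0 + 0.65 * d,
        "tc": 5.1 + 0.045 * d - 0.0010 * d**2,
        "smoker": 0.25 - 0.0035 * d,
        "diabetes": 0.03 + 0.0035 * d,
        "bmi": 25.0 + 0.080 * d - 0.0012 * d**2,
    }


def national_target_risk10(sex: str, age: np.ndarray) -> np.ndarray:
    """Target 10-year fatal+non-fatal CVD risk at national mean levels.

    A Gompertz-like annual hazard integrated over the ten attained ages;
    roughly 1.5% (men) / 0.7% (women) at 40 rising to 18% / 13% at 75.
    """
    if sex == "male":
        h0, slope = 0.0011, 0.072
    else:
        h0, slope = 0.00045, 0.085
    cum = np.zeros_like(age, dtype=float)
    for t in range(10):
        cum += h0 * np.exp(slope * (age + t - 40.0))
    return 1.0 - np.exp(-cum)


def build_globorisk_table(variant: str) -> pd.DataFrame:
    ages = np.arange(40, 85)
    frames = []
    for sex in ("male", "female"):
        means = national_means(sex, ages.astype(float))
        row = {"sex": sex, "age": ages, "lambda0": 0.0}
        for var in GLOBORISK_VARIABLES[variant]:
            row[f"mean_{var}"] = means[var]
        tgt = np.full(ages.shape, np.nan)
        mask = ages <= 75  # targets anchor lambda0 through attained age 84
        tgt[mask] = national_target_risk10(sex, ages[mask].astype(float))
        row["target_risk10"] = tgt
        frames.append(pd.DataFrame(row))
    table = pd.concat(frames).set_index(["sex", "age"]).sort_index()

    block = GLOBO_BETAS[variant]
    coeffs = GloboriskCoefficients(
        variant=variant,
        version=GLOBO_BETAS["version"],
        source=GLOBO_BETAS["source"],
        age_center=block["age_center"],
        betas={v: (b["main"], b["age_interaction"]) for v, b in block["betas"].items()},
        table=table,
    )
    return recalibrate_baseline(coeffs).table.reset_index()


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "score_low_risk.json").write_text(json.dumps(SCORE, indent=2) + "\n")
    (DATA / "fnf_multipliers.json").write_text(json.dumps(FNF, indent=2) + "\n")
    (DATA / "globorisk_betas.json").write_text(json.dumps(GLOBO_BETAS, indent=2) + "\n")
    for variant in ("lab", "office"):
        table = build_globorisk_table(variant)
        table.to_csv(DATA / f"globorisk_{variant}_table.csv", index=False)
    pd.DataFrame(OUTCOME_CODES).to_csv(DATA / "outcome_codes.csv", index=False)
    print(f"wrote coefficient files to {DATA}")


if __name__ == "__main__":
    main()
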