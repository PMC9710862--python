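# cvdval

External validation of 10-year cardiovascular risk prediction models on
routine general-practice data.

General practitioners estimate a patient's 10-year risk of cardiovascular
disease (CVD) with prediction equations — SCORE (fatal CVD), SCORE-FNF
(fatal plus non-fatal CVD, obtained by multiplying SCORE with age/sex
factors), and the two Globorisk variants (laboratory and office-based) —
but an equation derived in one population can be badly calibrated in
another. `cvdval` packages the complete workflow for checking this in a
GP setting, for epidemiologists and biostatisticians working with routine
electronic health records:

1. **Cohort construction** — select patients whose predictors were measured
   in a baseline window, apply each model's age band and history
   exclusions, link deterministically to a cause-of-death registry on
   (sex, date of birth, 4-digit postal code), classify model-specific
   fatal/non-fatal outcomes, and build censored 10-year follow-up.
2. **Risk computation** — the four engines, driven entirely by versioned,
   human-readable coefficient files.
3. **Validation** — discrimination by Harrell's C under right censoring,
   and calibration by decile plots against Kaplan–Meier estimates,
   three-knot restricted-cubic-spline curves, and the ICI/E50/E90 summary
   indices.
4. **Synthetic data** — because GP databases are not public, a seeded
   generator emulates the whole input structure (measurements, diagnoses,
   registry, linkage noise) from a Weibull proportional-hazards truth whose
   10-year risks are analytic, so every stage is testable end to end.

## The models

SCORE sums two cause-specific Weibull relative-risk equations. For each
cause, baseline survival to age *a* is S₀(a) = exp(−e^α (a−20)^p), and a
patient with linear predictor
w = β₁(ratio − 5) + β₂(SBP − 120) + β₃·smoker has 10-year risk
1 − (S₀(a+10)/S₀(a))^{e^w}. SCORE-FNF is min(1, SCORE × m(sex, age band)).
Globorisk accumulates hazard over ten one-year steps at attained age
a_t = a + t: risk = 1 − Π_t exp(−λ₀(a_t, sex) e^{LP_t}), where LP_t centres
each risk factor on national age/sex mean levels and λ₀ is recalibrated so
that mean-level profiles reproduce national 10-year risks exactly
(`recalibrate_baseline` solves this in closed form).

## Worked example

```yaml
# run.yaml
output_dir: out
seed: 7
models: [SCORE, SCORE_FNF, GLOBO_LAB, GLOBO_OFFICE]
simulation:
  n: 10000
```

```text
$ cvdval all -c run.yaml
SCORE: n=5400, events=17, C=0.776 (0.676-0.876), ICI=2.2%
SCORE_FNF: n=5400, events=547, C=0.670 (0.648-0.693), ICI=4.5%
GLOBO_LAB: n=8164, events=722, C=0.693 (0.674-0.711), ICI=3.1%
GLOBO_OFFICE: n=8164, events=722, C=0.661 (0.642-0.680), ICI=3.2%
```

Reading the output: of 10,000 simulated patients, 5,400 had complete SCORE
predictors in the window and passed the 40–70 age band and
diabetes/CVD-history exclusions (the Globorisk cohorts are larger — wider
age band, fewer exclusions). Only 17 fatal CVD events occurred in ten
years, which is why a fatal-only outcome is hard to validate in this
setting; the fatal-plus-non-fatal definitions yield hundreds. C around
0.66–0.69 is moderate discrimination; the ICI (mean absolute distance
between predicted risk and the spline-smoothed observed risk) of 3–5
percentage points reflects the deliberate mismatch between the generator's
true hazard and the shipped equations. `out/` also contains, per model, the
cohort and prediction CSVs, a baseline-characteristics table, decile and
spline calibration tables and plots, `report.json`, and a run manifest
(config hash, seed, coefficient file versions). Rerunning with the same
config and seed reproduces `report.json` byte for byte.

The same pipeline runs on real data by pointing `input_dir` at a directory
with `patients.csv`, `measurements.csv`, `diagnoses.csv` and
`death_registry.csv` (ISO-8601 dates; column layouts in
`cvdval/cohort.py`).

Coefficient files under `src/cvdval/data/` are versioned and editable;
files whose exact published values could not be transcribed are labelled
with placeholder provenance and should be replaced from the original
publications for substantive use (`scripts/build_coefficient_files.py`
regenerates everything, including solving the Globorisk baseline hazards
from the stored national targets).

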