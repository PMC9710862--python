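# Methods

`cvdval` re-creates the workflow for externally validating four 10-year
cardiovascular-disease (CVD) risk prediction models on routine
general-practice (GP) records: SCORE (fatal CVD only), SCORE-FNF (fatal plus
non-fatal via age/sex multipliers), and the Globorisk laboratory and office
variants. This note records the models as implemented, the choices made
where the published descriptions leave room, and what the synthetic data do
and do not establish.

## Cohort construction

**Timeline.** Baseline is 2009-01-01; follow-up runs to the administrative
end 2019-01-01, which coincides with the 10-year horizon. Predictors must
have been measured in the half-open window [2008-07-01, 2009-01-01) — the
operational definition of "selected for risk assessment by the GP". When a
patient has several measurements of one kind in the window the most recent
wins; same-date duplicates are averaged.

**Age** is completed years at baseline (integer floor), matching chart-based
age banding.

**Smoking.** Smoking status uses its own record window, 2008-01-01 to
2019-01-01: the record nearest in time to baseline decides, ties breaking to
the earlier record; `former` and `never` count as non-smoker; a patient with
no usable record (or only `unknown`) is undeterminable and cannot enter a
cohort whose model needs smoking. Registry-based analyses typically apply
more elaborate precedence rules among conflicting smoking records; the
nearest-record rule here is a deliberately simple, configurable choice.

**Eligibility.** SCORE/SCORE-FNF: ages 40–70, no history of diabetes or CVD;
Globorisk: ages 40–74, no history of stroke or coronary heart disease.
History means a diagnosis dated strictly before baseline — diagnoses on or
after baseline never exclude (no look-ahead). ICD-10 exclusion codes match
on the 3-character prefix, ICPC codes exactly.

**Registry linkage** is deterministic on the exact (sex, date of birth,
4-digit postal code) triple. Any key occurring more than once on either
side is ambiguous and its patients stay unlinked; linkage diagnostics count
linked/ambiguous/unlinked. No probabilistic linkage is attempted.

**Outcomes.** Each model has its own definition, shipped as an editable CSV
(`data/outcome_codes.csv`): fatal causes as ICD-10 3-character prefixes,
non-fatal diagnoses as exact ICPC codes. SCORE counts only fatal
atherosclerotic CVD; SCORE-FNF adds non-fatal MI, heart failure, stroke and
peripheral vascular disease; the two Globorisk variants share one narrower
definition (fatal IHD/stroke/sudden cardiac death plus non-fatal MI or
stroke). A linked death whose cause is outside the fatal set is a competing
(non-CVD) death and **censors** the patient — plain Kaplan–Meier follow-up,
not a competing-risks analysis. This matches how such validations are
usually run but overstates event risk when competing mortality is substantial;
with roughly 1–3% non-CVD death over ten years in this age band the bias is
small. Follow-up ends at the earliest of first qualifying event,
deregistration, non-CVD death, administrative end, or the horizon; an event
dated before baseline raises (prevalent disease should have been excluded),
and an event on the baseline date counts with half a day of follow-up.

## Risk engines

All numeric parameters live in versioned data files with provenance fields;
the engines contain only the functional forms. Files whose exact published
values could not be transcribed carry an explicit placeholder-provenance
label; every correctness guarantee in the test suite is independent of the
particular values.

**SCORE.** Two cause-specific Weibull relative-risk models (coronary and
non-coronary), each with baseline survival
`S0(a) = exp(−exp(α)(a−20)^p)` and linear predictor
`w = β_ratio (ratio − 5) + β_sbp (SBP − 120) + β_smoker·smoker`; the
conditional 10-year risk is `1 − (S0(a+10)/S0(a))^exp(w)`, summed over
causes, optionally multiplied by a rheumatoid-arthritis factor
(`ra_multiplier`, default 1.0 — the guideline's exact treatment of RA is not
public, so the factor is configurable and off by default), clipped to
[0, 1]. The TC/HDL-ratio coefficient variant is used, as the ratio is the
named predictor. The survival ratio is computed in log space
(`exp(−exp(α)[(a−10)^p − (a−20)^p])`) for accuracy.

**SCORE-FNF** multiplies the SCORE fatal risk by an age-band and sex
specific multiplier (inclusive integer bands partitioning 40–70, resolved at
completed baseline age), clipping at 1. Clipping after multiplication keeps
the output a probability; log-space combination was rejected as less
transparent. Risks are never rounded to chart cells — the validation uses
continuous predictions.

**Globorisk.** Ten one-year steps over attained ages `a_t = age + t`. The
coefficient of each risk factor carries an age interaction,
`β_j(a) = β_j + γ_j (a − 60)`; the linear predictor centres each factor on
the national mean level for that attained age and sex,
`LP_t = Σ_j β_j(a_t)(x_j − m_j(a_t, sex))`; annual survival is
`exp(−λ0(a_t, sex) exp(LP_t))` and the 10-year risk is one minus the
product. The laboratory variant uses SBP, total cholesterol, smoking and
diabetes; the office variant replaces cholesterol and diabetes with BMI.
One-year steps with annually updated age follow the published model;
sub-annual refinement is out of scope.

**Recalibration.** `recalibrate_baseline` solves the baseline annual hazards
`λ0(age, sex)` so that a profile at the national mean levels of each
baseline age attains exactly the national target 10-year risk. Because the
hazard enters the log-survival linearly, the system is triangular once
processed from the youngest target age (whose ten attained-age hazards are
taken constant): each subsequent age contributes exactly one new hazard,
recovered in closed form rather than by iterative root finding — the root is
exact to machine precision, and the round trip (recalibrate, then predict at
mean levels) reproduces targets to below 1e-10 by construction. Targets must
therefore be age-monotone enough that no residual hazard is negative;
violations raise. The shipped per-age tables (ages 40–84 per sex, so every
attained age of a 40–74-year-old is covered) were generated by exactly this
routine from the Netherlands-like target risks and mean levels stored in the
same file, making the files self-reproducing
(`scripts/build_coefficient_files.py`).

## Validation statistics

The unit is the prediction–outcome pair (predicted 10-year risk, follow-up
time in (0, 10], event indicator).

**Harrell's C.** Ordered pairs are comparable when the earlier time had the
event (ties in time count when exactly one of the two had the event);
concordant when the event-earlier subject had the higher prediction, with
prediction ties worth one half. The implementation is chunked O(n²) in
numpy; the default confidence interval is a normal approximation with the
linearised (Hájek-projection) variance of the concordant/comparable ratio,
with per-subject influence terms `u_s = K_s − c·W_s` and
`Var(ĉ) ≈ Σ_s u_s² / W²`. A seeded subject-resampling bootstrap
(percentile interval, configurable B, default 1000) is available as an
option; the two agree closely on simulated data. The C statistic assumes
censoring unrelated to risk; simulated deregistration is independent by
construction, so this holds exactly here although it need not in real data.

**Observed risk** is `1 − S_KM(10)` by the product-limit estimator
(lifelines), standard error by Greenwood's formula; when everyone is
censored before the horizon, the last estimate carries forward.

**Decile calibration** groups by sample deciles of predicted risk (linear
interpolation quantiles; boundary ties stay in the lower decile) and
compares the mean prediction per decile with the KM observed risk. With
fewer than ten distinct predictions the grouping falls back to the distinct
values, with a warning.

**Flexible curve.** Predictions clipped to [1e-6, 1−1e-6] are
cloglog-transformed, `x = log(−log(1−p))`; a restricted cubic spline with
three knots at the 10th/50th/90th percentiles of `x` (the conventional
placement for three knots) forms the covariates of a
Cox proportional-hazards calibration model. Each subject's smoothed
observed risk is the model-implied risk at the horizon; the curve is
evaluated on a 100-point grid over the observed prediction range. Constant
predictions degenerate to a flat line at the marginal KM risk.
Non-convergence raises with the sample size and event count in the message.
A logistic variant (event-by-horizon regression among subjects with known
10-year status) is available for sensitivity, since the survival-adapted and
binary formulations of the smoothed curve both appear in the literature;
the survival-adapted version is the default for censored outcomes.

**ICI / E50 / E90** are the mean, median and 90th percentile of
`|predicted − smoothed|`. Every quantile in the package (decile edges, E90,
knots) uses numpy's linear-interpolation convention, stated once in the
module docstring.

A configurable minimum-event guard (default 10) skips validation with an
explicit "insufficient events" note instead of reporting unstable
statistics — the situation that arises naturally for SCORE's fatal-only
outcome, where simulated cohorts yield event fractions of a few per mille.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
population. Risk-factor marginals default to the published baseline
characteristics of a GP population selected for risk assessment (age
≈58±8.6, SBP 141±16 mmHg, TC 5.4±1.2 mmol/L, TC/HDL 4.6±1.1, BMI 29±5,
smoking ≈14%, diabetes ≈29%), with presets per study cohort. Factors are
independent truncated normals/Bernoullis except a configurable SBP–BMI
correlation (default 0.3) — published cohort tables report marginals only. Each patient
has one GP visit date carrying all measurements (80% in the selection
window by default; a uniform-date mode exists for window-proportion tests)
plus, for 20%, an older superseded SBP reading.

The true event model is Weibull proportional hazards,
`H(t|x) = λ t^k exp(lp(x))` with λ = 0.0066, k = 1.1 and log-hazard ratios
of 0.07/year of age, 0.012/mmHg SBP, 0.55 for smoking, 0.12/mmol/L TC, 0.65
for diabetes and 0.45 for male sex — chosen once to give roughly 10–15%
ten-year fatal-plus-non-fatal risk with plausible gradients. The Weibull-PH
family makes every subject's true 10-year risk analytic, giving exact
ground truth for calibration recovery. Event times are drawn by inverse
transform; 3% of events are fatal (echoing the scarcity of fatal CVD in
this setting) and become registry rows; non-fatal events become dated ICPC
diagnosis rows with a code mix in which MI and stroke dominate but heart
failure and peripheral vascular disease appear, so the broader
fatal-plus-non-fatal outcome definition captures more events than the
Globorisk definition, as in the original setting. Deregistration (annual
hazard 0.03) and non-CVD death (0.002) censor independently; pre-baseline
history rows (diabetes T90, rheumatoid arthritis L88, prior CVD in 4% of
patients) drive the exclusion stages. Registry keys can be duplicated or
perturbed at configured rates to exercise linkage diagnostics.

What passing tests show: the pipeline's statistics recover known truth
under the model's own assumptions (independent censoring, correct
functional form, exact linkage keys, complete coding). What they do not
show: performance under informative censoring, GP selection-by-indication,
coding error, or real joint covariate distributions — none of which the
generator attempts to reproduce.

## Problem sizes and numerics

Default analysis runs use source populations of 5,000–20,000 patients;
calibration-recovery checks use 20,000 pairs and distributional checks up
to 50,000 — sizes at which binomial/Greenwood error bands are a percent or
less, chosen as the package's own test conditions. Engine agreement with
extended-precision (40-digit) reevaluation is required to 1e-12;
recalibration round trips to 1e-10; concordance equals brute-force
enumeration exactly. All simulation randomness flows from one integer seed
through `numpy.random.default_rng`; identical configurations reproduce
byte-identical tables and reports.

## Known limitations

- Competing mortality is censored, not modelled; observed "risks" are
  KM-complement estimates of the hypothetical world without competing
  death.
- Shipped SCORE-FNF multipliers and Globorisk coefficient/recalibration
  tables carry placeholder provenance (representative values in the
  published structure); replace them from the original publications before
  any substantive use. The file schema and validators make this a data
  edit, not a code change.
- Medication use and treatment drop-in are ignored: predicted and observed
  risks are both "as measured at baseline".
- Only binary sex is supported — the models define coefficients for two
  sexes only.
- ICPC-3 and SNOMED coding are out of scope.
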