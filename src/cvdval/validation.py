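"""Discrimination and calibration of predicted risks against censored outcomes.

The unit of analysis is the prediction-outcome pair: a predicted 10-year
risk, a follow-up time in (0, 10] years and an event indicator.  Functions
accept either three arrays ``(risk, time, event)`` or a single DataFrame with
columns ``risk10``, ``time_years``, ``event``.

Statistics
----------
* Harrell's C under right censoring, with a normal-approximation confidence
  interval from the linearised (Hajek-projection) variance of the
  concordant/comparable ratio.
* Observed risk as ``1 - S_KM(horizon)`` with Greenwood standard errors
  (via lifelines).
* Decile calibration: mean predicted risk per decile of predicted risk
  against the Kaplan-Meier observed risk.
* Flexible calibration: a proportional-hazards model on a three-knot
  restricted cubic spline of cloglog-transformed predictions, giving a
  per-subject smoothed observed risk and a 100-point curve; a
  logistic-regression variant on the subjects with known 10-year status is
  available for sensitivity analysis.
* ICI / E50 / E90: mean, median and 90th percentile of the absolute
  difference between predicted and smoothed observed risk.

Quantile convention: every quantile in this module (decile edges, E50, E90,
knot percentiles) uses linear interpolation (numpy's default), documented
here once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

__all__ = [
    "CStatistic",
    "DecileCalibration",
    "FlexibleCurve",
    "ValidationReport",
    "harrells_c",
    "km_observed_risk",
    "decile_calibration",
    "flexible_calibration",
    "ici_e50_e90",
    "validate",
]

_EPS = 1e-6


def _as_arrays(pairs, time=None, event=None):
    if time is None:
        df = pairs
        risk = np.asarray(df["risk10"], dtype=float)
        time = np.asarray(df["time_years"], dtype=float)
        event = np.asarray(df["event"], dtype=bool)
    else:
        risk = np.asarray(pairs, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
    if not (np.all(np.isfinite(risk)) and np.all(np.isfinite(time))):
        raise ValueError("risk and time must be finite")
    return risk, time, event


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CStatistic:
    c: float
    se: float
    ci_lo: float
    ci_hi: float
    n_comparable: int


def harrells_c(
    pairs,
    time=None,
    event=None,
    alpha=0.05,
    ci_method: str = "normal",
    n_bootstrap: int = 1000,
    bootstrap_seed: int = 0,
    _chunk=512,
) -> CStatistic:
    """Harrell's concordance for right-censored data.

    An ordered pair (i, j) is comparable when ``t_i < t_j`` and i had the
    event, or ``t_i == t_j`` with i the only event of the two.  It is
    concordant when ``risk_i > risk_j``; prediction ties count one half.
    With ``ci_method='normal'`` (default) the confidence interval is a
    normal approximation using the linearised variance of the ratio
    U-statistic (per-subject influence terms); ``ci_method='bootstrap'``
    uses seeded subject resampling (percentile interval; O(B n^2), intended
    for moderate n).
    """
    risk, time, event = _as_arrays(pairs, time, event)
    if ci_method == "bootstrap":
        point = harrells_c(risk, time, event, alpha, ci_method="normal", _chunk=_chunk)
        rng = np.random.RandomState(bootstrap_seed)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.randint(0, len(risk), len(risk))
            try:
                reps.append(
                    harrells_c(risk[idx], time[idx], event[idx], _chunk=_chunk).c
                )
            except ValueError:  # resample with no comparable pairs
                continue
        reps = np.asarray(reps)
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return CStatistic(point.c, float(reps.std(ddof=1)), float(lo), float(hi), point.n_comparable)
    if ci_method != "normal":
        raise ValueError(f"unknown ci_method {ci_method!r}")
    n = len(risk)
    if n < 2:
        raise ValueError("need at least two subjects")
    k_side = np.zeros(n)  # numerator contributions touching each subject
    w_side = np.zeros(n)  # comparable-pair counts touching each subject
    K = 0.0
    W = 0.0
    for start in range(0, n, _chunk):
        sl = slice(start, min(start + _chunk, n))
        ti = time[sl, None]
        ei = event[sl, None]
        ri = risk[sl, None]
        comp = (ei & (ti < time[None, :])) | (ei & ~event[None, :] & (ti == time[None, :]))
        kern = np.where(ri > risk[None, :], 1.0, np.where(ri == risk[None, :], 0.5, 0.0))
        kern = kern * comp
        K += kern.sum()
        W += comp.sum()
        k_side[sl] += kern.sum(axis=1)
        w_side[sl] += comp.sum(axis=1)
        k_side += kern.sum(axis=0)
        w_side += comp.sum(axis=0)
    if W == 0:
        raise ValueError("no comparable pairs under censoring")
    c = K / W
    u = k_side - c * w_side
    se = float(np.sqrt(np.sum(u**2)) / W)
    z = stats.norm.ppf(1 - alpha / 2)
    return CStatistic(
        c=float(c),
        se=se,
        ci_lo=float(max(0.0, c - z * se)),
        ci_hi=float(min(1.0, c + z * se)),
        n_comparable=int(W),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier observed risk
# ---------------------------------------------------------------------------


def km_observed_risk(pairs, time=None, event=None, horizon: float = 10.0):
    """Observed risk ``1 - S_KM(horizon)`` with its Greenwood standard error.

    If the last observation is censored before the horizon the product-limit
    estimate carries forward.
    """
    _, time, event = _as_arrays(pairs, time, event) if time is None else (
        None,
        np.asarray(time, dtype=float),
        np.asarray(event, dtype=bool),
    )
    if time is None or len(time) == 0:
        raise ValueError("km_observed_risk needs a nonempty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    s = float(kmf.predict(horizon))
    tab = kmf.event_table
    mask = (tab.index <= horizon) & (tab["observed"] > 0)
    d = tab.loc[mask, "observed"].to_numpy(dtype=float)
    r = tab.loc[mask, "at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.sum(d / (r * (r - d)))
    var = s**2 * gw if np.isfinite(gw) else 0.0
    return 1.0 - s, float(np.sqrt(max(var, 0.0)))


def _km_pairs(pairs, time, event, horizon):
    risk, t, e = _as_arrays(pairs, time, event)
    return risk, t, e


# ---------------------------------------------------------------------------
# decile calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecileCalibration:
    table: pd.DataFrame  # decile, n, mean_predicted, observed_risk, observed_se

    def __post_init__(self):
        mp = self.table["mean_predicted"].to_numpy()
        if np.any(np.diff(mp) < -1e-12):
            raise ValueError("mean predicted risk must be nondecreasing across deciles")


def decile_calibration(pairs, time=None, event=None, horizon: float = 10.0) -> DecileCalibration:
    """Group by decile of predicted risk; observed risk per group by KM.

    Decile edges are sample quantiles (linear interpolation); ties at an
    edge stay together in the lower decile.  With fewer than ten distinct
    prediction values the grouping falls back to the distinct values, with a
    warning.
    """
    risk, t, e = _as_arrays(pairs, time, event)
    if len(risk) < 10:
        raise ValueError("decile calibration needs n >= 10")
    distinct = np.unique(risk)
    if len(distinct) < 10:
        warnings.warn(
            f"fewer than 10 distinct prediction values; using "
            f"{len(distinct)} distinct-value groups",
            stacklevel=2,
        )
        bins = np.searchsorted(distinct, risk)
        n_groups = len(distinct)
    else:
        bins = pd.qcut(risk, 10, labels=False, duplicates="drop")
        n_groups = int(bins.max()) + 1
        if n_groups < 10:
            warnings.warn(
                f"tied prediction values reduced the deciles to {n_groups} groups",
                stacklevel=2,
            )
    rows = []
    for g in range(n_groups):
        m = bins == g
        obs, se = km_observed_risk(None, t[m], e[m], horizon)
        rows.append(
            {
                "decile": g + 1,
                "n": int(m.sum()),
                "mean_predicted": float(risk[m].mean()),
                "observed_risk": obs,
                "observed_se": se,
            }
        )
    return DecileCalibration(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# flexible calibration curve
# ---------------------------------------------------------------------------


def _cloglog(p: np.ndarray) -> np.ndarray:
    return np.log(-np.log1p(-p))


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails), Harrell's normalisation.

    For k knots returns k-1 columns: x itself plus k-2 nonlinear terms.
    """
    k = len(knots)
    t = knots
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[k - 2], 0, None) ** 3 * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + np.clip(x - t[k - 1], 0, None) ** 3 * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass(frozen=True)
class FlexibleCurve:
    grid_risk: np.ndarray = field(repr=False)
    grid_observed: np.ndarray = field(repr=False)
    per_subject: np.ndarray = field(repr=False)
    knots: np.ndarray  # on the cloglog(predicted risk) scale
    method: str = "cox"


def flexible_calibration(
    pairs,
    time=None,
    event=None,
    horizon: float = 10.0,
    n_knots: int = 3,
    method: str = "cox",
    grid_size: int = 100,
) -> FlexibleCurve:
    """Smooth observed risk as a function of predicted risk.

    Predictions are clipped to [1e-6, 1-1e-6] and cloglog-transformed; the
    spline knots sit at the 10th/50th/90th percentiles of the transformed
    predictions (for ``n_knots=3``; equally spaced tail percentiles
    otherwise).  ``method='cox'`` (default) fits a proportional-hazards
    calibration model and evaluates each subject's model-implied risk at the
    horizon; ``method='logistic'`` fits event-by-horizon logistic regression
    on the subjects whose 10-year status is known (event, or followed to the
    horizon) and is provided for sensitivity analysis.
    """
    risk, t, e = _as_arrays(pairs, time, event)
    if len(risk) < 50:
        raise ValueError("flexible calibration needs n >= 50")
    p = np.clip(risk, _EPS, 1 - _EPS)
    x = _cloglog(p)
    grid_p = np.linspace(p.min(), p.max(), grid_size)
    grid_x = _cloglog(grid_p)

    if np.ptp(x) < 1e-10:  # constant predictions: flat at the marginal risk
        marg, _ = km_observed_risk(None, t, e, horizon)
        return FlexibleCurve(
            grid_risk=grid_p,
            grid_observed=np.full(grid_size, marg),
            per_subject=np.full(len(p), marg),
            knots=np.full(n_knots, x[0]),
            method=method,
        )

    if n_knots == 3:
        q = [10.0, 50.0, 90.0]
    else:
        q = np.linspace(5, 95, n_knots)
    knots = np.percentile(x, q)
    basis = _rcs_basis(x, knots)
    gbasis = _rcs_basis(grid_x, knots)

    if method == "cox":
        df = pd.DataFrame(basis, columns=[f"b{i}" for i in range(basis.shape[1])])
        df["T"] = t
        df["E"] = e.astype(int)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="T", event_col="E")
        except ConvergenceError as exc:
            raise RuntimeError(
                f"flexible calibration PH model failed to converge (n={len(p)}, "
                f"events={int(e.sum())}): {exc}"
            ) from exc
        cols = [f"b{i}" for i in range(basis.shape[1])]
        sub = 1.0 - cph.predict_survival_function(df[cols], times=[horizon]).to_numpy()[0]
        grid_df = pd.DataFrame(gbasis, columns=cols)
        grid_obs = 1.0 - cph.predict_survival_function(grid_df, times=[horizon]).to_numpy()[0]
    elif method == "logistic":
        import statsmodels.api as sm

        known = e | (t >= horizon - 1e-9)
        if known.sum() < 50:
            raise ValueError("too few subjects with known 10-year status")
        X = sm.add_constant(basis[known])
        model = sm.GLM(e[known].astype(float), X, family=sm.families.Binomial())
        res = model.fit()
        sub = np.asarray(res.predict(sm.add_constant(basis)))
        grid_obs = np.asarray(res.predict(sm.add_constant(gbasis)))
    else:
        raise ValueError(f"unknown method {method!r}")

    return FlexibleCurve(
        grid_risk=grid_p,
        grid_observed=np.clip(grid_obs, 0.0, 1.0),
        per_subject=np.clip(sub, 0.0, 1.0),
        knots=knots,
        method=method,
    )


# ---------------------------------------------------------------------------
# ICI / E50 / E90
# ---------------------------------------------------------------------------


def ici_e50_e90(pairs, curve: FlexibleCurve | np.ndarray, time=None, event=None):
    """Mean, median and 90th percentile of |predicted - smoothed observed|.

    Quantiles use linear interpolation; the median at even n is the midpoint
    of the two central values.
    """
    if time is None and not isinstance(pairs, np.ndarray):
        risk = np.asarray(pairs["risk10"], dtype=float)
    else:
        risk = np.asarray(pairs, dtype=float)
    smoothed = curve.per_subject if isinstance(curve, FlexibleCurve) else np.asarray(curve)
    if len(smoothed) != len(risk):
        raise ValueError("smoothed values must align with predictions")
    d = np.abs(risk - smoothed)
    return float(d.mean()), float(np.median(d)), float(np.quantile(d, 0.9))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    model_id: str
    n: int
    n_events: int
    c_statistic: CStatistic
    mean_predicted: float
    event_fraction: float
    observed_risk: float
    observed_se: float
    ici: float
    e50: float
    e90: float
    deciles: DecileCalibration
    curve: FlexibleCurve

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n": self.n,
            "n_events": self.n_events,
            "c_statistic": self.c_statistic.c,
            "c_se": self.c_statistic.se,
            "c_ci": [self.c_statistic.ci_lo, self.c_statistic.ci_hi],
            "mean_predicted": self.mean_predicted,
            "event_fraction": self.event_fraction,
            "observed_risk_10y": self.observed_risk,
            "observed_se": self.observed_se,
            "ici": self.ici,
            "e50": self.e50,
            "e90": self.e90,
            "deciles": self.deciles.table.to_dict(orient="records"),
            "curve": {
                "method": self.curve.method,
                "knots_cloglog": self.curve.knots.tolist(),
                "grid_risk": self.curve.grid_risk.tolist(),
                "grid_observed": self.curve.grid_observed.tolist(),
            },
        }


def validate(
    pairs,
    time=None,
    event=None,
    horizon: float = 10.0,
    model_id: str = "",
    ici_method: str = "cox",
) -> ValidationReport:
    """Assemble the full discrimination + calibration report for one model."""
    risk, t, e = _as_arrays(pairs, time, event)
    cstat = harrells_c(risk, t, e)
    obs, obs_se = km_observed_risk(None, t, e, horizon)
    deciles = decile_calibration(risk, t, e, horizon)
    curve = flexible_calibration(risk, t, e, horizon, method=ici_method)
    ici, e50, e90 = ici_e50_e90(risk, curve)
    return ValidationReport(
        model_id=model_id,
        n=len(risk),
        n_events=int(e.sum()),
        c_statistic=cstat,
        mean_predicted=float(risk.mean()),
        event_fraction=float(e.mean()),
        observed_risk=obs,
        observed_se=obs_se,
        ici=ici,
        e50=e50,
        e90=e90,
        deciles=deciles,
        curve=curve,
    )
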