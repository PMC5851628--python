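"""Incidence rates and proportional-hazards estimation.

For each outcome the person-time table (one row per subject: follow-up days,
event indicator, exposure group) yields unadjusted incidence rates per 1,000
person-years with exact Poisson confidence intervals, and Cox
proportional-hazards fits of each NSAID versus ibuprofen — unadjusted
(exposure indicators only) and adjusted (a single ten-level-exposure model
per outcome that also includes the multinomial propensity probabilities as
continuous covariates, omitting the referent-group probability, plus every
covariate whose WCSD exceeded 0.1).

The proportional-hazards assumption is tested on the exposure terms with the
scaled Schoenfeld-residual test; when it rejects, the model is refit with
exposure x log(time) interaction terms (via episode splitting) and hazard
ratios are reported at the median follow-up time.

Time scale is days since cohort entry; the entry day contributes one day.
Incidence-rate confidence intervals use the exact Poisson (chi-square)
method.  No multiplicity adjustment is applied across the nine comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from clopnsaid.data_model import REFERENT_NSAID, STUDY_NSAIDS

DAYS_PER_YEAR = 365.25
EXPOSURE_PREFIX = "nsaid_"


def incidence_rate(
    n_events: int, person_years: float, per: float = 1000.0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Event rate per ``per`` person-years with an exact Poisson CI.

    The CI treats the event count as Poisson: lower bound
    ``chi2.ppf(alpha/2, 2k)/2`` (0 for k = 0), upper bound
    ``chi2.ppf(1 - alpha/2, 2k + 2)/2``, scaled by ``per / person_years``.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    k = int(n_events)
    scale = per / person_years
    rate = k * scale
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2 * scale
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2 * scale
    return rate, lo, hi


def person_time_table(followup: pd.DataFrame) -> pd.DataFrame:
    """Minimal per-subject survival frame from a follow-up table."""
    pt = followup[["person_id", "exposure_nsaid", "futime_days", "event"]].copy()
    pt["person_years"] = pt["futime_days"] / DAYS_PER_YEAR
    return pt


def incidence_table(pt: pd.DataFrame) -> pd.DataFrame:
    """Per-NSAID (plus overall) users, events, person-years, rate and CI."""
    rows = []
    groups = [("overall", pt)] + [
        (d, pt[pt["exposure_nsaid"] == d]) for d in STUDY_NSAIDS
    ]
    for name, sub in groups:
        if sub.empty:
            continue
        py = sub["person_years"].sum()
        k = int(sub["event"].sum())
        rate, lo, hi = incidence_rate(k, py)
        rows.append({"nsaid": name, "n_users": len(sub), "n_events": k,
                     "person_years": py, "rate_per_1000py": rate,
                     "rate_lo": lo, "rate_hi": hi})
    return pd.DataFrame(rows)


def _exposure_dummies(pt: pd.DataFrame, referent: str) -> pd.DataFrame:
    d = pd.get_dummies(pt["exposure_nsaid"], prefix=EXPOSURE_PREFIX, prefix_sep="")
    ref_col = f"{EXPOSURE_PREFIX}{referent}"
    return d.drop(columns=[ref_col], errors="ignore").astype(float)


def _prune_collinear(df: pd.DataFrame, keep: Sequence[str], log: list[str]) -> pd.DataFrame:
    """Drop zero-variance and linearly dependent columns (never `keep`)."""
    out = df.copy()
    for c in [c for c in out.columns if c not in keep]:
        if out[c].nunique() <= 1:
            out = out.drop(columns=c)
            log.append(f"dropped zero-variance column {c!r}")
    extra = [c for c in out.columns if c not in keep]
    if extra:
        X = out[list(keep) + extra].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * 1e-8 if diag.size else 0
        names = list(keep) + extra
        for i, c in enumerate(names):
            if diag[i] < tol and c not in keep:
                out = out.drop(columns=c)
                log.append(f"dropped collinear column {c!r}")
    return out


@dataclass
class CoxResult:
    """Hazard ratios for the exposure terms of one Cox fit."""

    hr: pd.DataFrame  # index nsaid; columns hr, lo, hi, coef, se
    fitter: object
    penalized: bool = False
    interaction: bool = False
    ph_test: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)
    design: pd.DataFrame | None = None


def _hr_frame(fitter: CoxPHFitter) -> pd.DataFrame:
    s = fitter.summary
    exp_rows = s.index[s.index.str.startswith(EXPOSURE_PREFIX)]
    out = s.loc[exp_rows, ["coef", "se(coef)", "exp(coef)",
                           "exp(coef) lower 95%", "exp(coef) upper 95%"]]
    out = out.rename(columns={"coef": "coef", "se(coef)": "se", "exp(coef)": "hr",
                              "exp(coef) lower 95%": "lo", "exp(coef) upper 95%": "hi"})
    out.index = [i[len(EXPOSURE_PREFIX):] for i in out.index]
    out.index.name = "nsaid"
    return out[["hr", "lo", "hi", "coef", "se"]]


def _fit_cox(df: pd.DataFrame, log: list[str]) -> tuple[CoxPHFitter, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="futime_days", event_col="event")
            return cph, False
        except ConvergenceError as exc:
            log.append(f"penalized fallback engaged: {exc}")
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="futime_days", event_col="event")
            return cph, True


def fit_unadjusted(pt: pd.DataFrame, referent: str = REFERENT_NSAID) -> CoxResult:
    """Cox fit with exposure-group indicators only (referent omitted)."""
    if (pt["exposure_nsaid"] == referent).sum() == 0:
        raise ValueError(f"referent group {referent!r} is empty")
    log: list[str] = []
    df = pd.concat(
        [pt[["futime_days", "event"]].reset_index(drop=True),
         _exposure_dummies(pt, referent).reset_index(drop=True)], axis=1
    )
    df["event"] = df["event"].astype(bool)
    cph, penalized = _fit_cox(df, log)
    return CoxResult(hr=_hr_frame(cph), fitter=cph, penalized=penalized,
                     log=log, design=df)


def ph_check(result: CoxResult, alpha: float = 0.05) -> tuple[pd.DataFrame, bool]:
    """Scaled Schoenfeld-residual proportionality test on exposure terms.

    Returns the per-term table (test statistic and p-value, log-time
    transform) and whether any exposure term rejects at ``alpha``; when too
    few events are available the check is skipped with a warning.
    """
    df = result.design
    n_events = int(df["event"].sum())
    if n_events < 10:
        warnings.warn("too few events for the proportionality test; check skipped")
        return pd.DataFrame(columns=["test_statistic", "p"]), False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(result.fitter, df, time_transform="log")
    tbl = res.summary
    tbl = tbl[tbl.index.get_level_values(0).str.startswith(EXPOSURE_PREFIX)]
    tbl = tbl.reset_index(level=list(range(1, tbl.index.nlevels)), drop=True) \
        if tbl.index.nlevels > 1 else tbl
    reject = bool((tbl["p"] < alpha).any())
    return tbl, reject


def _episode_split(df: pd.DataFrame, n_cuts: int = 4) -> pd.DataFrame:
    """Long (start, stop] format split at event-time quantiles.

    Adds ``log_t``: log analysis time evaluated at the episode midpoint —
    a step-function approximation of log(t) that is constant within an
    episode, hence identical for every subject in the same risk set.  (A
    per-subject time value would leak each subject's own event/censoring
    time into the covariate and bias time-interaction estimates.)
    """
    ev_times = df.loc[df["event"].astype(bool), "futime_days"]
    cuts = np.unique(np.quantile(ev_times, np.linspace(0, 1, n_cuts + 1)[1:-1]))
    cuts = cuts[(cuts > 0)]
    t_max = float(df["futime_days"].max())
    rows = []
    ids = np.arange(len(df))
    covs = [c for c in df.columns if c not in ("futime_days", "event")]
    for lo, hi in zip(np.r_[0, cuts], np.r_[cuts, np.inf]):
        m = (df["futime_days"] > lo).to_numpy()
        sub = df[m]
        mid = (lo + min(hi, t_max)) / 2
        ep = pd.concat(
            [pd.DataFrame({"id": ids[m], "start": float(lo),
                           "stop": np.minimum(sub["futime_days"].to_numpy(), hi),
                           "event": sub["event"].to_numpy()
                           & (sub["futime_days"].to_numpy() <= hi),
                           "log_t": np.log(max(mid, 0.5))}),
             sub[covs].reset_index(drop=True)], axis=1)
        rows.append(ep)
    return pd.concat(rows, ignore_index=True)


def fit_adjusted(
    pt: pd.DataFrame,
    ps_probabilities: pd.DataFrame,
    flagged_covariates: pd.DataFrame | None = None,
    referent: str = REFERENT_NSAID,
    alpha: float = 0.05,
    check_proportionality: bool = True,
) -> CoxResult:
    """Propensity-adjusted Cox model per outcome.

    One model with the full ten-level exposure: exposure indicators
    (referent omitted), the propensity probability vector as continuous
    covariates (referent-group probability omitted to avoid the sum-to-one
    redundancy), and all covariates flagged by the WCSD > 0.1 rule.
    Collinear columns are pruned automatically (logged).  If the
    proportionality test rejects on any exposure term, the model is refit
    with exposure x log(time) interactions and hazard ratios are reported at
    the median follow-up time.
    """
    log: list[str] = []
    parts = [pt[["futime_days", "event"]].reset_index(drop=True),
             _exposure_dummies(pt, referent).reset_index(drop=True)]
    exposure_cols = list(parts[1].columns)
    ps = ps_probabilities.loc[pt["person_id"]].reset_index(drop=True)
    ps = ps.drop(columns=[referent], errors="ignore")
    ps.columns = [f"ps_{c}" for c in ps.columns]
    parts.append(ps)
    if flagged_covariates is not None and len(flagged_covariates.columns):
        fc = flagged_covariates.loc[pt["person_id"]].reset_index(drop=True)
        parts.append(fc)
    df = pd.concat(parts, axis=1)
    df["event"] = df["event"].astype(bool)
    df = _prune_collinear(df, keep=["futime_days", "event"] + exposure_cols, log=log)

    cph, penalized = _fit_cox(df, log)
    result = CoxResult(hr=_hr_frame(cph), fitter=cph, penalized=penalized,
                       log=log, design=df)
    if not check_proportionality:
        return result
    ph_tbl, reject = ph_check(result, alpha=alpha)
    result.ph_test = ph_tbl
    if not reject:
        return result

    # PH violated: exposure x log(time) interaction via episode splitting.
    # The interaction uses log(t) centered at the median follow-up, so the
    # exposure main effect is directly the hazard ratio at the median time
    # and the fit stays well-conditioned at modest event counts.
    log.append("proportionality rejected; refitting with exposure x log(time) terms")
    t_med = np.log(max(float(df.loc[df["event"], "futime_days"].median()
                             if df["event"].any() else df["futime_days"].median()), 1.0))
    long = _episode_split(df)
    t_c = (long.pop("log_t") - t_med).to_numpy()
    inter = pd.DataFrame(
        {f"{c}__logt": long[c].to_numpy() * t_c for c in exposure_cols}, index=long.index
    )
    long = pd.concat([long, inter], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv = CoxTimeVaryingFitter(penalizer=1e-6)
        ctv.fit(long, id_col="id", start_col="start", stop_col="stop", event_col="event")
    s = ctv.summary
    rows = {}
    for c in exposure_cols:
        r = s.loc[c]
        rows[c[len(EXPOSURE_PREFIX):]] = {
            "hr": float(r["exp(coef)"]),
            "lo": float(r["exp(coef) lower 95%"]),
            "hi": float(r["exp(coef) upper 95%"]),
            "coef": float(r["coef"]), "se": float(r["se(coef)"]),
        }
    hr = pd.DataFrame.from_dict(rows, orient="index")
    hr.index.name = "nsaid"
    log.append(f"hazard ratios reported at median follow-up = {np.exp(t_med):.0f} days")
    return CoxResult(hr=hr, fitter=ctv, penalized=penalized, interaction=True,
                     ph_test=ph_tbl, log=log, design=df)


ANALYSIS_VARIANTS = (
    "primary", "age_lt65", "age_ge65", "male", "female",
    "nsaid_triggered", "clopidogrel_or_combination_triggered",
    "sens_180d", "sens_complete_data",
)


def _variant_mask(variant: str, followup: pd.DataFrame, female: pd.Series,
                  managed: set) -> pd.Series:
    if variant in ("primary", "sens_180d"):
        return pd.Series(True, index=followup.index)
    if variant == "age_lt65":
        return followup["age_at_entry"] < 65
    if variant == "age_ge65":
        return followup["age_at_entry"] >= 65
    if variant == "male":
        return ~followup["person_id"].map(female).astype(bool)
    if variant == "female":
        return followup["person_id"].map(female).astype(bool)
    if variant == "nsaid_triggered":
        return followup["trigger"] == "nsaid_triggered"
    if variant == "clopidogrel_or_combination_triggered":
        return followup["trigger"].isin(["clopidogrel_triggered", "combination_triggered"])
    if variant == "sens_complete_data":
        return ~followup["person_id"].isin(managed)
    raise ValueError(f"unknown analysis variant {variant!r}")


def run_analyses(
    followups: Mapping[str, pd.DataFrame],
    followups_180: Mapping[str, pd.DataFrame],
    ps_probabilities: pd.DataFrame,
    flagged_covariates: pd.DataFrame | None,
    female: pd.Series,
    managed_persons: set,
    variants: Sequence[str] = ANALYSIS_VARIANTS,
    referent: str = REFERENT_NSAID,
    adjust: bool = True,
    check_proportionality: bool = True,
) -> dict[str, dict[str, dict]]:
    """Primary, subgroup and sensitivity analyses for every outcome.

    ``followups``/``followups_180`` map outcome name to a follow-up table
    (with ``age_at_entry`` and ``trigger`` columns); ``female`` maps
    person_id to sex; ``managed_persons`` holds ids with potentially
    incomplete (managed-care) capture.  Returns, per outcome and variant,
    the incidence table and unadjusted/adjusted Cox results.  Variants whose
    stratum is empty (or loses an exposure arm entirely) are skipped with a
    warning.
    """
    results: dict[str, dict[str, dict]] = {}
    for outcome, fu in followups.items():
        ps = ps_probabilities[outcome] if isinstance(ps_probabilities, dict) else ps_probabilities
        flagged = (flagged_covariates[outcome] if isinstance(flagged_covariates, dict)
                   else flagged_covariates)
        results[outcome] = {}
        for variant in variants:
            base = followups_180[outcome] if variant == "sens_180d" else fu
            mask = _variant_mask(variant, base, female, managed_persons)
            sub = base[mask.to_numpy(dtype=bool)]
            if sub.empty or (sub["exposure_nsaid"] == referent).sum() == 0:
                warnings.warn(f"variant {variant!r} for {outcome!r}: empty stratum; skipped")
                continue
            pt = person_time_table(sub)
            entry = {"incidence": incidence_table(pt),
                     "unadjusted": fit_unadjusted(pt, referent=referent)}
            if adjust:
                entry["adjusted"] = fit_adjusted(
                    pt, ps, flagged, referent=referent,
                    check_proportionality=check_proportionality,
                )
            results[outcome][variant] = entry
    return results
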