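"""Simulation-based validation runs: planted-truth recovery and test calibration.

These helpers run the full analysis path on generated bundles with known
ground truth:

* :func:`adjusted_hr_recovery` — generate a confounded bundle with planted
  hazard ratios, run cohort construction, ascertainment, covariates,
  propensity fitting, balance and the adjusted Cox model for one outcome,
  and return estimated versus planted hazard ratios per comparator.
* :func:`coverage_fraction` — repeat recovery over seeds and report how
  often the 95% CI covers the planted value.
* :func:`ph_rejection_rate` — under exactly exponential (proportional)
  truth with homogeneous hazards, the per-term rejection rate of the
  proportionality test, which should sit near its nominal level.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

from clopnsaid import balance as _balance
from clopnsaid import covariates as _cov
from clopnsaid import hazards as _haz
from clopnsaid.cohort import build_drug_eras, compute_follow_up, find_cohort_entry
from clopnsaid.pipeline import post_entry_events
from clopnsaid.simulate import SimConfig, generate_bundle

#: default planted hazard ratios exercising protective, null and harmful effects
DEFAULT_PLANTED = {"celecoxib": 2.0, "naproxen": 0.7}


def _lean_followup(bundle, outcome: str, dataset_end):
    eras = build_drug_eras(bundle.dispensings)
    cohort, _ = find_cohort_entry(eras, bundle.enrollment, bundle.persons, dataset_end)
    events = post_entry_events(bundle, cohort)
    fu = compute_follow_up(
        cohort, bundle.dispensings, bundle.enrollment, events[outcome], dataset_end,
    )
    return cohort, fu


def adjusted_hr_recovery(
    seed: int,
    n_persons: int = 20_000,
    planted: Mapping[str, float] | None = None,
    outcome: str = "gib_ich",
    events_per_variable: int = 5,
    check_proportionality: bool = True,
    sim_overrides: Mapping | None = None,
) -> pd.DataFrame:
    """One recovery replicate: adjusted HRs vs the planted truth.

    The bundle is generated with the default (confounded) channeling and the
    planted hazard ratios applied to ``outcome``.  Adjustment follows the
    study procedure at synthetic scale: multinomial propensity on the
    prespecified covariates, WCSD-flagged covariates (capped by an
    events-per-variable floor), propensity probabilities as continuous terms.

    Returns a frame indexed by comparator with ``hr``, ``lo``, ``hi``,
    ``truth`` and ``covered``.
    """
    planted = dict(DEFAULT_PLANTED if planted is None else planted)
    cfg = SimConfig(
        n_persons=n_persons, seed=seed,
        true_hr={drug: {outcome: hr} for drug, hr in planted.items()},
        **(dict(sim_overrides) if sim_overrides else {}),
    )
    bundle = generate_bundle(cfg)
    cohort, fu = _lean_followup(bundle, outcome, cfg.calendar_end)

    prespec = _cov.build_prespecified(bundle, cohort)
    matrix = prespec.loc[:, prespec.nunique() > 1]
    exposure = pd.Series(
        cohort["exposure_nsaid"].to_numpy(),
        index=pd.Index(cohort["person_id"], name="person_id"),
    )
    model = _balance.fit_propensity(matrix, exposure)
    btab = _balance.balance_table(matrix, exposure, model)
    flag_rank = (
        btab.loc[btab["flag"]].groupby("covariate")["wcsd"].max().sort_values(ascending=False)
    )
    n_events = int(fu["event"].sum())
    budget = max(0, n_events // events_per_variable - (len(model.classes) - 1) * 2)
    flagged = matrix[list(flag_rank.index[:budget])]

    pt = _haz.person_time_table(fu)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _haz.fit_adjusted(
            pt, model.probabilities, flagged,
            check_proportionality=check_proportionality,
        )
    out = res.hr.copy()
    out["truth"] = [planted.get(d, 1.0) for d in out.index]
    out["covered"] = (out["lo"] <= out["truth"]) & (out["truth"] <= out["hi"])
    out["n_events"] = n_events
    out["interaction"] = res.interaction
    return out


def coverage_fraction(
    seeds: Sequence[int],
    n_persons: int = 20_000,
    planted: Mapping[str, float] | None = None,
    outcome: str = "gib_ich",
    drugs: Sequence[str] | None = None,
    **kwargs,
) -> tuple[float, pd.DataFrame]:
    """CI coverage of planted hazard ratios across replicate seeds.

    ``drugs`` restricts scoring to specific comparators (default: the
    planted drugs plus one null arm per planted value).  Returns the overall
    coverage fraction and the per-replicate detail table.
    """
    planted = dict(DEFAULT_PLANTED if planted is None else planted)
    if drugs is None:
        drugs = sorted(planted) + ["meloxicam"]  # a null (HR = 1) comparator
    rows = []
    for seed in seeds:
        rec = adjusted_hr_recovery(seed, n_persons=n_persons, planted=planted,
                                   outcome=outcome, **kwargs)
        sub = rec.loc[[d for d in drugs if d in rec.index]].reset_index()
        sub["seed"] = seed
        rows.append(sub)
    detail = pd.concat(rows, ignore_index=True)
    return float(detail["covered"].mean()), detail


def ph_rejection_rate(
    seeds: Sequence[int],
    n_persons: int = 6_000,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Per-term type-I error of the proportionality test under exponential truth.

    Simulates homogeneous exponential hazards (no covariate effects, no
    planted treatment effects), fits the exposure-only Cox model, applies the
    scaled Schoenfeld-residual test to each exposure term and pools term-level
    rejections across seeds.  Returns (rejection rate, number of term tests).
    """
    n_reject = 0
    n_tests = 0
    for seed in seeds:
        cfg = SimConfig(
            n_persons=n_persons, seed=seed,
            outcome_coef={o: {} for o in ("mortality", "ami_stroke", "gib_ich")},
        )
        bundle = generate_bundle(cfg)
        cohort, fu = _lean_followup(bundle, "mortality", cfg.calendar_end)
        pt = _haz.person_time_table(fu)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _haz.fit_unadjusted(pt)
            tbl, _ = _haz.ph_check(res, alpha=alpha)
        n_reject += int((tbl["p"] < alpha).sum())
        n_tests += len(tbl)
    return (n_reject / n_tests if n_tests else float("nan")), n_tests
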