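"""Synthetic administrative-claims generator with known ground truth.

Emulates the structure of a multi-state Medicaid-style claims extract for
studying concomitant clopidogrel + NSAID use: per-person enrollment spans, a
latent concomitancy (index) date, dispensings of clopidogrel and one of ten
study NSAIDs with days' supply and refill chains, baseline claims encoding
clinical covariates, background claims across the nine hdPS data dimensions,
and event processes for death, AMI/ischemic stroke and GIB/ICH.

The generator's two load-bearing properties:

* **Channeling.** NSAID assignment follows a multinomial logit on baseline
  covariates (age, sex, race, clinical flags), so naive between-drug
  contrasts are confounded and the same covariates are observable downstream
  (as baseline diagnosis/dispensing claims) for the propensity machinery.
* **Closed-form truth.** Event times are exponential: per-subject hazard =
  (per-outcome baseline) x (planted hazard ratio for the assigned NSAID)
  x exp(covariate log-hazard effects).  Proportional hazards holds exactly
  and planted hazard ratios are recoverable.  The baseline is normalized so
  that the referent-arm marginal event rate matches the configured rate per
  1,000 person-years.

Outcome events are written into claims with the exact setting/diagnosis
position the ascertainment algorithms require; "decoy" admissions (wrong
setting, wrong position, intracranial-injury-coded) are added at a
configurable rate and must never be captured.  Death competes with the
nonfatal outcomes by first-event-wins.
"""

from __future__ import annotations

import json
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from clopnsaid.data_model import (
    CLOPIDOGREL,
    REFERENT_NSAID,
    STUDY_NSAIDS,
    ClaimsBundle,
    make_bundle,
)

OUTCOMES = ("mortality", "ami_stroke", "gib_ich")

#: demographic columns of the channeling/outcome design matrix, in order
DEMOGRAPHIC_COLUMNS = (
    "age_std",
    "female",
    "race_black",
    "race_hispanic_latino",
    "race_other_unknown",
)

STATES = ("CA", "FL", "NY", "OH", "PA")

# synthetic code dictionaries ------------------------------------------------
AMI_EVENT_CODES = tuple(f"410{d}1" for d in range(10))
STROKE_EVENT_CODES = ("43301", "43311", "43391", "43401", "43411", "43491", "436", "43691")
GIB_EVENT_CODES = ("53140", "53100", "5310", "578", "5789", "57800", "56202", "53501", "53783")
ICH_EVENT_CODES = ("430", "431")
INJURY_CODES = ("80000", "80121", "85221", "85400")

OUTPATIENT_DX_POOL = tuple(
    f"7{i:03d}" for i in range(245, 285)
) + ("4659", "2859", "78079", "4019", "25000", "2724", "496")
INPATIENT_DX_POOL = ("486", "5990", "4280", "41400", "5859", "2762", "7802")
ICD9_PROC_POOL = tuple(f"{i:04d}" for i in range(3722, 3737))
CPT_POOL = tuple(f"99{i:03d}" for i in range(201, 226))
OTHER_MED_POOL = (
    "metformin", "lisinopril", "amlodipine", "furosemide", "metoprolol",
    "levothyroxine", "gabapentin", "sertraline", "albuterol", "insulin_glargine",
    "hydrochlorothiazide", "atenolol", "prednisone", "tramadol", "oxycodone",
    "digoxin", "isosorbide", "clonidine", "alendronate", "donepezil",
)


class ClinicalCovariate(BaseModel):
    """One binary baseline covariate, observable via a claim or dispensing."""

    name: str
    prevalence: float = Field(gt=0, lt=1)
    kind: Literal["diagnosis", "drug"]
    code: str  # ICD-9 dx code or ingredient name


def default_clinical_covariates() -> list[ClinicalCovariate]:
    spec = [
        ("hypertension", 0.55, "diagnosis", "4019"),
        ("diabetes", 0.30, "diagnosis", "25000"),
        ("hyperlipidemia", 0.40, "diagnosis", "2724"),
        ("osteoarthritis", 0.35, "diagnosis", "71590"),
        ("rheumatoid_arthritis", 0.06, "diagnosis", "7140"),
        ("heart_failure", 0.20, "diagnosis", "4280"),
        ("prior_ami", 0.12, "diagnosis", "412"),
        ("prior_gib", 0.08, "diagnosis", "53190"),
        ("renal_disease", 0.10, "diagnosis", "5859"),
        ("copd", 0.18, "diagnosis", "496"),
        ("aspirin", 0.18, "drug", "aspirin"),
        ("statin", 0.45, "drug", "simvastatin"),
        ("anticoagulant", 0.08, "drug", "warfarin"),
        ("ppi", 0.30, "drug", "omeprazole"),
    ]
    return [ClinicalCovariate(name=n, prevalence=p, kind=k, code=c) for n, p, k, c in spec]


def default_market_share() -> dict[str, float]:
    # user counts in the source population, normalized
    users = {
        "ibuprofen": 69779, "celecoxib": 66317, "naproxen": 36577,
        "rofecoxib": 26247, "meloxicam": 25459, "diclofenac": 18593,
        "valdecoxib": 7624, "indomethacin": 7651, "nabumetone": 7060,
        "etodolac": 2807,
    }
    total = sum(users.values())
    return {k: v / total for k, v in users.items()}


def default_channeling() -> dict[str, dict[str, float]]:
    """Covariate -> log-odds shifts of each NSAID vs ibuprofen.

    COX-2-selective agents channel toward older, female patients with GI
    history (they were marketed as gastroprotective); indomethacin skews
    male.  These same covariates carry outcome risk, inducing confounding.
    """
    return {
        "celecoxib": {"age_std": 0.45, "female": 0.25, "prior_gib": 0.50,
                      "osteoarthritis": 0.30, "ppi": 0.20},
        "rofecoxib": {"age_std": 0.50, "female": 0.30, "prior_gib": 0.40,
                      "osteoarthritis": 0.30},
        "valdecoxib": {"age_std": 0.50, "female": 0.35, "prior_gib": 0.40},
        "meloxicam": {"age_std": 0.35, "female": 0.20, "osteoarthritis": 0.30},
        "diclofenac": {"race_black": -0.20, "osteoarthritis": 0.20},
        "indomethacin": {"female": -0.45, "age_std": 0.15},
        "naproxen": {"age_std": 0.05},
        "nabumetone": {"female": 0.25, "age_std": 0.10},
        "etodolac": {"age_std": 0.20},
    }


def default_outcome_coef() -> dict[str, dict[str, float]]:
    """Covariate log hazard-ratio effects per outcome."""
    return {
        "mortality": {"age_std": 0.60, "heart_failure": 0.50, "renal_disease": 0.40,
                      "copd": 0.30, "prior_ami": 0.30, "diabetes": 0.20},
        "ami_stroke": {"age_std": 0.50, "prior_ami": 0.60, "diabetes": 0.30,
                       "hypertension": 0.30, "heart_failure": 0.30},
        "gib_ich": {"age_std": 0.30, "prior_gib": 0.80, "anticoagulant": 0.50,
                    "aspirin": 0.30},
    }


class SimConfig(BaseModel):
    """Generator configuration; defaults emulate the study conditions."""

    n_persons: int = Field(ge=0, default=10_000)
    seed: int = 0
    calendar_start: str = "1999-01-01"
    calendar_end: str = "2010-12-31"

    covariates: list[ClinicalCovariate] = Field(default_factory=default_clinical_covariates)
    market_share: dict[str, float] = Field(default_factory=default_market_share)
    channeling: dict[str, dict[str, float]] = Field(default_factory=default_channeling)
    #: nsaid -> outcome -> hazard ratio vs ibuprofen (missing entries = 1.0)
    true_hr: dict[str, dict[str, float]] = Field(default_factory=dict)
    #: referent-arm marginal event rates, events per 1,000 person-years
    marginal_rate_per_1000py: dict[str, float] = Field(
        default_factory=lambda: {"mortality": 50.8, "ami_stroke": 58.6, "gib_ich": 54.3}
    )
    outcome_coef: dict[str, dict[str, float]] = Field(default_factory=default_outcome_coef)

    female_fraction: float = Field(gt=0, lt=1, default=0.61)
    race_probs: dict[str, float] = Field(
        default_factory=lambda: {"white": 0.43, "black": 0.15,
                                 "hispanic_latino": 0.19, "other_unknown": 0.23}
    )
    age_mean: float = 66.0
    age_sd: float = 13.0

    supply_days: dict[int, float] = Field(
        default_factory=lambda: {15: 0.10, 30: 0.60, 60: 0.20, 90: 0.10}
    )
    refill_prob: float = Field(ge=0, le=1, default=0.70)
    max_refills: int = Field(ge=0, default=6)
    trigger_mix: dict[str, float] = Field(
        default_factory=lambda: {"nsaid": 0.45, "clopidogrel": 0.40, "combination": 0.15}
    )

    managed_care_fraction: float = Field(ge=0, le=1, default=0.10)
    short_baseline_fraction: float = Field(ge=0, le=1, default=0.03)
    age_out_fraction: float = Field(ge=0, le=1, default=0.02)
    multi_nsaid_fraction: float = Field(ge=0, le=1, default=0.02)
    switch_fraction: float = Field(ge=0, le=1, default=0.08)
    decoy_rate: float = Field(ge=0, le=1, default=0.25)
    background_claims: bool = True

    @field_validator("market_share")
    @classmethod
    def _arms_positive(cls, v):
        missing = set(STUDY_NSAIDS) - set(v)
        if missing:
            raise ValueError(f"market_share missing arms: {sorted(missing)}")
        if any(p <= 0 for p in v.values()):
            raise ValueError("zero-probability NSAID arm in market_share")
        return v

    @field_validator("true_hr")
    @classmethod
    def _hr_positive(cls, v):
        for drug, m in v.items():
            for o, hr in m.items():
                if hr <= 0:
                    raise ValueError(f"true_hr[{drug}][{o}] must be > 0")
        return v

    @model_validator(mode="after")
    def _check(self):
        if pd.Timestamp(self.calendar_start) >= pd.Timestamp(self.calendar_end):
            raise ValueError("calendar_start must precede calendar_end")
        for m in (self.supply_days, self.trigger_mix, self.race_probs):
            if abs(sum(m.values()) - 1) > 1e-6:
                raise ValueError("probability map must normalize to 1")
        return self

    def design_columns(self) -> list[str]:
        return list(DEMOGRAPHIC_COLUMNS) + [c.name for c in self.covariates]

    def hr(self, nsaid: str, outcome: str) -> float:
        return float(self.true_hr.get(nsaid, {}).get(outcome, 1.0))


def planted_truth(config: SimConfig) -> dict:
    """Machine-readable record of the generative truth for recovery tests."""
    return {
        "referent": REFERENT_NSAID,
        "outcomes": list(OUTCOMES),
        "true_hr": {
            n: {o: config.hr(n, o) for o in OUTCOMES}
            for n in STUDY_NSAIDS if n != REFERENT_NSAID
        },
        "channeling": config.channeling,
        "outcome_coef": config.outcome_coef,
        "marginal_rate_per_1000py": config.marginal_rate_per_1000py,
        "design_columns": config.design_columns(),
        "seed": config.seed,
    }


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _coef_vector(coef_map: dict[str, float], columns: list[str]) -> np.ndarray:
    unknown = set(coef_map) - set(columns)
    if unknown:
        raise ValueError(f"coefficients reference unknown covariates: {sorted(unknown)}")
    return np.array([coef_map.get(c, 0.0) for c in columns])


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; probs shape (n, k)."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def generate_bundle(
    config: SimConfig, return_truth: bool = False
) -> ClaimsBundle | tuple[ClaimsBundle, dict]:
    """Generate a claims bundle under the configured generative model.

    Deterministic for a fixed config (seed included); the returned bundle
    satisfies all claims-table invariants.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    cal0 = pd.Timestamp(config.calendar_start)
    cal1 = pd.Timestamp(config.calendar_end)
    horizon = (cal1 - cal0).days

    if n == 0:
        bundle = make_bundle()
        return (bundle, planted_truth(config)) if return_truth else bundle

    # ---- persons & demographics -------------------------------------------
    pid = np.array([f"P{i:07d}" for i in range(n)])
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 25, 97)
    n_out = int(round(config.age_out_fraction * n))
    if n_out:
        idx = rng.choice(n, n_out, replace=False)
        young = idx[: n_out // 2]
        age[young] = rng.uniform(10, 17, young.size)
        age[idx[n_out // 2:]] = rng.uniform(101, 105, idx[n_out // 2:].size)
    female = rng.random(n) < config.female_fraction
    races = list(config.race_probs)
    race = np.array(races)[_sample_categorical(rng, np.tile(
        np.array([config.race_probs[r] for r in races]), (n, 1)))]
    state = np.array(STATES)[rng.integers(0, len(STATES), n)]

    # latent index (first concomitancy) day, leaving >= 400 days of lookback
    t0 = rng.integers(400, horizon + 1, n)
    birth_day = t0 - (age * 365.25).astype(int) - rng.integers(0, 180, n)

    persons = pd.DataFrame({
        "person_id": pid,
        "birth_date": cal0 + pd.to_timedelta(birth_day, unit="D"),
        "sex": np.where(female, "female", "male"),
        "race_ethnicity": race,
        "state": state,
    })

    # ---- design matrix & treatment assignment -----------------------------
    cols = config.design_columns()
    X = np.zeros((n, len(cols)))
    X[:, 0] = (age - age.mean()) / age.std()
    X[:, 1] = female
    X[:, 2] = race == "black"
    X[:, 3] = race == "hispanic_latino"
    X[:, 4] = race == "other_unknown"
    for j, cov in enumerate(config.covariates, start=len(DEMOGRAPHIC_COLUMNS)):
        X[:, j] = rng.random(n) < cov.prevalence

    arms = list(STUDY_NSAIDS)
    share = config.market_share
    logits = np.zeros((n, len(arms)))
    for g, drug in enumerate(arms):
        if drug == REFERENT_NSAID:
            continue
        beta = _coef_vector(config.channeling.get(drug, {}), cols)
        logits[:, g] = np.log(share[drug] / share[REFERENT_NSAID]) + X @ beta
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    assigned = np.array(arms)[_sample_categorical(rng, probs)]

    # ---- enrollment --------------------------------------------------------
    enr_start = t0 - 365 - rng.integers(0, 700, n)
    short = rng.random(n) < config.short_baseline_fraction
    enr_start[short] = t0[short] - rng.integers(30, 300, short.sum())
    enr_end = t0 + rng.exponential(500, n).astype(int)
    enr_start = np.maximum(enr_start, 0)
    enr_end = np.clip(enr_end, t0, horizon)
    managed = (rng.random(n) < config.managed_care_fraction).astype(int)
    enrollment = pd.DataFrame({
        "person_id": pid,
        "start_date": cal0 + pd.to_timedelta(enr_start, unit="D"),
        "end_date": cal0 + pd.to_timedelta(enr_end, unit="D"),
        "managed_care": managed,
    })

    # ---- dispensings: clopidogrel + assigned NSAID ------------------------
    supplies = np.array(sorted(config.supply_days))
    supply_p = np.array([config.supply_days[s] for s in supplies])

    def draw_supply(k: int) -> np.ndarray:
        return supplies[_sample_categorical(rng, np.tile(supply_p, (k, 1)))]

    trig_labels = list(config.trigger_mix)
    trig = np.array(trig_labels)[_sample_categorical(rng, np.tile(
        np.array([config.trigger_mix[t] for t in trig_labels]), (n, 1)))]

    disp_pid: list[np.ndarray] = []
    disp_ing: list[np.ndarray] = []
    disp_day: list[np.ndarray] = []
    disp_sup: list[np.ndarray] = []

    def emit(mask_or_idx, ingredient, day, supply):
        disp_pid.append(pid[mask_or_idx])
        ing = ingredient if isinstance(ingredient, np.ndarray) else np.repeat(ingredient, len(day))
        disp_ing.append(ing)
        disp_day.append(day)
        disp_sup.append(supply)

    def drug_chain(leads: np.ndarray, ingredient_arr: np.ndarray):
        """First fill at t0 - lead, then a refill chain; guarantees the first
        fill's grace-extended coverage reaches t0 (lead <= supply + 14)."""
        s0 = draw_supply(n)
        lead = np.minimum(leads, s0 + 14 - rng.integers(0, 10, n))
        lead = np.maximum(lead, 0)
        start = t0 - lead
        emit(slice(None), ingredient_arr, start, s0)
        covered = start + s0 - 1
        alive = np.ones(n, dtype=bool)
        for _ in range(config.max_refills):
            alive &= rng.random(n) < config.refill_prob
            if not alive.any():
                break
            gap = rng.integers(-5, 13, n)
            late = rng.random(n) < 0.10  # occasional era-breaking gap
            gap[late] = rng.integers(16, 60, late.sum())
            nxt = covered + 1 + gap
            sup = draw_supply(n)
            ok = alive & (nxt <= horizon)
            emit(ok, ingredient_arr[ok] if isinstance(ingredient_arr, np.ndarray) else ingredient_arr,
                 nxt[ok], sup[ok])
            covered = np.where(ok, np.maximum(covered, nxt + sup - 1), covered)

    lead = rng.integers(10, 121, n)
    clop_lead = np.where(trig == "nsaid", lead, 0)  # NSAID-triggered: clop started earlier
    nsaid_lead = np.where(trig == "clopidogrel", lead, 0)
    drug_chain(clop_lead, np.repeat(CLOPIDOGREL, n))
    drug_chain(nsaid_lead, assigned)

    # entry-day multi-NSAID exposure (excluded downstream)
    n_multi = int(round(config.multi_nsaid_fraction * n))
    if n_multi:
        idx = rng.choice(n, n_multi, replace=False)
        other = np.array([
            rng.choice([d for d in STUDY_NSAIDS if d != assigned[i]]) for i in idx
        ])
        emit(idx, other, t0[idx], np.repeat(30, n_multi))
    # later switch to a different study NSAID (censoring rule 3)
    n_switch = int(round(config.switch_fraction * n))
    if n_switch:
        idx = rng.choice(n, n_switch, replace=False)
        other = np.array([
            rng.choice([d for d in STUDY_NSAIDS if d != assigned[i]]) for i in idx
        ])
        day = t0[idx] + rng.integers(20, 121, n_switch)
        keep = day <= horizon
        emit(idx[keep], other[keep], day[keep], np.repeat(30, int(keep.sum())))

    # baseline drug-covariate dispensings
    for j, cov in enumerate(config.covariates, start=len(DEMOGRAPHIC_COLUMNS)):
        if cov.kind != "drug":
            continue
        has = X[:, j] > 0
        day = t0[has] - rng.integers(10, 331, int(has.sum()))
        emit(has, cov.code, day, draw_supply(int(has.sum())))

    # ---- outcome event processes ------------------------------------------
    rate_day = {}
    for o in OUTCOMES:
        gamma = _coef_vector(config.outcome_coef.get(o, {}), cols)
        risk = np.exp(X @ gamma)
        target = config.marginal_rate_per_1000py[o] / 1000.0 / 365.25
        base = target / risk.mean()  # referent-arm marginal rate == target
        hr = np.array([config.hr(d, o) for d in assigned])
        rate_day[o] = base * risk * hr

    t_event = {o: rng.exponential(1.0 / rate_day[o]) for o in OUTCOMES}
    death_day = t0 + np.floor(t_event["mortality"]).astype(int)

    deaths_mask = death_day <= horizon
    deaths = pd.DataFrame({
        "person_id": pid[deaths_mask],
        "death_date": cal0 + pd.to_timedelta(death_day[deaths_mask], unit="D"),
    })

    # ---- claims ------------------------------------------------------------
    claim_rows: list[pd.DataFrame] = []
    claim_counter = [0]

    def add_claims(person_idx, setting, day, codes, code_type="icd9_dx",
                   position="principal", extra=None):
        """One claim per row of person_idx; `extra` adds a second code row
        sharing the claim id: (code, code_type, position) arrays/scalars."""
        k = len(person_idx)
        if k == 0:
            return np.array([], dtype=object)
        ids = np.array([f"C{claim_counter[0] + i:08d}" for i in range(k)])
        claim_counter[0] += k
        dates = cal0 + pd.to_timedelta(day, unit="D")
        base = pd.DataFrame({
            "person_id": pid[person_idx], "claim_id": ids, "setting": setting,
            "admission_date": dates, "discharge_date": dates,
            "code": codes, "code_type": code_type, "position": position,
        })
        claim_rows.append(base)
        if extra is not None:
            code2, ct2, pos2 = extra
            claim_rows.append(base.assign(code=code2, code_type=ct2, position=pos2))
        return ids

    def pick(pool, k):
        return np.array(pool)[rng.integers(0, len(pool), k)]

    # planted nonfatal outcome events (first-event-wins vs death)
    event_meta = {}
    for fam, components in (("ami_stroke", None), ("gib_ich", None)):
        t = t_event[fam]
        day = t0 + np.floor(t).astype(int)
        occurs = (t <= t_event["mortality"]) & (day <= horizon)
        idx = np.flatnonzero(occurs)
        if fam == "ami_stroke":
            u = rng.random(idx.size)
            is_both = u < 0.007
            is_ami = u < 0.007 + 0.635
            ami_idx = idx[is_ami]  # includes "both"
            stroke_idx = idx[~is_ami | is_both]
            add_claims(ami_idx, "inpatient", day[ami_idx],
                       pick(AMI_EVENT_CODES, ami_idx.size),
                       position=np.where(rng.random(ami_idx.size) < 0.7,
                                         "principal", "secondary"))
            add_claims(stroke_idx, "inpatient", day[stroke_idx],
                       pick(STROKE_EVENT_CODES, stroke_idx.size), position="principal")
        else:
            u = rng.random(idx.size)
            is_both = u < 0.001
            is_gib = u < 0.001 + 0.93
            gib_idx = idx[is_gib]
            ich_idx = idx[~is_gib | is_both]
            add_claims(gib_idx, "inpatient", day[gib_idx],
                       pick(GIB_EVENT_CODES, gib_idx.size),
                       position=np.where(rng.random(gib_idx.size) < 0.6,
                                         "principal", "secondary"))
            ich_setting = np.where(rng.random(ich_idx.size) < 0.8,
                                   "inpatient", "emergency_department")
            add_claims(ich_idx, ich_setting, day[ich_idx],
                       pick(ICH_EVENT_CODES, ich_idx.size), position="principal")
        event_meta[fam] = pd.DataFrame({
            "person_id": pid[idx],
            "date": cal0 + pd.to_timedelta(day[idx], unit="D"),
        })

    # decoy admissions: must never be ascertained
    n_decoy = int(round(config.decoy_rate * n))
    if n_decoy:
        idx = rng.choice(n, n_decoy, replace=False)
        day = t0[idx] + rng.integers(0, 201, n_decoy)
        day = np.minimum(day, horizon)
        kind = rng.integers(0, 4, n_decoy)
        # wrong setting: AMI code on an outpatient claim
        a = idx[kind == 0]
        add_claims(a, "outpatient", day[kind == 0], pick(AMI_EVENT_CODES, a.size))
        # wrong position: stroke code only as secondary diagnosis
        b = idx[kind == 1]
        add_claims(b, "inpatient", day[kind == 1], np.repeat("78650", b.size),
                   position="principal",
                   extra=(pick(("43491", "43411"), b.size), "icd9_dx", "secondary"))
        # stroke admission with intracranial-injury code as secondary dx
        c = idx[kind == 2]
        add_claims(c, "inpatient", day[kind == 2], pick(("43491", "43301"), c.size),
                   position="principal",
                   extra=(pick(INJURY_CODES, c.size), "icd9_dx", "secondary"))
        # ICH admission with injury code on the same admission
        d = idx[kind == 3]
        add_claims(d, "inpatient", day[kind == 3], pick(ICH_EVENT_CODES, d.size),
                   position="principal",
                   extra=(pick(INJURY_CODES, d.size), "icd9_dx", "secondary"))

    # baseline diagnosis-covariate claims (signal for prespecified covariates)
    for j, cov in enumerate(config.covariates, start=len(DEMOGRAPHIC_COLUMNS)):
        if cov.kind != "diagnosis":
            continue
        has = np.flatnonzero(X[:, j] > 0)
        day = t0[has] - rng.integers(10, 331, has.size)
        add_claims(has, "outpatient", day, np.repeat(cov.code, has.size))

    # background claims across the hdPS dimensions (baseline window)
    if config.background_claims:
        def background(setting, pool, lam, code_type="icd9_dx", position="principal"):
            counts = rng.poisson(lam, n)
            ridx = np.repeat(np.arange(n), counts)
            if ridx.size == 0:
                return
            day = t0[ridx] - rng.integers(1, 361, ridx.size)
            add_claims(ridx, setting, day, pick(pool, ridx.size),
                       code_type=code_type, position=position)

        background("outpatient", OUTPATIENT_DX_POOL, 3.0)
        background("outpatient", ICD9_PROC_POOL, 0.7, code_type="icd9_proc", position="")
        background("outpatient", CPT_POOL, 1.5, code_type="cpt_hcpcs", position="")
        background("other", OUTPATIENT_DX_POOL, 0.8)
        background("other", ICD9_PROC_POOL, 0.2, code_type="icd9_proc", position="")
        # inpatient admissions with dx + procedures sharing one claim
        inp = np.flatnonzero(rng.random(n) < 0.25)
        day = t0[inp] - rng.integers(1, 361, inp.size)
        ids = add_claims(inp, "inpatient", day, pick(INPATIENT_DX_POOL, inp.size),
                         extra=(pick(ICD9_PROC_POOL, inp.size), "icd9_proc", ""))
        if len(ids):
            claim_rows.append(claim_rows[-1].assign(
                code=pick(CPT_POOL, inp.size), code_type="cpt_hcpcs", position=""))
        # non-study outpatient medications
        counts = rng.poisson(2.0, n)
        ridx = np.repeat(np.arange(n), counts)
        if ridx.size:
            emit(ridx, pick(OTHER_MED_POOL, ridx.size),
                 t0[ridx] - rng.integers(1, 361, ridx.size), draw_supply(ridx.size))

    # no dispensings or claims after death: real claims stop at death, which
    # is what lets supply exhaustion end follow-up for the deceased
    death_of = pd.Series(death_day, index=pid)

    dispensings = pd.DataFrame({
        "person_id": np.concatenate(disp_pid),
        "ingredient": np.concatenate(disp_ing),
        "dispense_date": cal0 + pd.to_timedelta(np.concatenate(disp_day), unit="D"),
        "days_supply": np.concatenate(disp_sup).astype(int),
    })
    disp_day_all = (dispensings["dispense_date"] - cal0).dt.days
    alive = disp_day_all <= dispensings["person_id"].map(death_of)
    dispensings = dispensings[
        alive & (dispensings["dispense_date"] >= cal0) & (dispensings["dispense_date"] <= cal1)
    ].reset_index(drop=True)

    claims = (pd.concat(claim_rows, ignore_index=True) if claim_rows
              else None)
    if claims is not None:
        adm_day = (claims["admission_date"] - cal0).dt.days
        keep = (
            (claims["admission_date"] >= cal0) & (claims["admission_date"] <= cal1)
            & (adm_day <= claims["person_id"].map(death_of))
        )
        claims = claims[keep].sort_values(["claim_id"], kind="stable").reset_index(drop=True)

    bundle = make_bundle(
        persons=persons, enrollment=enrollment, dispensings=dispensings,
        claims=claims, deaths=deaths,
    )
    if return_truth:
        truth = planted_truth(config)
        truth["assigned_counts"] = pd.Series(assigned).value_counts().to_dict()
        truth["assigned"] = dict(zip(pid, assigned))
        truth["index_date"] = {
            p: (cal0 + pd.Timedelta(days=int(d))).strftime("%Y-%m-%d")
            for p, d in zip(pid, t0)
        }
        truth["planted_events"] = {
            fam: [
                {"person_id": r.person_id, "date": r.date.strftime("%Y-%m-%d")}
                for r in meta.itertuples()
            ]
            for fam, meta in event_meta.items()
        }
        truth["planted_deaths"] = [
            {"person_id": r.person_id, "date": r.death_date.strftime("%Y-%m-%d")}
            for r in deaths.itertuples()
        ]
        return bundle, truth
    return bundle
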