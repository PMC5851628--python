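"""Baseline covariate construction: prespecified + hdPS-selected.

Prespecified covariates are declared in a spec file (demographics,
utilization-intensity counts thresholded to binary, diagnosis flags, drug
flags, and prior-outcome flags) and are measured strictly within each
subject's one-year baseline window (entry - 365 .. entry - 1; a claim dated
on the entry day does not count).

The high-dimensional propensity score (hdPS) procedure generates empirical
covariates from nine claims "dimensions" (setting x coding system, plus
outpatient medication ingredients): per dimension the ``top_k`` most
prevalent codes become candidates; per comparator-vs-referent pair each
candidate is scored by its confounding potential — the absolute log of the
Bross multiplicative bias

    BiasM = (PC1 (RR - 1) + 1) / (PC0 (RR - 1) + 1)

where PC1/PC0 are the candidate's prevalences in the comparator/referent arm
and RR its outcome risk ratio (covariate-positive vs covariate-negative,
continuity-corrected, with RR < 1 folded to 1/RR so protective covariates
rank too) — and the ``top_n`` highest-scoring candidates are selected.  The
nine per-pair selections are pooled, de-duplicated, filtered for minimum
exposed-person counts and overlap with prespecified covariates, and the
survivors join the propensity model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clopnsaid.data_model import (
    CLOPIDOGREL,
    REFERENT_NSAID,
    STUDY_NSAIDS,
    ClaimsBundle,
    ValidationError,
)
from clopnsaid.outcomes import (
    OutcomeDefinition,
    _alternation,
    _matches,
    ascertain_outcome,
    load_outcome_definitions,
)

#: the nine hdPS data dimensions: (label, setting, code_type)
HDPS_DIMENSIONS = (
    ("inpatient_dx", "inpatient", "icd9_dx"),
    ("inpatient_px", "inpatient", "icd9_proc"),
    ("inpatient_cpt", "inpatient", "cpt_hcpcs"),
    ("outpatient_dx", "outpatient", "icd9_dx"),
    ("outpatient_px", "outpatient", "icd9_proc"),
    ("outpatient_cpt", "outpatient", "cpt_hcpcs"),
    ("other_dx", "other", "icd9_dx"),
    ("other_px", "other", "icd9_proc"),
    ("outpatient_meds", "meds", "ingredient"),
)


@dataclass(frozen=True)
class PrespecifiedCovariateSpec:
    name: str
    source: str  # demographic | utilization_count | diagnosis_flag | drug_flag | prior_outcome_flag
    coding: str  # binary | continuous
    definition: Mapping


def load_prespecified_specs(path: str | None = None) -> list[PrespecifiedCovariateSpec]:
    """Load the prespecified-covariate spec file (default: shipped spec)."""
    if path is None:
        text = resources.files("clopnsaid.data").joinpath("prespecified_covariates.json").read_text()
    else:
        text = open(path).read()
    return [PrespecifiedCovariateSpec(d["name"], d["source"], d["coding"], d["definition"])
            for d in json.loads(text)]


def _baseline_claims(bundle: ClaimsBundle, cohort: pd.DataFrame) -> pd.DataFrame:
    c = bundle.claims.merge(
        cohort[["person_id", "baseline_start", "baseline_end"]], on="person_id"
    )
    return c[(c["admission_date"] >= c["baseline_start"])
             & (c["admission_date"] <= c["baseline_end"])]


def _baseline_dispensings(bundle: ClaimsBundle, cohort: pd.DataFrame) -> pd.DataFrame:
    d = bundle.dispensings.merge(
        cohort[["person_id", "baseline_start", "baseline_end"]], on="person_id"
    )
    return d[(d["dispense_date"] >= d["baseline_start"])
             & (d["dispense_date"] <= d["baseline_end"])]


def build_prespecified(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    specs: Sequence[PrespecifiedCovariateSpec] | None = None,
    outcome_definitions: Mapping[str, OutcomeDefinition] | None = None,
) -> pd.DataFrame:
    """Prespecified covariate matrix, one row per cohort subject.

    All binary covariates are measured from claims/dispensings dated within
    the subject's baseline window; age is continuous at entry.
    """
    specs = specs if specs is not None else load_prespecified_specs()
    defs = outcome_definitions or load_outcome_definitions()
    idx = cohort["person_id"]
    out = pd.DataFrame(index=pd.Index(idx, name="person_id"))

    persons = bundle.persons.set_index("person_id").reindex(idx)
    demo = pd.DataFrame(index=out.index)
    demo["age"] = cohort.set_index("person_id")["age_at_entry"].astype(float)
    demo["female"] = (persons["sex"] == "female").astype(float)
    for r in ("black", "hispanic_latino", "other_unknown", "white"):
        demo[f"race_{r}"] = (persons["race_ethnicity"] == r).astype(float)
    for spec in specs:
        fld = spec.definition.get("field", "")
        if spec.source == "demographic" and fld.startswith("state_"):
            demo[fld] = (persons["state"] == fld[len("state_"):]).astype(float)

    bc = _baseline_claims(bundle, cohort)
    bd = _baseline_dispensings(bundle, cohort)

    for spec in specs:
        d = spec.definition
        if spec.source == "demographic":
            fld = d["field"]
            if fld not in demo.columns:
                raise ValidationError(f"covariate {spec.name!r}: unknown demographic field {fld!r}")
            out[spec.name] = demo[fld].to_numpy()
        elif spec.source == "utilization_count":
            if d.get("unit") == "dispensings":
                cnt = bd.groupby("person_id").size()
            else:
                sub = bc[bc["setting"] == d["setting"]]
                cnt = sub.groupby("person_id")["claim_id"].nunique()
            vals = out.index.map(cnt).fillna(0).to_numpy(dtype=float)
            out[spec.name] = (vals >= d["min_count"]).astype(float)
        elif spec.source == "diagnosis_flag":
            rx = _alternation(d["patterns"])
            sub = bc[(bc["code_type"] == "icd9_dx") & _matches(bc["code"].astype(str), rx)]
            flagged = set(sub["person_id"])
            out[spec.name] = idx.isin(flagged).astype(float).to_numpy()
        elif spec.source == "drug_flag":
            sub = bd[bd["ingredient"].isin(set(d["ingredients"]))]
            flagged = set(sub["person_id"])
            out[spec.name] = idx.isin(flagged).astype(float).to_numpy()
        elif spec.source == "prior_outcome_flag":
            ev = ascertain_outcome(bc, defs[d["outcome"]])
            flagged = set(ev["person_id"])
            out[spec.name] = idx.isin(flagged).astype(float).to_numpy()
        else:
            raise ValidationError(f"covariate {spec.name!r}: unknown source {spec.source!r}")
    return out


@dataclass
class HdpsCandidates:
    """Candidate empirical covariates and their per-subject flags."""

    table: pd.DataFrame  # dimension, code, column, n_persons
    flags: pd.DataFrame  # subjects x candidate columns (0/1)


def enumerate_candidates(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    top_k: int = 200,
    exclude_ingredients: Sequence[str] = (CLOPIDOGREL, *STUDY_NSAIDS),
) -> HdpsCandidates:
    """Per hdPS dimension, the ``top_k`` codes by distinct baseline persons.

    Ties at the rank-``top_k`` boundary break by lexicographic code order.
    Study-exposure ingredients are excluded from the medication dimension.
    """
    bc = _baseline_claims(bundle, cohort)
    bd = _baseline_dispensings(bundle, cohort)
    bd = bd[~bd["ingredient"].isin(set(exclude_ingredients))]

    rows = []
    flag_frames = {}
    subjects = pd.Index(cohort["person_id"], name="person_id")
    for label, setting, code_type in HDPS_DIMENSIONS:
        if setting == "meds":
            sub = bd.rename(columns={"ingredient": "code"})[["person_id", "code"]]
        else:
            sub = bc[(bc["setting"] == setting) & (bc["code_type"] == code_type)][
                ["person_id", "code"]
            ]
        if sub.empty:
            continue
        counts = (
            sub.drop_duplicates()
            .groupby("code")
            .size()
            .rename("n_persons")
            .reset_index()
            .sort_values(["n_persons", "code"], ascending=[False, True], kind="stable")
            .head(top_k)
        )
        for _, r in counts.iterrows():
            rows.append({"dimension": label, "code": r["code"],
                         "column": f"{label}:{r['code']}", "n_persons": int(r["n_persons"])})
        hit = sub[sub["code"].isin(set(counts["code"]))].drop_duplicates()
        piv = pd.crosstab(hit["person_id"], hit["code"]).clip(upper=1)
        piv.columns = [f"{label}:{c}" for c in piv.columns]
        flag_frames[label] = piv
    table = pd.DataFrame(rows, columns=["dimension", "code", "column", "n_persons"])
    if flag_frames:
        flags = pd.concat(flag_frames.values(), axis=1).reindex(subjects).fillna(0).astype(np.int8)
    else:
        flags = pd.DataFrame(index=subjects)
    flags = flags.loc[:, list(table["column"])] if len(table) else flags
    return HdpsCandidates(table=table, flags=flags)


def bross_bias_score(pc1: np.ndarray, pc0: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """|log BiasM| with RR folded to max(RR, 1/RR)."""
    rr = np.asarray(rr, dtype=float)
    rr_star = np.maximum(rr, 1.0 / rr)
    bias = (pc1 * (rr_star - 1) + 1) / (pc0 * (rr_star - 1) + 1)
    return np.abs(np.log(bias))


def rank_and_select(
    candidates: HdpsCandidates,
    exposure: pd.Series,
    comparator: str,
    outcome_event: pd.Series,
    referent: str = REFERENT_NSAID,
    top_n: int = 500,
) -> pd.DataFrame:
    """Score candidates on one comparator-vs-referent pair; keep ``top_n``.

    PC1/PC0 are covariate prevalences in the comparator/referent arm; RR is
    the outcome risk ratio in covariate-positive vs covariate-negative
    subjects of the pair, with a 0.5/1.0 continuity correction on empty
    cells.  Ranking is by descending bias score, ties broken by higher
    pooled prevalence then lexicographic column name.
    """
    mask = exposure.isin([comparator, referent]).to_numpy()
    if not mask.any() or not (exposure == comparator).any() or not (exposure == referent).any():
        raise ValueError(f"pair {comparator!r} vs {referent!r}: an arm has zero subjects")
    F = candidates.flags.to_numpy()[mask].astype(float)
    exp1 = (exposure == comparator).to_numpy()[mask]
    y = outcome_event.to_numpy()[mask].astype(float)

    pc1 = F[exp1].mean(axis=0)
    pc0 = F[~exp1].mean(axis=0)
    n1 = F.sum(axis=0)
    e1 = (F * y[:, None]).sum(axis=0)
    n0 = len(y) - n1
    e0 = y.sum() - e1
    degenerate = (e1 == 0) | (e0 == 0) | (n1 == 0) | (n0 == 0)
    e1 = np.where(degenerate, e1 + 0.5, e1)
    e0 = np.where(degenerate, e0 + 0.5, e0)
    n1 = np.where(degenerate, n1 + 1.0, n1)
    n0 = np.where(degenerate, n0 + 1.0, n0)
    rr = (e1 / n1) / (e0 / n0)

    score = bross_bias_score(pc1, pc0, rr)
    tbl = candidates.table.copy()
    tbl["PC1"], tbl["PC0"], tbl["RRcd"], tbl["bias_score"] = pc1, pc0, rr, score
    tbl["prevalence"] = F.mean(axis=0)
    tbl = tbl.sort_values(
        ["bias_score", "prevalence", "column"], ascending=[False, False, True], kind="stable"
    ).head(top_n)
    return tbl.reset_index(drop=True)


def merge_and_filter(
    per_pair_selections: Mapping[str, pd.DataFrame],
    candidates: HdpsCandidates,
    prespecified_codes: set[str] | None = None,
    min_exposed: int = 10,
) -> tuple[list[str], dict[str, int]]:
    """Pool per-pair selections into the final hdPS column set.

    De-duplicates identical covariates across pairs, drops columns flagged in
    fewer than ``min_exposed`` subjects, drops columns whose code coincides
    with a prespecified covariate definition, and returns the retained
    columns with the bookkeeping record.  The accounting identity
    ``retained = pooled - duplicates - under_threshold - prespecified_overlap``
    holds by construction.
    """
    pooled = sum(len(s) for s in per_pair_selections.values())
    seen: list[str] = []
    seen_set: set[str] = set()
    for sel in per_pair_selections.values():
        for col in sel["column"]:
            if col not in seen_set:
                seen.append(col)
                seen_set.add(col)
    duplicates = pooled - len(seen)

    counts = candidates.flags[seen].sum(axis=0) if seen else pd.Series(dtype=float)
    enough = [c for c in seen if counts[c] >= min_exposed]
    under = len(seen) - len(enough)

    pres = prespecified_codes or set()
    code_of = dict(zip(candidates.table["column"], candidates.table["code"]))
    retained_cols = [c for c in enough if code_of.get(c) not in pres]
    overlap = len(enough) - len(retained_cols)

    accounting = hdps_accounting(pooled, duplicates, under, overlap)
    return retained_cols, accounting


def hdps_accounting(
    pooled: int, duplicates: int, under_threshold: int, prespecified_overlap: int
) -> dict[str, int]:
    """The hdPS selection bookkeeping record and its defining identity."""
    return {
        "pooled": int(pooled),
        "duplicates": int(duplicates),
        "under_threshold": int(under_threshold),
        "prespecified_overlap": int(prespecified_overlap),
        "retained": int(pooled - duplicates - under_threshold - prespecified_overlap),
    }


def prespecified_code_set(
    specs: Sequence[PrespecifiedCovariateSpec] | None = None,
) -> set[str]:
    """Codes/ingredients referenced exactly by prespecified definitions."""
    specs = specs if specs is not None else load_prespecified_specs()
    out: set[str] = set()
    for s in specs:
        d = s.definition
        if s.source == "diagnosis_flag":
            out |= {p.replace(".", "") for p in d["patterns"] if "*" not in p}
        elif s.source == "drug_flag":
            out |= set(d["ingredients"])
    return out


def hdps_select(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    exposure: pd.Series,
    outcome_event: pd.Series,
    top_k: int = 200,
    top_n: int = 500,
    min_exposed: int = 10,
    referent: str = REFERENT_NSAID,
    specs: Sequence[PrespecifiedCovariateSpec] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full hdPS pass for one outcome: enumerate, rank per pair, merge.

    Returns the selected empirical covariate matrix (subjects x columns)
    and the accounting record.  Pairs with an empty arm are skipped.
    """
    cand = enumerate_candidates(bundle, cohort, top_k=top_k)
    if cand.table.empty:
        return pd.DataFrame(index=cand.flags.index), hdps_accounting(0, 0, 0, 0)
    selections: dict[str, pd.DataFrame] = {}
    for drug in STUDY_NSAIDS:
        if drug == referent:
            continue
        try:
            selections[drug] = rank_and_select(
                cand, exposure, drug, outcome_event, referent=referent, top_n=top_n
            )
        except ValueError:
            continue  # empty arm: pair skipped
    cols, accounting = merge_and_filter(
        selections, cand, prespecified_code_set(specs), min_exposed=min_exposed
    )
    return cand.flags[cols].astype(float), accounting
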