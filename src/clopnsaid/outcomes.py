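"""Claims-based outcome ascertainment.

Each outcome (AMI, ischemic stroke, GIB, ICH) is defined declaratively by the
claim settings it may appear in, the diagnosis position required, ICD-9
wildcard include/exclude patterns, and an optional intracranial-injury
exclusion applied to the whole admission.  The shipped definition file
(``data/outcome_definitions.json``) carries the standard validated code
lists; all-cause death comes from the death-record table.

Wildcard semantics mirror ICD-9-CM code structure: a pattern without ``*``
requires an exact full-length match; a terminal ``*`` matches any suffix
(including the empty one); an interior ``*`` matches exactly one character,
so ``410.*1`` denotes the five-digit family 410x1.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from clopnsaid.data_model import ClaimsBundle, ValidationError, normalize_icd9

DEATH = "death"
OUTCOME_FAMILIES = {
    "mortality": (DEATH,),
    "ami_stroke": ("AMI", "ischemic_stroke"),
    "gib_ich": ("GIB", "ICH"),
}

_PATTERN_RE = re.compile(r"^[0-9A-Za-z.]*\*?[0-9A-Za-z.]*$")


@dataclass(frozen=True)
class InjuryExclusion:
    patterns: tuple[str, ...]
    position_scope: str  # "secondary" or "any"


@dataclass(frozen=True)
class OutcomeDefinition:
    """Operational definition of one claims-ascertained outcome."""

    name: str
    settings: tuple[str, ...]
    positions: str  # "principal_only" or "any_position"
    include_patterns: tuple[str, ...]
    exclude_patterns: tuple[str, ...] = ()
    injury_exclusion: InjuryExclusion | None = None
    description: str = ""


def _pattern_to_regex(pattern: str) -> str:
    pat = normalize_icd9(pattern)
    if not pat or pat.count("*") > 1 or not _PATTERN_RE.match(pattern):
        raise ValidationError(f"malformed ICD-9 pattern: {pattern!r}")
    if pat.endswith("*"):
        return re.escape(pat[:-1]) + r"[0-9A-Za-z]*"
    if "*" in pat:
        i = pat.index("*")
        return re.escape(pat[:i]) + r"[0-9A-Za-z]" + re.escape(pat[i + 1 :])
    return re.escape(pat)


def match_icd9(pattern: str, code: str) -> bool:
    """Whether a dot-free code matches one ICD-9 wildcard pattern."""
    return re.fullmatch(_pattern_to_regex(pattern), normalize_icd9(code)) is not None


def _alternation(patterns: Iterable[str]) -> re.Pattern | None:
    parts = [_pattern_to_regex(p) for p in patterns]
    if not parts:
        return None
    return re.compile("^(?:" + "|".join(parts) + ")$")


def _matches(codes: pd.Series, rx: re.Pattern | None) -> pd.Series:
    if rx is None:
        return pd.Series(False, index=codes.index)
    return codes.str.match(rx)


def load_outcome_definitions(path: str | None = None) -> dict[str, OutcomeDefinition]:
    """Load outcome definitions from JSON (default: the shipped code lists)."""
    if path is None:
        text = resources.files("clopnsaid.data").joinpath("outcome_definitions.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)
    out: dict[str, OutcomeDefinition] = {}
    for name, d in raw.items():
        inj = d.get("injury_exclusion")
        out[name] = OutcomeDefinition(
            name=name,
            settings=tuple(d["settings"]),
            positions=d["positions"],
            include_patterns=tuple(d["include_patterns"]),
            exclude_patterns=tuple(d.get("exclude_patterns", ())),
            injury_exclusion=(
                InjuryExclusion(tuple(inj["patterns"]), inj["position_scope"]) if inj else None
            ),
            description=d.get("description", ""),
        )
    return out


def ascertain_outcome(
    claims: pd.DataFrame,
    definition: OutcomeDefinition,
    widen_same_admission: bool = False,
) -> pd.DataFrame:
    """First qualifying event date per person for one outcome definition.

    A claim qualifies when its setting is allowed, a diagnosis in an allowed
    position matches an include pattern and no exclude pattern, and no
    diagnosis on the same admission matches the injury exclusion (with its
    stated position scope).  "Same admission" means the same claim record;
    with ``widen_same_admission`` an injury code on any overlapping inpatient
    claim of the person also disqualifies.  The event date is the admission
    date.

    Returns
    -------
    DataFrame with columns ``person_id``, ``outcome``, ``date``.
    """
    empty = pd.DataFrame({"person_id": pd.Series(dtype=object),
                          "outcome": pd.Series(dtype=object),
                          "date": pd.Series(dtype="datetime64[ns]")})
    if claims.empty:
        return empty
    dx = claims[(claims["code_type"] == "icd9_dx") & claims["setting"].isin(definition.settings)]
    if dx.empty:
        return empty
    codes = dx["code"].astype(str)
    hit = _matches(codes, _alternation(definition.include_patterns))
    hit &= ~_matches(codes, _alternation(definition.exclude_patterns))
    if definition.positions == "principal_only":
        hit &= dx["position"] == "principal"
    cand = dx[hit]
    if cand.empty:
        return empty

    inj = definition.injury_exclusion
    if inj is not None:
        inj_dx = claims[claims["code_type"] == "icd9_dx"]
        if inj.position_scope == "secondary":
            inj_dx = inj_dx[inj_dx["position"] == "secondary"]
        inj_hit = inj_dx[_matches(inj_dx["code"].astype(str), _alternation(inj.patterns))]
        bad_claims = set(inj_hit["claim_id"])
        cand = cand[~cand["claim_id"].isin(bad_claims)]
        if widen_same_admission and not inj_hit.empty and not cand.empty:
            spans = inj_hit.assign(
                end=inj_hit["discharge_date"].fillna(inj_hit["admission_date"])
            )[["person_id", "admission_date", "end"]]
            merged = cand.merge(spans, on="person_id", suffixes=("", "_inj"))
            bad = merged[
                (merged["admission_date"] >= merged["admission_date_inj"])
                & (merged["admission_date"] <= merged["end"])
            ]["claim_id"].unique()
            cand = cand[~cand["claim_id"].isin(set(bad))]
    if cand.empty:
        return empty
    first = cand.groupby("person_id", as_index=False)["admission_date"].min()
    return pd.DataFrame(
        {"person_id": first["person_id"], "outcome": definition.name, "date": first["admission_date"]}
    )


def ascertain_death(deaths: pd.DataFrame) -> pd.DataFrame:
    """Death events from the death-record table (one record per person)."""
    if deaths["person_id"].duplicated().any():
        pid = deaths.loc[deaths["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValidationError(f"duplicate death record for person {pid!r}")
    return pd.DataFrame(
        {"person_id": deaths["person_id"], "outcome": DEATH, "date": deaths["death_date"]}
    )


def composite_first_event(
    component_events: Sequence[pd.DataFrame], name: str
) -> pd.DataFrame:
    """Per person, the earliest event across component outcomes.

    A same-day pair of components counts once; the ``both`` flag marks such
    ties so the component overlap can be tallied separately.

    Returns
    -------
    DataFrame with columns ``person_id``, ``outcome`` (= ``name``), ``date``,
    ``both`` (bool).
    """
    frames = [f for f in component_events if f is not None and not f.empty]
    if not frames:
        return pd.DataFrame({"person_id": pd.Series(dtype=object),
                             "outcome": pd.Series(dtype=object),
                             "date": pd.Series(dtype="datetime64[ns]"),
                             "both": pd.Series(dtype=bool)})
    allev = pd.concat(frames, ignore_index=True)
    first = allev.groupby("person_id")["date"].min()
    at_min = allev.merge(first.rename("min_date"), on="person_id")
    at_min = at_min[at_min["date"] == at_min["min_date"]]
    n_components = at_min.groupby("person_id")["outcome"].nunique()
    out = first.reset_index()
    out["outcome"] = name
    out["both"] = out["person_id"].map(n_components).to_numpy() > 1
    return out[["person_id", "outcome", "date", "both"]]


def ascertain_all(bundle: ClaimsBundle, definitions=None) -> dict[str, pd.DataFrame]:
    """All three study endpoints: mortality, AMI/ischemic stroke, GIB/ICH.

    Returns a dict keyed by outcome family with first-event tables.
    """
    defs = definitions or load_outcome_definitions()
    ami = ascertain_outcome(bundle.claims, defs["AMI"])
    stroke = ascertain_outcome(bundle.claims, defs["ischemic_stroke"])
    gib = ascertain_outcome(bundle.claims, defs["GIB"])
    ich = ascertain_outcome(bundle.claims, defs["ICH"])
    death = ascertain_death(bundle.deaths)
    death = death.assign(both=False)
    return {
        "mortality": death[["person_id", "outcome", "date", "both"]],
        "ami_stroke": composite_first_event([ami, stroke], "ami_stroke"),
        "gib_ich": composite_first_event([gib, ich], "gib_ich"),
    }
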