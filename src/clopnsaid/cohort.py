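"""New-user concomitant-exposure cohort construction.

Dispensings are first assembled into *drug eras*: contiguous exposure
intervals for one person and ingredient, bridging gaps of at most
``grace_days`` (default 15) between the covered end of one fill and the next
fill, with overlapping refills stockpiled (coverage extends rather than
truncates).  Cohort entry is the first calendar day anywhere in a person's
observed history on which a clopidogrel era and exactly one study-NSAID era
overlap, each era extended by the grace tail; eligibility (age 18-100,
one-year continuous baseline enrollment) is assessed at that day and a
person who fails it never enters later (apparently-new-user design).

Follow-up runs from the entry day (which contributes one day of person-time)
to the earliest of: the outcome; exhaustion of either drug's supply plus
grace; the day before a dispensing of a different study NSAID; disenrollment;
the end of the dataset; and, optionally, a fixed day-count censor.  Ties
resolve in favor of the outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from clopnsaid.data_model import CLOPIDOGREL, STUDY_NSAIDS

DAY = pd.Timedelta(days=1)

#: follow-up end reasons, in tie-break priority order after the outcome
END_REASONS = (
    "outcome",
    "supply_end",
    "nsaid_switch",
    "disenrollment",
    "dataset_end",
    "day_censor",
)


def build_drug_eras(dispensings: pd.DataFrame, grace_days: int = 15) -> pd.DataFrame:
    """Merge dispensings into per-person, per-ingredient exposure eras.

    Successive coverage intervals are merged when the next fill starts no more
    than ``grace_days`` after the current covered end; the covered end extends
    as ``max(current_end, dispense_date + days_supply - 1)``.  The stored era
    ``end_date`` is the last covered supply day — the grace tail is applied by
    overlap/follow-up logic, not stored here.

    Returns
    -------
    DataFrame with ``person_id``, ``ingredient``, ``start_date``, ``end_date``,
    ``n_dispensings``.
    """
    cols = ["person_id", "ingredient", "start_date", "end_date", "n_dispensings"]
    if dispensings.empty:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if "date" in c else object)
                             for c in cols})
    d = dispensings.sort_values(["person_id", "ingredient", "dispense_date"]).copy()
    d["fill_end"] = d["dispense_date"] + pd.to_timedelta(d["days_supply"] - 1, unit="D")
    grp = d.groupby(["person_id", "ingredient"], sort=False)
    d["cum_end"] = grp["fill_end"].cummax()
    prev_end = grp["cum_end"].shift()
    gap_limit = pd.Timedelta(days=grace_days + 1)
    new_era = prev_end.isna() | (d["dispense_date"] - prev_end > gap_limit)
    d["era_id"] = new_era.cumsum()
    eras = d.groupby(["person_id", "ingredient", "era_id"], sort=False).agg(
        start_date=("dispense_date", "min"),
        end_date=("fill_end", "max"),
        n_dispensings=("dispense_date", "size"),
    ).reset_index().drop(columns="era_id")
    return eras.sort_values(["person_id", "ingredient", "start_date"]).reset_index(drop=True)


def classify_trigger(clop_era_start, nsaid_era_start) -> str:
    """Which drug's initiation created the concomitancy.

    ``nsaid_triggered`` when the clopidogrel era started strictly earlier
    (the NSAID was added to ongoing clopidogrel); ``clopidogrel_triggered``
    when the NSAID era started strictly earlier; ``combination_triggered``
    when both started on the entry day.
    """
    if clop_era_start < nsaid_era_start:
        return "nsaid_triggered"
    if nsaid_era_start < clop_era_start:
        return "clopidogrel_triggered"
    return "combination_triggered"


def _merged_enrollment(enrollment: pd.DataFrame, max_gap_days: int) -> pd.DataFrame:
    """Enrollment spans with gaps <= max_gap_days bridged, per person."""
    e = enrollment.sort_values(["person_id", "start_date"]).copy()
    grp = e.groupby("person_id", sort=False)
    e["cum_end"] = grp["end_date"].cummax()
    prev_end = grp["cum_end"].shift()
    new_span = prev_end.isna() | (e["start_date"] - prev_end > pd.Timedelta(days=max_gap_days + 1))
    e["span_id"] = new_span.cumsum()
    return e.groupby(["person_id", "span_id"], sort=False).agg(
        start_date=("start_date", "min"), end_date=("end_date", "max")
    ).reset_index().drop(columns="span_id")


def find_cohort_entry(
    eras: pd.DataFrame,
    enrollment: pd.DataFrame,
    persons: pd.DataFrame,
    dataset_end,
    grace_days: int = 15,
    baseline_days: int = 365,
    max_gap_days: int = 0,
    washout_days: int | None = None,
    min_age: int = 18,
    max_age: int = 100,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Identify apparently-new concomitant users and their entry records.

    Entry is the earliest day on which a clopidogrel era and a study-NSAID
    era overlap (both grace-extended).  Candidates are then dropped, in order,
    when: entry falls after ``dataset_end``; age at entry is outside
    ``[min_age, max_age]``; the year (``baseline_days``) before entry is not
    continuously covered by enrollment through the entry day; or more than
    one study NSAID's grace-extended era covers the entry day.  With
    ``washout_days`` set, a person is "new" when no overlap occurred in the
    ``washout_days`` before entry rather than in all lookback.

    Returns
    -------
    (cohort, attrition)
        ``cohort`` has one row per entering person (entry date, exposure
        NSAID, trigger, era bounds, baseline window, age); ``attrition``
        counts persons surviving each step.
    """
    dataset_end = pd.Timestamp(dataset_end)
    grace = pd.Timedelta(days=grace_days)
    attrition: dict[str, int] = {"persons": persons["person_id"].nunique()}

    clop = eras[eras["ingredient"] == CLOPIDOGREL]
    nsaid = eras[eras["ingredient"].isin(STUDY_NSAIDS)]
    pairs = clop.merge(nsaid, on="person_id", suffixes=("_clop", "_nsaid"))
    if not pairs.empty:
        ov_start = pairs[["start_date_clop", "start_date_nsaid"]].max(axis=1)
        ov_end = np.minimum(pairs["end_date_clop"] + grace, pairs["end_date_nsaid"] + grace)
        pairs = pairs.assign(overlap_start=ov_start, overlap_end=ov_end)[ov_start <= ov_end]
    attrition["with_concomitant_overlap"] = pairs["person_id"].nunique() if len(pairs) else 0
    if pairs.empty:
        return pd.DataFrame(), attrition

    entry = pairs.groupby("person_id")["overlap_start"].min().rename("entry_date")
    if washout_days is not None:
        # "new" relative to a washout: first overlap with no overlap coverage
        # in the preceding washout_days
        ordered = pairs.sort_values(["person_id", "overlap_start"]).copy()
        ordered["cum_end"] = ordered.groupby("person_id", sort=False)["overlap_end"].cummax()
        prev_end = ordered.groupby("person_id", sort=False)["cum_end"].shift()
        fresh = prev_end.isna() | (
            ordered["overlap_start"] - prev_end > pd.Timedelta(days=washout_days)
        )
        entry = (
            ordered[fresh.to_numpy()].groupby("person_id")["overlap_start"].min().rename("entry_date")
        )

    cand = entry.reset_index()
    cand = cand[cand["entry_date"] <= dataset_end]
    attrition["entry_within_dataset"] = len(cand)

    pdx = persons.set_index("person_id")
    cand["birth_date"] = cand["person_id"].map(pdx["birth_date"])
    cand["age_at_entry"] = (
        (cand["entry_date"] - cand["birth_date"]).dt.days / 365.25
    ).astype(int)
    cand = cand[(cand["age_at_entry"] >= min_age) & (cand["age_at_entry"] <= max_age)]
    attrition["age_18_100"] = len(cand)

    spans = _merged_enrollment(enrollment, max_gap_days)
    chk = cand.merge(spans, on="person_id", how="left")
    base_start = chk["entry_date"] - pd.Timedelta(days=baseline_days)
    covered = (chk["start_date"] <= base_start) & (chk["end_date"] >= chk["entry_date"])
    ok = chk[covered]["person_id"].unique()
    cand = cand[cand["person_id"].isin(set(ok))]
    attrition["baseline_enrollment"] = len(cand)

    # study-NSAID eras whose grace-extended coverage includes the entry day
    at_entry = cand.merge(nsaid, on="person_id")
    at_entry = at_entry[
        (at_entry["start_date"] <= at_entry["entry_date"])
        & (at_entry["end_date"] + grace >= at_entry["entry_date"])
    ]
    n_ing = at_entry.groupby("person_id")["ingredient"].nunique()
    single = set(n_ing[n_ing == 1].index)
    cand = cand[cand["person_id"].isin(single)]
    attrition["single_nsaid_at_entry"] = len(cand)
    if cand.empty:
        return pd.DataFrame(), attrition

    # the exposure-defining era: earliest-starting study-NSAID era covering entry
    nsaid_era = (
        at_entry[at_entry["person_id"].isin(set(cand["person_id"]))]
        .sort_values(["person_id", "start_date"])
        .groupby("person_id")
        .first()[["ingredient", "start_date", "end_date"]]
        .rename(columns={"ingredient": "exposure_nsaid",
                         "start_date": "nsaid_era_start", "end_date": "nsaid_era_end"})
    )
    clop_at = cand.merge(clop, on="person_id")
    clop_at = clop_at[
        (clop_at["start_date"] <= clop_at["entry_date"])
        & (clop_at["end_date"] + grace >= clop_at["entry_date"])
    ]
    clop_era = (
        clop_at.sort_values(["person_id", "start_date"])
        .groupby("person_id")
        .first()[["start_date", "end_date"]]
        .rename(columns={"start_date": "clop_era_start", "end_date": "clop_era_end"})
    )

    cohort = cand.set_index("person_id").join(nsaid_era).join(clop_era).reset_index()
    cohort["trigger"] = np.select(
        [
            cohort["clop_era_start"] < cohort["nsaid_era_start"],
            cohort["nsaid_era_start"] < cohort["clop_era_start"],
        ],
        ["nsaid_triggered", "clopidogrel_triggered"],
        default="combination_triggered",
    )
    cohort["baseline_start"] = cohort["entry_date"] - pd.Timedelta(days=baseline_days)
    cohort["baseline_end"] = cohort["entry_date"] - DAY
    cohort = cohort.drop(columns=["birth_date"])
    return cohort.reset_index(drop=True), attrition


def compute_follow_up(
    cohort: pd.DataFrame,
    dispensings: pd.DataFrame,
    enrollment: pd.DataFrame,
    outcome_events: pd.DataFrame,
    dataset_end,
    grace_days: int = 15,
    max_gap_days: int = 0,
    censor_at_day: int | None = None,
) -> pd.DataFrame:
    """Per-subject follow-up end and reason for one outcome.

    The end date is the minimum of: the first outcome date on/after entry;
    the last covered day of clopidogrel or the exposure NSAID plus the grace
    period; the day before the first dispensing of a non-exposure study NSAID
    after entry; the end of the enrollment span containing entry; the dataset
    end; and ``entry + censor_at_day`` when set.  The outcome wins ties
    (the event is counted); other ties resolve in :data:`END_REASONS` order.

    Returns the cohort frame with ``end_date``, ``end_reason``, ``event``,
    ``futime_days`` (closed-interval day count, entry day = 1) appended.
    """
    out = cohort.copy()
    dataset_end = pd.Timestamp(dataset_end)
    grace = pd.Timedelta(days=grace_days)

    ev = outcome_events.rename(columns={"date": "t_outcome"})[["person_id", "t_outcome"]]
    out = out.merge(ev, on="person_id", how="left")
    out.loc[out["t_outcome"] < out["entry_date"], "t_outcome"] = pd.NaT

    out["t_supply"] = np.minimum(out["clop_era_end"], out["nsaid_era_end"]) + grace

    sw = dispensings[dispensings["ingredient"].isin(STUDY_NSAIDS)][
        ["person_id", "ingredient", "dispense_date"]
    ].merge(out[["person_id", "exposure_nsaid", "entry_date"]], on="person_id")
    sw = sw[(sw["ingredient"] != sw["exposure_nsaid"]) & (sw["dispense_date"] > sw["entry_date"])]
    first_sw = sw.groupby("person_id")["dispense_date"].min() - DAY
    out["t_switch"] = pd.to_datetime(out["person_id"].map(first_sw))

    spans = _merged_enrollment(enrollment, max_gap_days)
    sp = out[["person_id", "entry_date"]].merge(spans, on="person_id")
    sp = sp[(sp["start_date"] <= sp["entry_date"]) & (sp["end_date"] >= sp["entry_date"])]
    out["t_disenroll"] = pd.to_datetime(out["person_id"].map(sp.groupby("person_id")["end_date"].min()))

    out["t_dataset"] = dataset_end
    out["t_censor"] = (
        out["entry_date"] + pd.Timedelta(days=censor_at_day) if censor_at_day is not None else pd.NaT
    )

    candidates = {
        "outcome": out["t_outcome"],
        "supply_end": out["t_supply"],
        "nsaid_switch": out["t_switch"],
        "disenrollment": out["t_disenroll"],
        "dataset_end": out["t_dataset"],
        "day_censor": out["t_censor"],
    }
    stacked = pd.concat(candidates, axis=1)
    end = stacked.min(axis=1)
    # reason: first column (in END_REASONS priority order) attaining the minimum
    reason = pd.Series("dataset_end", index=out.index, dtype=object)
    for name in reversed(END_REASONS):
        hit = stacked[name].notna() & (stacked[name] == end)
        reason[hit] = name

    out["end_date"] = end
    out["end_reason"] = reason
    out["event"] = (reason == "outcome").to_numpy()
    out["futime_days"] = (out["end_date"] - out["entry_date"]).dt.days + 1
    return out.drop(columns=["t_outcome", "t_supply", "t_switch", "t_disenroll",
                             "t_dataset", "t_censor"])
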