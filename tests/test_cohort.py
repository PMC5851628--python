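"""Drug eras, cohort entry, trigger classification and follow-up censoring."""

import numpy as np
import pandas as pd
import pytest

from clopnsaid.cohort import (
    build_drug_eras,
    classify_trigger,
    compute_follow_up,
    find_cohort_entry,
)
from clopnsaid.data_model import make_bundle

BASE = pd.Timestamp("2005-01-01")


def day(d: int) -> pd.Timestamp:
    return BASE + pd.Timedelta(days=int(d))


def _disp(fills, pid="A", ing="ibuprofen"):
    return pd.DataFrame([
        dict(person_id=pid, ingredient=ing, dispense_date=day(d), days_supply=s)
        for d, s in fills
    ])


def _era_days_oracle(fills, grace):
    """Brute force: mark covered days, then merge runs separated by <= grace
    uncovered days; era end is the last covered day of its run."""
    covered = set()
    for d, s in fills:
        covered.update(range(d, d + s))
    if not covered:
        return []
    days = sorted(covered)
    eras = [[days[0], days[0]]]
    for d in days[1:]:
        if d - eras[-1][1] - 1 <= grace:
            eras[-1][1] = d
        else:
            eras.append([d, d])
    return [tuple(e) for e in eras]


class TestDrugEras:
    def test_gap_within_grace_merges(self):
        eras = build_drug_eras(_disp([(0, 30), (40, 30)]), grace_days=15)
        assert len(eras) == 1
        assert eras["start_date"].iloc[0] == day(0)
        assert eras["end_date"].iloc[0] == day(69)

    def test_gap_beyond_grace_splits(self):
        eras = build_drug_eras(_disp([(0, 30), (46, 30)]), grace_days=15)
        assert len(eras) == 2
        assert list(eras["end_date"]) == [day(29), day(75)]

    def test_single_fill(self):
        eras = build_drug_eras(_disp([(0, 30)]))
        assert len(eras) == 1
        assert eras["end_date"].iloc[0] == day(29)

    def test_stockpiling_extends_coverage(self):
        # early refill: coverage extends past the naive end of the second fill
        eras = build_drug_eras(_disp([(0, 60), (10, 10)]))
        assert len(eras) == 1
        assert eras["end_date"].iloc[0] == day(59)

    def test_matches_day_set_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 7))
            fills = [(int(rng.integers(0, 120)), int(rng.integers(1, 45))) for _ in range(n)]
            grace = int(rng.integers(0, 25))
            eras = build_drug_eras(_disp(fills), grace_days=grace)
            got = [((e - BASE).days, (f - BASE).days)
                   for e, f in zip(eras["start_date"], eras["end_date"])]
            assert got == _era_days_oracle(fills, grace)


def _entry_bundle(disp_rows, enr=None, birth="1940-01-01"):
    persons = [dict(person_id="A", birth_date=pd.Timestamp(birth), sex="female",
                    race_ethnicity="white", state="PA")]
    enr = enr or [dict(person_id="A", start_date=day(-800), end_date=day(900))]
    return make_bundle(persons, enr, disp_rows)


class TestCohortEntry:
    def test_entry_at_first_overlap_day(self):
        disp = pd.concat([
            _disp([(0, 90)], ing="clopidogrel"),
            _disp([(30, 30)], ing="ibuprofen"),
        ])
        b = _entry_bundle(disp)
        eras = build_drug_eras(b.dispensings)
        cohort, _ = find_cohort_entry(eras, b.enrollment, b.persons, day(700))
        assert len(cohort) == 1
        assert cohort["entry_date"].iloc[0] == day(30)
        assert cohort["exposure_nsaid"].iloc[0] == "ibuprofen"
        assert cohort["trigger"].iloc[0] == "nsaid_triggered"

    def test_grace_tail_extends_overlap_detection(self):
        # clopidogrel covered through day 29; NSAID starts day 40 (<= 29+15)
        disp = pd.concat([
            _disp([(0, 30)], ing="clopidogrel"),
            _disp([(40, 30)], ing="naproxen"),
        ])
        b = _entry_bundle(disp)
        eras = build_drug_eras(b.dispensings)
        cohort, _ = find_cohort_entry(eras, b.enrollment, b.persons, day(700))
        assert len(cohort) == 1
        assert cohort["entry_date"].iloc[0] == day(40)

    def test_prior_concomitancy_without_baseline_excludes_person(self):
        # first overlap at day 10 but enrollment starts day -100: baseline
        # fails at the true first concomitancy, and the person never enters
        disp = pd.concat([
            _disp([(10, 30), (200, 90)], ing="clopidogrel"),
            _disp([(10, 30), (210, 30)], ing="naproxen"),
        ])
        b = _entry_bundle(disp, enr=[dict(person_id="A", start_date=day(-100),
                                          end_date=day(900))])
        eras = build_drug_eras(b.dispensings)
        cohort, att = find_cohort_entry(eras, b.enrollment, b.persons, day(700))
        assert cohort.empty
        assert att["baseline_enrollment"] == 0

    def test_two_nsaids_covering_entry_day_excludes_person(self):
        disp = pd.concat([
            _disp([(0, 90)], ing="clopidogrel"),
            _disp([(30, 30)], ing="ibuprofen"),
            _disp([(30, 30)], ing="naproxen"),
        ])
        b = _entry_bundle(disp)
        eras = build_drug_eras(b.dispensings)
        cohort, att = find_cohort_entry(eras, b.enrollment, b.persons, day(700))
        assert cohort.empty
        assert att["single_nsaid_at_entry"] == 0

    def test_age_limits_exclude(self):
        disp = pd.concat([
            _disp([(0, 90)], ing="clopidogrel"),
            _disp([(30, 30)], ing="ibuprofen"),
        ])
        b = _entry_bundle(disp, birth="1990-01-01")  # age ~15 at entry
        eras = build_drug_eras(b.dispensings)
        cohort, att = find_cohort_entry(eras, b.enrollment, b.persons, day(700))
        assert cohort.empty
        assert att["age_18_100"] == 0


@pytest.mark.parametrize(
    "clop_start,nsaid_start,expected",
    [
        (0, 30, "nsaid_triggered"),
        (30, 0, "clopidogrel_triggered"),
        (30, 30, "combination_triggered"),
    ],
)
def test_trigger_classification(clop_start, nsaid_start, expected):
    assert classify_trigger(day(clop_start), day(nsaid_start)) == expected


def _cohort_row(entry=30, clop_end=120, nsaid_end=100, exposure="ibuprofen"):
    return pd.DataFrame([{
        "person_id": "A", "entry_date": day(entry),
        "exposure_nsaid": exposure, "trigger": "nsaid_triggered",
        "clop_era_start": day(0), "clop_era_end": day(clop_end),
        "nsaid_era_start": day(entry), "nsaid_era_end": day(nsaid_end),
        "age_at_entry": 65,
        "baseline_start": day(entry - 365), "baseline_end": day(entry - 1),
    }])


def _enr(end=900):
    return pd.DataFrame([dict(person_id="A", start_date=day(-800),
                              end_date=day(end), managed_care=0)])


EMPTY_EVENTS = pd.DataFrame({"person_id": [], "date": pd.to_datetime([])})
EMPTY_DISP = pd.DataFrame({"person_id": pd.Series(dtype=str),
                           "ingredient": pd.Series(dtype=str),
                           "dispense_date": pd.Series(dtype="datetime64[ns]"),
                           "days_supply": pd.Series(dtype=int)})


class TestFollowUp:
    def test_switch_censors_day_before_dispensing(self):
        other = _disp([(50, 30)], ing="naproxen")
        fu = compute_follow_up(_cohort_row(), other, _enr(), EMPTY_EVENTS, day(700))
        assert fu["end_date"].iloc[0] == day(49)
        assert fu["end_reason"].iloc[0] == "nsaid_switch"

    def test_supply_end_includes_grace(self):
        fu = compute_follow_up(_cohort_row(clop_end=120, nsaid_end=100),
                               EMPTY_DISP, _enr(),
                               EMPTY_EVENTS, day(700))
        assert fu["end_date"].iloc[0] == day(115)  # min(120,100) + 15
        assert fu["end_reason"].iloc[0] == "supply_end"

    def test_dataset_end_binds_when_supplies_run_long(self):
        fu = compute_follow_up(_cohort_row(clop_end=900, nsaid_end=900),
                               EMPTY_DISP, _enr(2000),
                               EMPTY_EVENTS, day(60))
        assert fu["end_date"].iloc[0] == day(60)
        assert fu["end_reason"].iloc[0] == "dataset_end"

    def test_fixed_day_censor(self):
        fu = compute_follow_up(_cohort_row(clop_end=900, nsaid_end=900),
                               EMPTY_DISP, _enr(2000),
                               EMPTY_EVENTS, day(999), censor_at_day=180)
        assert fu["end_date"].iloc[0] == day(30 + 180)
        assert fu["end_reason"].iloc[0] == "day_censor"

    def test_outcome_wins_ties(self):
        ev = pd.DataFrame({"person_id": ["A"], "date": [day(115)]})
        fu = compute_follow_up(_cohort_row(), EMPTY_DISP,
                               _enr(), ev, day(700))
        assert fu["end_reason"].iloc[0] == "outcome"
        assert bool(fu["event"].iloc[0])
        assert fu["futime_days"].iloc[0] == 115 - 30 + 1

    def test_event_before_entry_does_not_count(self):
        ev = pd.DataFrame({"person_id": ["A"], "date": [day(10)]})
        fu = compute_follow_up(_cohort_row(), EMPTY_DISP,
                               _enr(), ev, day(700))
        assert fu["end_reason"].iloc[0] == "supply_end"
        assert not bool(fu["event"].iloc[0])


def followup_day_scan_oracle(entry, clop_end, nsaid_end, switch_days, enr_end,
                             dataset_end, outcome_day, censor_at, grace=15):
    """Walk forward from entry one day at a time; first binding rule wins,
    outcome beating censoring on ties."""
    d = entry
    while True:
        if outcome_day is not None and d == outcome_day:
            return d, "outcome"
        stops = []
        if d == min(clop_end, nsaid_end) + grace:
            stops.append("supply_end")
        if (d + 1) in switch_days:
            stops.append("nsaid_switch")
        if d == enr_end:
            stops.append("disenrollment")
        if d == dataset_end:
            stops.append("dataset_end")
        if censor_at is not None and d == entry + censor_at:
            stops.append("day_censor")
        if stops:
            order = ["supply_end", "nsaid_switch", "disenrollment",
                     "dataset_end", "day_censor"]
            return d, sorted(stops, key=order.index)[0]
        d += 1


def test_follow_up_matches_day_scan_oracle_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(300):
        entry = int(rng.integers(0, 30))
        clop_end = entry + int(rng.integers(0, 120))
        nsaid_end = entry + int(rng.integers(0, 120))
        enr_end = entry + int(rng.integers(0, 250))
        dataset_end = entry + int(rng.integers(0, 250))
        outcome_day = entry + int(rng.integers(0, 150)) if rng.random() < 0.5 else None
        switch_day = entry + int(rng.integers(1, 150)) if rng.random() < 0.5 else None
        censor_at = int(rng.integers(1, 200)) if rng.random() < 0.3 else None

        cohort = _cohort_row(entry=entry, clop_end=clop_end, nsaid_end=nsaid_end)
        other = (_disp([(switch_day, 30)], ing="naproxen") if switch_day is not None
                 else EMPTY_DISP)
        ev = (pd.DataFrame({"person_id": ["A"], "date": [day(outcome_day)]})
              if outcome_day is not None else EMPTY_EVENTS)
        fu = compute_follow_up(cohort, other, _enr(enr_end), ev, day(dataset_end),
                               censor_at_day=censor_at)
        exp_day, exp_reason = followup_day_scan_oracle(
            entry, clop_end, nsaid_end,
            {switch_day} if switch_day is not None else set(),
            enr_end, dataset_end, outcome_day, censor_at,
        )
        got_day = (fu["end_date"].iloc[0] - BASE).days
        assert (got_day, fu["end_reason"].iloc[0]) == (exp_day, exp_reason)
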