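"""Prespecified covariate measurement and hdPS candidate generation/selection."""

import numpy as np
import pandas as pd
import pytest

from clopnsaid.cohort import build_drug_eras, find_cohort_entry
from clopnsaid.covariates import (
    HdpsCandidates,
    bross_bias_score,
    build_prespecified,
    enumerate_candidates,
    hdps_accounting,
    hdps_select,
    merge_and_filter,
    rank_and_select,
)
from clopnsaid.data_model import make_bundle


def D(s):
    return pd.Timestamp(s)


@pytest.fixture
def small_cohorted_bundle():
    """Two cohort subjects with controlled baseline claims."""
    persons = [
        dict(person_id=p, birth_date=D("1940-01-01"), sex=s, race_ethnicity="white", state="PA")
        for p, s in [("A", "female"), ("B", "male")]
    ]
    enrollment = [dict(person_id=p, start_date=D("2003-01-01"), end_date=D("2008-12-31"))
                  for p in ("A", "B")]
    disp = [
        dict(person_id="A", ingredient="clopidogrel", dispense_date=D("2005-06-01"), days_supply=30),
        dict(person_id="A", ingredient="ibuprofen", dispense_date=D("2005-06-01"), days_supply=30),
        dict(person_id="B", ingredient="clopidogrel", dispense_date=D("2005-06-01"), days_supply=30),
        dict(person_id="B", ingredient="celecoxib", dispense_date=D("2005-06-01"), days_supply=30),
        # baseline statin for A only
        dict(person_id="A", ingredient="simvastatin", dispense_date=D("2005-01-10"), days_supply=30),
    ]
    claims = [
        # A: hypertension inside baseline
        dict(person_id="A", claim_id="c1", setting="outpatient",
             admission_date=D("2005-03-01"), discharge_date=D("2005-03-01"),
             code="4019", code_type="icd9_dx", position="principal"),
        # B: hypertension claim dated ON the entry day -> must not count
        dict(person_id="B", claim_id="c2", setting="outpatient",
             admission_date=D("2005-06-01"), discharge_date=D("2005-06-01"),
             code="4019", code_type="icd9_dx", position="principal"),
        # shared baseline code for candidate enumeration
        dict(person_id="A", claim_id="c3", setting="outpatient",
             admission_date=D("2005-02-01"), discharge_date=D("2005-02-01"),
             code="7245", code_type="icd9_dx", position="principal"),
        dict(person_id="B", claim_id="c4", setting="outpatient",
             admission_date=D("2005-02-01"), discharge_date=D("2005-02-01"),
             code="7245", code_type="icd9_dx", position="principal"),
        dict(person_id="B", claim_id="c5", setting="outpatient",
             admission_date=D("2005-02-02"), discharge_date=D("2005-02-02"),
             code="4659", code_type="icd9_dx", position="principal"),
    ]
    bundle = make_bundle(persons, enrollment, disp, claims)
    eras = build_drug_eras(bundle.dispensings)
    cohort, _ = find_cohort_entry(eras, bundle.enrollment, bundle.persons, D("2008-12-31"))
    assert len(cohort) == 2
    return bundle, cohort


class TestPrespecified:
    def test_flags_measured_in_baseline_only(self, small_cohorted_bundle):
        bundle, cohort = small_cohorted_bundle
        m = build_prespecified(bundle, cohort)
        assert m.loc["A", "hypertension"] == 1.0
        assert m.loc["B", "hypertension"] == 0.0  # entry-day claim excluded
        assert m.loc["A", "statin"] == 1.0
        assert m.loc["B", "statin"] == 0.0

    def test_age_populated_even_with_empty_baseline(self, small_cohorted_bundle):
        bundle, cohort = small_cohorted_bundle
        m = build_prespecified(bundle, cohort)
        assert (m["age"] > 60).all()
        assert m.loc["B", "female"] == 0.0


class TestEnumerateCandidates:
    def test_counts_match_manual_tally(self, small_cohorted_bundle):
        bundle, cohort = small_cohorted_bundle
        cand = enumerate_candidates(bundle, cohort, top_k=200)
        outp = cand.table[cand.table["dimension"] == "outpatient_dx"].set_index("code")
        assert outp.loc["7245", "n_persons"] == 2
        assert outp.loc["4659", "n_persons"] == 1
        assert outp.loc["4019", "n_persons"] == 1  # B's entry-day claim not baseline
        assert cand.flags.loc["A", "outpatient_dx:7245"] == 1

    def test_top_k_truncates_with_lexicographic_ties(self):
        subjects = [f"P{i}" for i in range(4)]
        persons = [dict(person_id=p, birth_date=D("1940-01-01"), sex="male",
                        race_ethnicity="white", state="PA") for p in subjects]
        enrollment = [dict(person_id=p, start_date=D("2003-01-01"), end_date=D("2008-12-31"))
                      for p in subjects]
        disp = []
        for p in subjects:
            disp += [dict(person_id=p, ingredient="clopidogrel",
                          dispense_date=D("2005-06-01"), days_supply=30),
                     dict(person_id=p, ingredient="ibuprofen",
                          dispense_date=D("2005-06-01"), days_supply=30)]
        claims = []
        for i, code in enumerate(["111", "222", "333"]):  # all prevalence 1
            for p in subjects:
                claims.append(dict(person_id=p, claim_id=f"{code}{p}", setting="outpatient",
                                   admission_date=D("2005-02-01"), discharge_date=D("2005-02-01"),
                                   code=code, code_type="icd9_dx", position="principal"))
        bundle = make_bundle(persons, enrollment, disp, claims)
        eras = build_drug_eras(bundle.dispensings)
        cohort, _ = find_cohort_entry(eras, bundle.enrollment, bundle.persons, D("2008-12-31"))
        cand = enumerate_candidates(bundle, cohort, top_k=2)
        codes = list(cand.table[cand.table["dimension"] == "outpatient_dx"]["code"])
        assert codes == ["111", "222"]  # tie broken lexicographically


class TestBrossRanking:
    def test_worked_bias_score(self):
        # PC1=0.2, PC0=0.1, RR=2 -> BiasM = 1.2/1.1, |log| ~ 0.0870
        score = bross_bias_score(np.array([0.2]), np.array([0.1]), np.array([2.0]))[0]
        assert score == pytest.approx(np.log(1.2 / 1.1))
        assert round(score, 4) == 0.0870

    def test_no_outcome_association_scores_zero(self):
        assert bross_bias_score(np.array([0.4]), np.array([0.1]), np.array([1.0]))[0] == 0.0

    def test_equal_prevalence_scores_zero(self):
        assert bross_bias_score(np.array([0.3]), np.array([0.3]), np.array([3.0]))[0] == 0.0

    def test_protective_covariates_rank_by_folded_rr(self):
        s_protect = bross_bias_score(np.array([0.2]), np.array([0.1]), np.array([0.5]))[0]
        s_harm = bross_bias_score(np.array([0.2]), np.array([0.1]), np.array([2.0]))[0]
        assert s_protect == pytest.approx(s_harm)


def _toy_candidates(n=40, m=6, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"outpatient_dx:{100 + j}" for j in range(m)]
    flags = pd.DataFrame(rng.integers(0, 2, (n, m)), columns=cols,
                         index=pd.Index([f"P{i}" for i in range(n)], name="person_id"))
    table = pd.DataFrame({
        "dimension": "outpatient_dx",
        "code": [str(100 + j) for j in range(m)],
        "column": cols,
        "n_persons": flags.sum(axis=0).to_numpy(),
    })
    return HdpsCandidates(table=table, flags=flags)


class TestRankAndSelect:
    def test_empty_arm_raises(self):
        cand = _toy_candidates()
        exposure = pd.Series(["ibuprofen"] * 40, index=cand.flags.index)
        y = pd.Series(False, index=cand.flags.index)
        with pytest.raises(ValueError, match="zero subjects"):
            rank_and_select(cand, exposure, "naproxen", y)

    def test_selection_stable_under_row_permutation(self):
        cand = _toy_candidates()
        rng = np.random.default_rng(3)
        exposure = pd.Series(rng.choice(["ibuprofen", "naproxen"], 40), index=cand.flags.index)
        y = pd.Series(rng.random(40) < 0.3, index=cand.flags.index)
        sel1 = rank_and_select(cand, exposure, "naproxen", y, top_n=3)
        perm = rng.permutation(40)
        cand2 = HdpsCandidates(table=cand.table, flags=cand.flags.iloc[perm])
        sel2 = rank_and_select(cand2, exposure.iloc[perm], "naproxen", y.iloc[perm], top_n=3)
        assert list(sel1["column"]) == list(sel2["column"])


class TestMergeAndFilter:
    def test_identical_selections_deduplicate_to_one_set(self):
        cand = _toy_candidates()
        sel = cand.table.head(5)
        cols, acct = merge_and_filter({d: sel for d in ("a", "b", "c")}, cand,
                                      min_exposed=0)
        assert len(cols) == 5
        assert acct["pooled"] == 15
        assert acct["duplicates"] == 10
        assert acct["retained"] == 5

    def test_disjoint_selections_concatenate(self):
        cand = _toy_candidates()
        s1, s2 = cand.table.iloc[:3], cand.table.iloc[3:6]
        cols, acct = merge_and_filter({"a": s1, "b": s2}, cand, min_exposed=0)
        assert len(cols) == 6
        assert acct["duplicates"] == 0

    def test_threshold_and_overlap_filters_are_counted(self):
        cand = _toy_candidates()
        # make one column rare and one column collide with a prespecified code
        cand.flags.iloc[:, 0] = 0
        cand.flags.iloc[0, 0] = 1
        cand.table.loc[cand.table.index[-1], "code"] = "4019"
        sel = cand.table
        cols, acct = merge_and_filter({"a": sel}, cand,
                                      prespecified_codes={"4019"}, min_exposed=5)
        assert acct["under_threshold"] == 1
        assert acct["prespecified_overlap"] == 1
        assert acct["retained"] == len(cols)

    def test_accounting_identity_holds_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p, d, u, o = (int(rng.integers(0, 5000)) for _ in range(4))
            acct = hdps_accounting(p, d, u, o)
            assert acct["retained"] == acct["pooled"] - acct["duplicates"] \
                - acct["under_threshold"] - acct["prespecified_overlap"]


def test_hdps_select_end_to_end(sim_bundle_small):
    from clopnsaid.cohort import build_drug_eras, compute_follow_up, find_cohort_entry
    from clopnsaid.pipeline import post_entry_events

    b = sim_bundle_small
    eras = build_drug_eras(b.dispensings)
    cohort, _ = find_cohort_entry(eras, b.enrollment, b.persons, "2010-12-31")
    ev = post_entry_events(b, cohort)
    fu = compute_follow_up(cohort, b.dispensings, b.enrollment, ev["mortality"], "2010-12-31")
    exposure = pd.Series(cohort["exposure_nsaid"].to_numpy(),
                         index=pd.Index(cohort["person_id"], name="person_id"))
    event = pd.Series(fu["event"].to_numpy(), index=exposure.index)
    cols, acct = hdps_select(b, cohort, exposure, event, top_k=50, top_n=10, min_exposed=5)
    assert acct["retained"] == cols.shape[1]
    assert acct["retained"] == acct["pooled"] - acct["duplicates"] \
        - acct["under_threshold"] - acct["prespecified_overlap"]
    assert (cols.sum(axis=0) >= 5).all()
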