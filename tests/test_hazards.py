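"""Incidence rates, Cox fits, proportionality diagnostics, analysis variants."""

import numpy as np
import pandas as pd
import pytest

from clopnsaid.datasets import reference_incidence_table
from clopnsaid.hazards import (
    fit_adjusted,
    fit_unadjusted,
    incidence_rate,
    incidence_table,
    person_time_table,
    ph_check,
    run_analyses,
)


class TestIncidenceRate:
    @pytest.mark.parametrize("events,py,printed", [
        (2463, 48483, 50.8),   # overall mortality
        (108, 829, 130.3),     # indomethacin bleeding row
        (414, 8667, 47.8),     # referent-arm mortality
    ])
    def test_published_cells_reproduce_to_one_decimal(self, events, py, printed):
        rate, _, _ = incidence_rate(events, py)
        assert round(rate, 1) == printed

    def test_zero_events_rate_zero_with_positive_upper_bound(self):
        rate, lo, hi = incidence_rate(0, 100.0)
        assert rate == 0.0 and lo == 0.0 and hi > 0.0

    def test_ci_contains_point_estimate(self):
        rate, lo, hi = incidence_rate(57, 834)
        assert lo < rate < hi

    def test_nonpositive_person_years_raises(self):
        with pytest.raises(ValueError):
            incidence_rate(5, 0.0)


def _synthetic_pt(seed=0, n=4000, hr_map=None, arms=("ibuprofen", "naproxen", "celecoxib"),
                  censor_at=120.0):
    """Exponential survival data with known hazard ratios, integer-day times."""
    rng = np.random.default_rng(seed)
    hr_map = hr_map or {}
    exposure = rng.choice(arms, n)
    rate = 0.01 * np.array([hr_map.get(a, 1.0) for a in exposure])
    t = rng.exponential(1 / rate)
    event = t <= censor_at
    futime = np.minimum(np.ceil(t), censor_at).astype(int) + 1
    return pd.DataFrame({
        "person_id": [f"P{i}" for i in range(n)],
        "exposure_nsaid": exposure,
        "futime_days": futime,
        "event": event,
        "person_years": futime / 365.25,
    })


class TestUnadjustedCox:
    def test_null_data_give_hr_near_one(self):
        pt = _synthetic_pt(seed=1)
        res = fit_unadjusted(pt)
        for _, r in res.hr.iterrows():
            assert abs(r["coef"]) < 3 * r["se"]

    def test_planted_hr_recovered_within_three_se(self):
        pt = _synthetic_pt(seed=2, n=8000, hr_map={"celecoxib": 2.0})
        res = fit_unadjusted(pt)
        row = res.hr.loc["celecoxib"]
        assert abs(row["coef"] - np.log(2.0)) < 3 * row["se"]

    def test_relabelling_comparators_permutes_hrs(self):
        pt = _synthetic_pt(seed=3, hr_map={"naproxen": 1.5})
        res1 = fit_unadjusted(pt)
        swapped = pt.copy()
        swapped["exposure_nsaid"] = swapped["exposure_nsaid"].map(
            {"ibuprofen": "ibuprofen", "naproxen": "celecoxib", "celecoxib": "naproxen"}
        )
        res2 = fit_unadjusted(swapped)
        assert res1.hr.loc["naproxen", "hr"] == pytest.approx(
            res2.hr.loc["celecoxib", "hr"], rel=1e-9
        )

    def test_empty_referent_raises(self):
        pt = _synthetic_pt(seed=4, arms=("naproxen", "celecoxib"))
        with pytest.raises(ValueError, match="referent"):
            fit_unadjusted(pt)

    def test_agrees_with_independent_partial_likelihood_fit(self):
        """Dual route: the lifelines-based fit matches statsmodels PHReg
        (Efron ties) on the same data."""
        import statsmodels.api as sm

        pt = _synthetic_pt(seed=5, n=3000, hr_map={"celecoxib": 1.6})
        res = fit_unadjusted(pt)
        d = pd.get_dummies(pt["exposure_nsaid"]).drop(columns="ibuprofen").astype(float)
        phreg = sm.PHReg(pt["futime_days"], d, status=pt["event"].astype(int), ties="efron")
        fit = phreg.fit()
        for j, name in enumerate(d.columns):
            assert res.hr.loc[name, "coef"] == pytest.approx(fit.params[j], abs=1e-4)


def _uniform_ps(pt, arms):
    probs = pd.DataFrame(1.0 / len(arms), index=pd.Index(pt["person_id"], name="person_id"),
                         columns=list(arms))
    return probs


class TestAdjustedCox:
    def test_null_ps_leaves_estimates_near_unadjusted(self):
        pt = _synthetic_pt(seed=6, n=6000, hr_map={"celecoxib": 2.0})
        arms = ("ibuprofen", "naproxen", "celecoxib")
        unadj = fit_unadjusted(pt)
        adj = fit_adjusted(pt, _uniform_ps(pt, arms), None, check_proportionality=False)
        for a in ("naproxen", "celecoxib"):
            assert adj.hr.loc[a, "coef"] == pytest.approx(unadj.hr.loc[a, "coef"], abs=0.02)

    def test_balanced_covariate_barely_moves_estimates(self):
        rng = np.random.default_rng(7)
        pt = _synthetic_pt(seed=7, n=6000, hr_map={"celecoxib": 1.5})
        arms = ("ibuprofen", "naproxen", "celecoxib")
        base = fit_adjusted(pt, _uniform_ps(pt, arms), None, check_proportionality=False)
        noise = pd.DataFrame({"noise": (rng.random(len(pt)) < 0.5).astype(float)},
                             index=pd.Index(pt["person_id"], name="person_id"))
        plus = fit_adjusted(pt, _uniform_ps(pt, arms), noise, check_proportionality=False)
        for a in ("naproxen", "celecoxib"):
            assert plus.hr.loc[a, "coef"] == pytest.approx(base.hr.loc[a, "coef"], abs=0.05)

    def test_collinear_columns_pruned_and_logged(self):
        pt = _synthetic_pt(seed=8, n=2000)
        arms = ("ibuprofen", "naproxen", "celecoxib")
        probs = _uniform_ps(pt, arms)
        dup = pd.DataFrame(
            {"c1": np.ones(len(pt)), "c2": probs["naproxen"].to_numpy()},
            index=probs.index,
        )
        res = fit_adjusted(pt, probs, dup, check_proportionality=False)
        assert any("zero-variance" in line or "collinear" in line for line in res.log)


def _time_varying_pt(seed=0, n=6000):
    """Treated-arm hazard declines over time (early 3x, late 0.3x): a strong
    proportionality violation."""
    rng = np.random.default_rng(seed)
    exposure = rng.choice(["ibuprofen", "naproxen"], n)
    treated = exposure == "naproxen"
    base = 0.012
    t = np.empty(n)
    # piecewise-exponential sampling: rate r1 before day 30, r2 after
    for mask, r1, r2 in [(treated, base * 3.0, base * 0.3), (~treated, base, base)]:
        k = mask.sum()
        t1 = rng.exponential(1 / r1, k)
        extra = rng.exponential(1 / r2, k)
        t[mask] = np.where(t1 <= 30, t1, 30 + extra)
    censor = 150.0
    return pd.DataFrame({
        "person_id": [f"P{i}" for i in range(n)],
        "exposure_nsaid": exposure,
        "futime_days": np.minimum(np.ceil(t), censor).astype(int) + 1,
        "event": t <= censor,
        "person_years": 1.0,
    })


class TestProportionalityCheck:
    def test_detects_planted_time_varying_effect(self):
        pt = _time_varying_pt(seed=9)
        res = fit_unadjusted(pt)
        tbl, reject = ph_check(res)
        assert reject
        assert (tbl["p"] < 0.05).any()

    def test_interaction_refit_reports_hr_at_median_followup(self):
        pt = _time_varying_pt(seed=10, n=4000)
        arms = ("ibuprofen", "naproxen")
        adj = fit_adjusted(pt, _uniform_ps(pt, arms), None, check_proportionality=True)
        assert adj.interaction
        row = adj.hr.loc["naproxen"]
        assert np.isfinite(row["hr"]) and row["lo"] < row["hr"] < row["hi"]

    def test_too_few_events_skips_check_with_warning(self):
        pt = _synthetic_pt(seed=11, n=60, censor_at=5.0)
        res = fit_unadjusted(pt)
        with pytest.warns(UserWarning, match="skipped"):
            tbl, reject = ph_check(res)
        assert not reject


class TestIncidenceTableAndVariants:
    def test_group_events_sum_to_overall(self, sim_bundle_small):
        from clopnsaid.cohort import build_drug_eras, compute_follow_up, find_cohort_entry
        from clopnsaid.pipeline import post_entry_events

        b = sim_bundle_small
        eras = build_drug_eras(b.dispensings)
        cohort, _ = find_cohort_entry(eras, b.enrollment, b.persons, "2010-12-31")
        ev = post_entry_events(b, cohort)
        fu = compute_follow_up(cohort, b.dispensings, b.enrollment, ev["gib_ich"],
                               "2010-12-31")
        tab = incidence_table(person_time_table(fu)).set_index("nsaid")
        groups = tab.drop(index="overall")
        assert groups["n_events"].sum() == tab.loc["overall", "n_events"]
        assert groups["person_years"].sum() == pytest.approx(tab.loc["overall", "person_years"])

    def test_variants_partition_and_truncate(self, sim_bundle_small):
        from clopnsaid.cohort import build_drug_eras, compute_follow_up, find_cohort_entry
        from clopnsaid.pipeline import post_entry_events

        b = sim_bundle_small
        eras = build_drug_eras(b.dispensings)
        cohort, _ = find_cohort_entry(eras, b.enrollment, b.persons, "2010-12-31")
        ev = post_entry_events(b, cohort)
        fu = {o: compute_follow_up(cohort, b.dispensings, b.enrollment, ev[o], "2010-12-31")
              for o in ev}
        fu180 = {o: compute_follow_up(cohort, b.dispensings, b.enrollment, ev[o],
                                      "2010-12-31", censor_at_day=180) for o in ev}
        res = run_analyses(
            fu, fu180, None, None,
            female=b.persons.set_index("person_id")["sex"].eq("female"),
            managed_persons=set(
                b.enrollment.loc[b.enrollment["managed_care"] == 1, "person_id"]),
            variants=("primary", "age_lt65", "age_ge65", "sens_180d", "sens_complete_data"),
            adjust=False,
        )
        for o in res:
            n_primary = res[o]["primary"]["incidence"].set_index("nsaid").loc["overall", "n_users"]
            n_lt = res[o]["age_lt65"]["incidence"].set_index("nsaid").loc["overall", "n_users"]
            n_ge = res[o]["age_ge65"]["incidence"].set_index("nsaid").loc["overall", "n_users"]
            assert n_lt + n_ge == n_primary  # age strata partition the cohort
            py180 = res[o]["sens_180d"]["incidence"].set_index("nsaid").loc["overall", "person_years"]
            py = res[o]["primary"]["incidence"].set_index("nsaid").loc["overall", "person_years"]
            assert py180 <= py + 1e-9
            n_complete = res[o]["sens_complete_data"]["incidence"].set_index("nsaid").loc[
                "overall", "n_users"]
            assert n_complete <= n_primary
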