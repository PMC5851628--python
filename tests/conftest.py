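"""Shared fixtures: a hand-built miniature claims bundle and small simulated
bundles (generated once per session)."""

from __future__ import annotations

import pandas as pd
import pytest

from clopnsaid.data_model import make_bundle
from clopnsaid.simulate import SimConfig, generate_bundle


def D(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture
def tiny_bundle():
    """Five persons exercising eras, entry, triggers and outcome codes.

    P1: clopidogrel 2005-01-01 (90d), ibuprofen added 2005-01-31 (30d)
        -> entry 2005-01-31, NSAID-triggered; stroke admission 2005-02-20.
    P2: naproxen first 2006-03-01 (30d), clopidogrel added 2006-03-11 (30d)
        -> clopidogrel-triggered; decoy stroke admission with injury code.
    P3: both start 2007-05-10 -> combination-triggered; dies 2007-06-15.
    P4: ibuprofen AND naproxen both cover the entry day -> excluded.
    P5: overlap exists but baseline enrollment is too short -> excluded.
    """
    persons = [
        dict(person_id=p, birth_date=D(b), sex=s, race_ethnicity=r, state="PA")
        for p, b, s, r in [
            ("P1", "1940-06-01", "female", "white"),
            ("P2", "1950-02-01", "male", "black"),
            ("P3", "1935-12-25", "female", "hispanic_latino"),
            ("P4", "1945-07-04", "male", "white"),
            ("P5", "1960-01-01", "female", "other_unknown"),
        ]
    ]
    enrollment = [
        dict(person_id="P1", start_date=D("2003-01-01"), end_date=D("2006-12-31")),
        dict(person_id="P2", start_date=D("2004-01-01"), end_date=D("2008-12-31")),
        dict(person_id="P3", start_date=D("2005-01-01"), end_date=D("2008-12-31")),
        dict(person_id="P4", start_date=D("2003-01-01"), end_date=D("2008-12-31")),
        dict(person_id="P5", start_date=D("2006-01-01"), end_date=D("2008-12-31"),
             managed_care=1),
    ]
    disp = [
        dict(person_id="P1", ingredient="clopidogrel", dispense_date=D("2005-01-01"), days_supply=90),
        dict(person_id="P1", ingredient="ibuprofen", dispense_date=D("2005-01-31"), days_supply=30),
        dict(person_id="P2", ingredient="naproxen", dispense_date=D("2006-03-01"), days_supply=30),
        dict(person_id="P2", ingredient="clopidogrel", dispense_date=D("2006-03-11"), days_supply=30),
        dict(person_id="P3", ingredient="clopidogrel", dispense_date=D("2007-05-10"), days_supply=30),
        dict(person_id="P3", ingredient="celecoxib", dispense_date=D("2007-05-10"), days_supply=30),
        dict(person_id="P4", ingredient="clopidogrel", dispense_date=D("2004-06-01"), days_supply=30),
        dict(person_id="P4", ingredient="ibuprofen", dispense_date=D("2004-06-01"), days_supply=30),
        dict(person_id="P4", ingredient="naproxen", dispense_date=D("2004-06-01"), days_supply=30),
        dict(person_id="P5", ingredient="clopidogrel", dispense_date=D("2006-06-01"), days_supply=30),
        dict(person_id="P5", ingredient="ibuprofen", dispense_date=D("2006-06-01"), days_supply=30),
    ]
    claims = [
        # P1: qualifying ischemic stroke (principal, inpatient)
        dict(person_id="P1", claim_id="c1", setting="inpatient",
             admission_date=D("2005-02-20"), discharge_date=D("2005-02-24"),
             code="43491", code_type="icd9_dx", position="principal"),
        # P2: stroke code but injury-coded admission -> excluded
        dict(person_id="P2", claim_id="c2", setting="inpatient",
             admission_date=D("2006-03-20"), discharge_date=D("2006-03-25"),
             code="43411", code_type="icd9_dx", position="principal"),
        dict(person_id="P2", claim_id="c2", setting="inpatient",
             admission_date=D("2006-03-20"), discharge_date=D("2006-03-25"),
             code="85200", code_type="icd9_dx", position="secondary"),
        # P3: baseline hypertension claim
        dict(person_id="P3", claim_id="c3", setting="outpatient",
             admission_date=D("2007-01-15"), discharge_date=D("2007-01-15"),
             code="4019", code_type="icd9_dx", position="principal"),
    ]
    deaths = [dict(person_id="P3", death_date=D("2007-06-15"))]
    return make_bundle(persons, enrollment, disp, claims, deaths)


@pytest.fixture(scope="session")
def sim_bundle_small():
    """A modest default-configuration bundle shared across tests."""
    return generate_bundle(SimConfig(n_persons=2500, seed=42))


@pytest.fixture(scope="session")
def sim_bundle_with_truth():
    cfg = SimConfig(n_persons=3000, seed=17, decoy_rate=0.5)
    bundle, truth = generate_bundle(cfg, return_truth=True)
    return cfg, bundle, truth
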