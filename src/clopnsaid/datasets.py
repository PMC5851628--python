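"""Published reference summaries for worked examples and arithmetic checks.

These tables transcribe the printed summary statistics of a large published
five-state US Medicaid cohort study of concomitant clopidogrel + NSAID use
(268,114 subjects, 1999-2010): per-NSAID event counts, person-years and
crude incidence rates for the three outcomes; selected baseline proportions
with their standardized differences versus ibuprofen; and the bookkeeping of
the study's hdPS covariate selection.  They contain no person-level data —
only printed aggregate cells — and serve as fixed inputs for recomputing the
study's worked-example arithmetic (incidence rates from events/person-years,
standardized differences from proportions, the hdPS accounting identity).
"""

from __future__ import annotations

import pandas as pd

# outcome, nsaid, n_users, n_events, person_years, printed rate per 1,000 py
_INCIDENCE_CELLS = [
    ("mortality", "overall", 268114, 2463, 48483, 50.8),
    ("mortality", "celecoxib", 66317, 901, 15930, 56.6),
    ("mortality", "diclofenac", 18593, 138, 3379, 40.8),
    ("mortality", "etodolac", 2807, 20, 536, 37.3),
    ("mortality", "ibuprofen", 69779, 414, 8667, 47.8),
    ("mortality", "indomethacin", 7651, 57, 834, 68.3),
    ("mortality", "meloxicam", 25459, 191, 5277, 36.2),
    ("mortality", "nabumetone", 7060, 54, 1392, 38.8),
    ("mortality", "naproxen", 36577, 245, 5695, 43.0),
    ("mortality", "rofecoxib", 26247, 398, 5303, 75.0),
    ("mortality", "valdecoxib", 7624, 45, 1470, 30.6),
    ("ami_stroke", "overall", 268113, 2822, 48176, 58.6),
    ("ami_stroke", "celecoxib", 66316, 888, 15807, 56.2),
    ("ami_stroke", "diclofenac", 18593, 183, 3360, 54.5),
    ("ami_stroke", "etodolac", 2807, 33, 531, 62.2),
    ("ami_stroke", "ibuprofen", 69779, 538, 8623, 62.4),
    ("ami_stroke", "indomethacin", 7651, 93, 828, 112.4),
    ("ami_stroke", "meloxicam", 25459, 225, 5245, 42.9),
    ("ami_stroke", "nabumetone", 7060, 59, 1386, 42.6),
    ("ami_stroke", "naproxen", 36577, 311, 5670, 54.9),
    ("ami_stroke", "rofecoxib", 26247, 417, 5264, 79.2),
    ("ami_stroke", "valdecoxib", 7624, 75, 1463, 51.3),
    ("gib_ich", "overall", 268087, 2620, 48225, 54.3),
    ("gib_ich", "celecoxib", 66310, 736, 15846, 46.4),
    ("gib_ich", "diclofenac", 18592, 207, 3354, 61.7),
    ("gib_ich", "etodolac", 2806, 29, 533, 54.5),
    ("gib_ich", "ibuprofen", 69775, 416, 8635, 48.2),
    ("gib_ich", "indomethacin", 7651, 108, 829, 130.3),
    ("gib_ich", "meloxicam", 25455, 246, 5252, 46.8),
    ("gib_ich", "nabumetone", 7060, 45, 1385, 32.5),
    ("gib_ich", "naproxen", 36576, 365, 5668, 64.4),
    ("gib_ich", "rofecoxib", 26240, 411, 5259, 78.1),
    ("gib_ich", "valdecoxib", 7622, 57, 1463, 39.0),
]

# covariate, comparator, proportion in comparator, proportion in ibuprofen,
# printed standardized difference (2 d.p.)
_BALANCE_CELLS = [
    ("female", "celecoxib", 0.672, 0.563, 0.23),
    ("female", "diclofenac", 0.643, 0.563, 0.16),
    ("female", "indomethacin", 0.455, 0.563, 0.22),
    ("female", "rofecoxib", 0.690, 0.563, 0.26),
    ("female", "valdecoxib", 0.708, 0.563, 0.31),
    ("race_black", "celecoxib", 0.109, 0.166, 0.17),
    ("race_black", "diclofenac", 0.105, 0.166, 0.18),
    ("race_black", "rofecoxib", 0.118, 0.166, 0.14),
    ("race_hispanic_latino", "celecoxib", 0.146, 0.212, 0.17),
    ("race_white", "etodolac", 0.575, 0.404, 0.35),
    ("age_65_to_80", "celecoxib", 0.509, 0.402, 0.22),
    ("age_80_to_100", "celecoxib", 0.260, 0.144, 0.29),
]

#: the published hdPS bookkeeping: 9 pairs x 500 selected, then filters
REFERENCE_HDPS_BOOKKEEPING = {
    "pooled": 4500,
    "duplicates": 3856,
    "under_threshold": 42,
    "prespecified_overlap": 6,
    "retained": 596,
}


def reference_incidence_table() -> pd.DataFrame:
    """Printed event counts, person-years and crude rates per NSAID group."""
    return pd.DataFrame(
        _INCIDENCE_CELLS,
        columns=["outcome", "nsaid", "n_users", "n_events", "person_years",
                 "printed_rate_per_1000py"],
    )


def reference_balance_table() -> pd.DataFrame:
    """Printed baseline proportions and standardized differences vs ibuprofen."""
    return pd.DataFrame(
        _BALANCE_CELLS,
        columns=["covariate", "comparator", "p_comparator", "p_ibuprofen",
                 "printed_s_diff"],
    )
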