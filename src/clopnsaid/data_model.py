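"""Domain model for administrative-claims-style data.

Five tables describe a claims extract: persons, enrollment spans, outpatient
drug dispensings, medical claims in long (one row per diagnosis/procedure
code) format, and death records.  The reader/writer pair uses UTF-8
comma-delimited text with a header row and ISO-8601 dates, so that a bundle
can be inspected with any spreadsheet or shell tool.

Conventions
-----------
* ICD-9 codes are stored dot-free ("410.11" -> "41011"); the reader strips
  dots on ingest so downstream pattern matching is unambiguous.
* Date intervals are closed: a dispensing on day ``d`` with ``days_supply s``
  covers days ``d .. d + s - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: the ten study NSAIDs, descending order of users in the source population
STUDY_NSAIDS = (
    "ibuprofen",
    "celecoxib",
    "naproxen",
    "rofecoxib",
    "meloxicam",
    "diclofenac",
    "indomethacin",
    "valdecoxib",
    "nabumetone",
    "etodolac",
)

REFERENT_NSAID = "ibuprofen"
CLOPIDOGREL = "clopidogrel"

SEXES = ("male", "female")
RACE_ETHNICITY = ("white", "black", "hispanic_latino", "other_unknown")
CLAIM_SETTINGS = ("inpatient", "outpatient", "emergency_department", "other")
CODE_TYPES = ("icd9_dx", "icd9_proc", "cpt_hcpcs")
DX_POSITIONS = ("principal", "secondary")

TABLE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "persons": ("person_id", "birth_date", "sex", "race_ethnicity", "state"),
    "enrollment": ("person_id", "start_date", "end_date", "managed_care"),
    "dispensings": ("person_id", "ingredient", "dispense_date", "days_supply"),
    "claims": (
        "person_id",
        "claim_id",
        "setting",
        "admission_date",
        "discharge_date",
        "code",
        "code_type",
        "position",
    ),
    "deaths": ("person_id", "death_date"),
}

_DATE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "persons": ("birth_date",),
    "enrollment": ("start_date", "end_date"),
    "dispensings": ("dispense_date",),
    "claims": ("admission_date", "discharge_date"),
    "deaths": ("death_date",),
}


class ValidationError(ValueError):
    """Raised when a claims table violates the declared schema or invariants."""


def normalize_icd9(code: str) -> str:
    """Return an ICD-9/CPT code with dots removed and whitespace stripped."""
    return str(code).replace(".", "").strip()


def _empty_table(name: str) -> pd.DataFrame:
    cols = TABLE_SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    for c in _DATE_COLUMNS[name]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    if name == "dispensings":
        df["days_supply"] = pd.Series(dtype="int64")
    if name == "enrollment":
        df["managed_care"] = pd.Series(dtype="int64")
    return df


@dataclass
class ClaimsBundle:
    """The five claims tables, cross-validated.

    Attributes
    ----------
    persons, enrollment, dispensings, claims, deaths : pandas.DataFrame
        See :data:`TABLE_SCHEMAS` for required columns.  ``claims`` is in
        long format: one row per (claim, code); a claim's rows share a
        ``claim_id``, setting and dates.
    """

    persons: pd.DataFrame = field(default_factory=lambda: _empty_table("persons"))
    enrollment: pd.DataFrame = field(default_factory=lambda: _empty_table("enrollment"))
    dispensings: pd.DataFrame = field(default_factory=lambda: _empty_table("dispensings"))
    claims: pd.DataFrame = field(default_factory=lambda: _empty_table("claims"))
    deaths: pd.DataFrame = field(default_factory=lambda: _empty_table("deaths"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "enrollment": self.enrollment,
            "dispensings": self.dispensings,
            "claims": self.claims,
            "deaths": self.deaths,
        }

    def validate(self) -> "ClaimsBundle":
        """Check schema, per-table invariants and referential integrity.

        Raises :class:`ValidationError` naming the offending table and row.
        """
        for name, df in self.tables().items():
            missing = set(TABLE_SCHEMAS[name]) - set(df.columns)
            if missing:
                raise ValidationError(f"table {name!r}: missing columns {sorted(missing)}")

        persons = self.persons
        if persons["person_id"].duplicated().any():
            dup = persons.loc[persons["person_id"].duplicated(), "person_id"].iloc[0]
            raise ValidationError(f"table 'persons': duplicate person_id {dup!r}")
        bad_sex = ~persons["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(
                f"table 'persons': row {int(np.flatnonzero(bad_sex)[0])}: invalid sex"
            )

        known = set(persons["person_id"])
        for name, df in self.tables().items():
            if name == "persons" or df.empty:
                continue
            dangling = ~df["person_id"].isin(known)
            if dangling.any():
                row = int(np.flatnonzero(dangling.to_numpy())[0])
                raise ValidationError(
                    f"table {name!r}: row {row}: person_id "
                    f"{df['person_id'].iloc[row]!r} not in persons"
                )

        disp = self.dispensings
        if not disp.empty:
            bad = disp["days_supply"].to_numpy() < 1
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"table 'dispensings': row {row}: days_supply must be >= 1"
                )

        enr = self.enrollment
        if not enr.empty:
            if (enr["end_date"] < enr["start_date"]).any():
                row = int(np.flatnonzero((enr["end_date"] < enr["start_date"]).to_numpy())[0])
                raise ValidationError(f"table 'enrollment': row {row}: end_date < start_date")
            srt = enr.sort_values(["person_id", "start_date"])
            same = srt["person_id"].eq(srt["person_id"].shift())
            overlap = same & (srt["start_date"] <= srt["end_date"].shift())
            if overlap.any():
                pid = srt.loc[overlap, "person_id"].iloc[0]
                raise ValidationError(
                    f"table 'enrollment': overlapping spans for person {pid!r}"
                )

        claims = self.claims
        if not claims.empty:
            bad_setting = ~claims["setting"].isin(CLAIM_SETTINGS)
            if bad_setting.any():
                row = int(np.flatnonzero(bad_setting.to_numpy())[0])
                raise ValidationError(f"table 'claims': row {row}: invalid setting")
            has_dis = claims["discharge_date"].notna()
            bad_dates = has_dis & (claims["discharge_date"] < claims["admission_date"])
            if bad_dates.any():
                row = int(np.flatnonzero(bad_dates.to_numpy())[0])
                raise ValidationError(
                    f"table 'claims': row {row}: discharge_date < admission_date"
                )
            dx = claims[claims["code_type"] == "icd9_dx"]
            n_principal = (
                dx[dx["position"] == "principal"].groupby("claim_id").size()
            )
            if (n_principal > 1).any():
                cid = n_principal[n_principal > 1].index[0]
                raise ValidationError(
                    f"table 'claims': claim {cid!r}: more than one principal diagnosis"
                )
            birth = persons.set_index("person_id")["birth_date"]
            adm_min = claims.groupby("person_id")["admission_date"].min()
            too_early = adm_min < birth.reindex(adm_min.index)
            if too_early.any():
                pid = too_early[too_early].index[0]
                raise ValidationError(
                    f"table 'claims': person {pid!r}: claim predates birth_date"
                )

        deaths = self.deaths
        if not deaths.empty and deaths["person_id"].duplicated().any():
            pid = deaths.loc[deaths["person_id"].duplicated(), "person_id"].iloc[0]
            raise ValidationError(f"table 'deaths': duplicate death record for {pid!r}")
        return self


def _parse_dates(df: pd.DataFrame, name: str, path: str) -> pd.DataFrame:
    for col in _DATE_COLUMNS[name]:
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"table {name!r} ({path}): unparseable date in {col!r}: {exc}")
    return df


def read_claims_bundle(paths: Mapping[str, str | Path] | str | Path) -> ClaimsBundle:
    """Read and validate a claims bundle from delimited-text tables.

    Parameters
    ----------
    paths
        Either a directory containing ``persons.csv`` .. ``deaths.csv``, or a
        mapping from table name to file path.

    Returns
    -------
    ClaimsBundle
        Parsed, typed, dot-stripped and cross-validated.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in TABLE_SCHEMAS}
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_SCHEMAS:
        p = Path(paths[name])
        if not p.exists():
            raise ValidationError(f"table {name!r}: file not found: {p}")
        df = pd.read_csv(p, dtype={"person_id": str}, keep_default_na=False, na_values=[""])
        missing = set(TABLE_SCHEMAS[name]) - set(df.columns)
        if missing:
            raise ValidationError(f"table {name!r} ({p}): missing columns {sorted(missing)}")
        df = _parse_dates(df, name, str(p))
        if name == "dispensings" and len(df):
            df["days_supply"] = pd.to_numeric(df["days_supply"]).astype("int64")
        if name == "enrollment" and len(df):
            df["managed_care"] = pd.to_numeric(df["managed_care"]).astype("int64")
        if name == "claims" and len(df):
            df["code"] = df["code"].map(normalize_icd9)
            df["position"] = df["position"].fillna("").astype(str)
            df["claim_id"] = df["claim_id"].astype(str)
        tables[name] = df.loc[:, list(TABLE_SCHEMAS[name])]
        if not len(df):
            tables[name] = _empty_table(name)
    return ClaimsBundle(**tables).validate()


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle to ``directory`` as the five CSV tables (ISO dates)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, df in bundle.tables().items():
        df = df.copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        out[name] = path
    return out


def is_continuously_enrolled(
    spans: pd.DataFrame | Sequence[tuple],
    window_start,
    window_end,
    max_gap_days: int = 0,
) -> bool:
    """Whether enrollment spans cover a window, allowing gaps <= ``max_gap_days``.

    A person counts as continuously enrolled over ``[window_start, window_end]``
    when every maximal run of uncovered days inside the window (including runs
    touching the window edges) has length at most ``max_gap_days`` days.  With
    the default ``max_gap_days = 0`` this is exact day-by-day coverage.

    Parameters
    ----------
    spans
        DataFrame with ``start_date``/``end_date`` columns, or a sequence of
        ``(start, end)`` pairs (closed intervals).
    """
    ws = pd.Timestamp(window_start)
    we = pd.Timestamp(window_end)
    if ws > we:
        raise ValueError("window_start must be <= window_end")
    if isinstance(spans, pd.DataFrame):
        pairs = list(zip(spans["start_date"], spans["end_date"]))
    else:
        pairs = [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in spans]
    # clip to window and merge
    clipped = sorted(
        (max(pd.Timestamp(s), ws), min(pd.Timestamp(e), we))
        for s, e in pairs
        if pd.Timestamp(e) >= ws and pd.Timestamp(s) <= we
    )
    gap_limit = pd.Timedelta(days=max_gap_days)
    cursor = ws  # first uncovered day so far
    for s, e in clipped:
        if s - cursor > gap_limit:
            return False
        cursor = max(cursor, e + pd.Timedelta(days=1))
        if cursor > we:
            return True
    return (we + pd.Timedelta(days=1)) - cursor <= gap_limit


def make_bundle(
    persons: pd.DataFrame | Iterable[dict] | None = None,
    enrollment: pd.DataFrame | Iterable[dict] | None = None,
    dispensings: pd.DataFrame | Iterable[dict] | None = None,
    claims: pd.DataFrame | Iterable[dict] | None = None,
    deaths: pd.DataFrame | Iterable[dict] | None = None,
    validate: bool = True,
) -> ClaimsBundle:
    """Convenience constructor accepting record dicts; fills defaults and types."""

    def coerce(name: str, obj) -> pd.DataFrame:
        if obj is None:
            return _empty_table(name)
        df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(list(obj))
        for col in TABLE_SCHEMAS[name]:
            if col not in df.columns:
                if name == "claims" and col == "position":
                    df[col] = ""
                elif name == "claims" and col == "code_type":
                    df[col] = "icd9_dx"
                elif name == "claims" and col == "discharge_date":
                    df[col] = pd.NaT
                elif name == "enrollment" and col == "managed_care":
                    df[col] = 0
                else:
                    raise ValidationError(f"table {name!r}: missing column {col!r}")
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col])
        if name == "claims":
            df["code"] = df["code"].map(normalize_icd9)
            df["claim_id"] = df["claim_id"].astype(str)
            df["position"] = df["position"].fillna("")
        if name == "enrollment":
            df["managed_care"] = pd.to_numeric(df["managed_care"]).fillna(0).astype("int64")
        df["person_id"] = df["person_id"].astype(str)
        return df.loc[:, list(TABLE_SCHEMAS[name])]

    bundle = ClaimsBundle(
        persons=coerce("persons", persons),
        enrollment=coerce("enrollment", enrollment),
        dispensings=coerce("dispensings", dispensings),
        claims=coerce("claims", claims),
        deaths=coerce("deaths", deaths),
    )
    return bundle.validate() if validate else bundle
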