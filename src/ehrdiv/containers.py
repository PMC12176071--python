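"""In-memory containers for raw ("care zone") and processed ("research zone") data.

A raw extract mimics what a general practice's EHR system exports: flat event
tables keyed by an opaque patient key (``true_id``).  A processed dataset is
the research-ready product of one ETL rule-set: pseudonymized patients with
registration quarters plus derived contacts / claims / prescriptions /
episodes tables, all restricted to one analysis year.

Tables are plain :class:`pandas.DataFrame` objects with fixed, schema-checked
columns; dates are ``datetime64[ns]`` at day granularity, identifiers and
clinical codes are strings.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

#: column -> kind; kind in {str, int, float, bool, date, date_opt}
RAW_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "true_id": "str",
        "practice_id": "str",
        "ssn": "str",  # empty string = missing
        "postal_code": "str",
        "birth_year": "int",
        "sex": "str",
        "enrollment_date": "date",
        "disenrollment_date": "date_opt",  # NaT = still enrolled
    },
    "journal_contacts": {
        "true_id": "str",
        "date": "date",
        "icpc": "str",
        "episode_key": "str",  # empty = not linked to an episode record
    },
    "claims_events": {
        "true_id": "str",
        "date": "date",
        "claims_code": "str",
        "icpc": "str",  # same-day diagnosis link, empty = none
    },
    "episodes": {
        "episode_key": "str",
        "true_id": "str",
        "icpc": "str",
        "start_date": "date",
        "end_date": "date_opt",
        "chronic": "bool",
    },
    "prescriptions": {
        "true_id": "str",
        "date": "date",
        "atc": "str",
        "source": "str",  # "gp" | "pharmacy"
        "icpc_indication": "str",  # empty = unknown indication
    },
    "capitation": {
        "true_id": "str",
        "year": "int",
        "quarter": "int",
    },
}

PROCESSED_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "pseudo_id": "str",
        "platform_id": "str",  # empty = not linkable on the platform
        "practice_id": "str",
        "age_band": "str",
        "sex": "str",
        "quarters": "str",  # subset of "1234", e.g. "234"
        "patient_years": "float",
    },
    "contacts": {
        "pseudo_id": "str",
        "date": "date",
    },
    "claims": {
        "pseudo_id": "str",
        "date": "date",
        "claims_code": "str",
        "icpc": "str",
    },
    "prescriptions": {
        "pseudo_id": "str",
        "date": "date",
        "atc": "str",
    },
    "episodes": {
        "pseudo_id": "str",
        "icpc": "str",
        "start_date": "date",
        "end_date": "date_opt",  # NaT = open (chronic)
    },
}


class SchemaError(ValueError):
    """A table does not match its expected schema (names the table and column)."""


def coerce_table(df: pd.DataFrame, schema: dict[str, str], table: str) -> pd.DataFrame:
    """Coerce *df* to the canonical dtypes of *schema*, validating columns.

    Raises :class:`SchemaError` naming the table and the first offending
    column.  Extra columns are dropped; column order is normalised.
    """
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"table {table!r}: missing column {col!r}")
    out = {}
    for col, kind in schema.items():
        s = df[col]
        if kind == "str":
            s = s.astype(object).where(~pd.isna(s), "").astype(str)
            s = s.replace("nan", "")  # guard against stringified NaN
        elif kind == "int":
            try:
                s = s.astype(np.int64)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"table {table!r}: column {col!r} not integer") from exc
        elif kind == "float":
            s = s.astype(np.float64)
        elif kind == "bool":
            if s.dtype == object:
                s = s.map({"True": True, "False": False, True: True, False: False})
                if s.isna().any():
                    raise SchemaError(f"table {table!r}: column {col!r} not boolean")
            s = s.astype(bool)
        elif kind in ("date", "date_opt"):
            if s.dtype == object:
                s = s.replace("", pd.NaT)
            s = pd.to_datetime(s, format="mixed" if s.dtype == object else None)
            s = s.astype("datetime64[ns]")
            if kind == "date" and s.isna().any():
                raise SchemaError(f"table {table!r}: column {col!r} has missing dates")
        else:  # pragma: no cover - schema literal typo
            raise AssertionError(kind)
        out[col] = s
    res = pd.DataFrame(out, columns=list(schema))
    return res.reset_index(drop=True)


def empty_table(schema: dict[str, str]) -> pd.DataFrame:
    return coerce_table(pd.DataFrame({c: [] for c in schema}), schema, "empty")


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a, b, check_dtype=True)
        return True
    except AssertionError:
        return False


@dataclass
class RawEhrExtract:
    """The simulated care-zone event tables of a set of general practices."""

    patients: pd.DataFrame
    journal_contacts: pd.DataFrame
    claims_events: pd.DataFrame
    episodes: pd.DataFrame
    prescriptions: pd.DataFrame
    capitation: pd.DataFrame

    def table_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {n: len(self.table(n)) for n in self.table_names()}

    def equals(self, other: "RawEhrExtract") -> bool:
        return all(_frames_equal(self.table(n), other.table(n)) for n in self.table_names())

    def validate(self) -> None:
        """Check referential integrity and basic invariants; raise on violation."""
        for name in self.table_names():
            coerce_table(self.table(name), RAW_SCHEMAS[name], name)
        ids = set(self.patients["true_id"])
        if len(ids) != len(self.patients):
            raise ValueError("duplicate true_id in patients")
        for name in ("journal_contacts", "claims_events", "episodes", "prescriptions", "capitation"):
            t = self.table(name)
            if len(t) and not t["true_id"].isin(ids).all():
                raise ValueError(f"table {name!r}: events reference unknown patients")
        p = self.patients
        both = p["disenrollment_date"].notna()
        if (p.loc[both, "disenrollment_date"] < p.loc[both, "enrollment_date"]).any():
            raise ValueError("disenrollment before enrollment")
        e = self.episodes
        closed = e["end_date"].notna()
        if len(e) and (e.loc[closed, "end_date"] < e.loc[closed, "start_date"]).any():
            raise ValueError("episode end before start")


@dataclass
class ProcessedDataset:
    """A research-zone dataset: one ETL rule-set applied to a raw extract."""

    name: str
    analysis_year: int
    patients: pd.DataFrame
    contacts: pd.DataFrame
    claims: pd.DataFrame
    prescriptions: pd.DataFrame
    episodes: pd.DataFrame

    def table_names(self) -> tuple[str, ...]:
        return ("patients", "contacts", "claims", "prescriptions", "episodes")

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {n: len(self.table(n)) for n in self.table_names()}

    def equals(self, other: "ProcessedDataset") -> bool:
        return self.analysis_year == other.analysis_year and all(
            _frames_equal(self.table(n), other.table(n)) for n in self.table_names()
        )

    def validate(self) -> None:
        for name in self.table_names():
            coerce_table(self.table(name), PROCESSED_SCHEMAS[name], name)
        p = self.patients
        if p["pseudo_id"].duplicated().any():
            raise ValueError("duplicate pseudo_id in patients")
        ok_py = p["patient_years"].isin([0.25, 0.5, 0.75, 1.0])
        if len(p) and not ok_py.all():
            raise ValueError("patient_years outside {0.25, 0.5, 0.75, 1.0}")
        if len(p) and not (p["quarters"].str.len() * 0.25 == p["patient_years"]).all():
            raise ValueError("patient_years inconsistent with quarters")
        ids = set(p["pseudo_id"])
        for name in ("contacts", "claims", "prescriptions", "episodes"):
            t = self.table(name)
            if len(t) and not t["pseudo_id"].isin(ids).all():
                raise ValueError(f"table {name!r}: rows reference unknown patients")
        if self.contacts.duplicated(["pseudo_id", "date"]).any():
            raise ValueError("contacts not unique on (pseudo_id, date)")
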