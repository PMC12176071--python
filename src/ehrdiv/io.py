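"""CSV persistence for raw extracts and processed datasets.

Everything is UTF-8 CSV with a header row and ISO-8601 dates; missing
optional values (open end dates, absent SSNs) are empty fields.  Reading back
a written object reproduces it exactly, including dtypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import (
    PROCESSED_SCHEMAS,
    RAW_SCHEMAS,
    ProcessedDataset,
    RawEhrExtract,
    SchemaError,
    coerce_table,
)


class FormatError(ValueError):
    """A directory does not contain the expected table files/columns."""


def _write_table(df: pd.DataFrame, schema: dict[str, str], path: Path) -> None:
    out = df.copy()
    for col, kind in schema.items():
        if kind in ("date", "date_opt"):
            out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, index=False)


def _read_table(path: Path, schema: dict[str, str], table: str) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing table file for {table!r}: {path.name}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    try:
        return coerce_table(df, schema, table)
    except SchemaError as exc:
        raise FormatError(str(exc)) from exc


def write_extract(extract: RawEhrExtract, directory) -> list[Path]:
    """Write the six raw tables as ``<table>.csv`` under *directory*."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in extract.table_names():
        p = d / f"{name}.csv"
        _write_table(extract.table(name), RAW_SCHEMAS[name], p)
        paths.append(p)
    return paths


def read_extract(directory) -> RawEhrExtract:
    d = Path(directory)
    tables = {name: _read_table(d / f"{name}.csv", RAW_SCHEMAS[name], name) for name in RAW_SCHEMAS}
    return RawEhrExtract(**tables)


def write_processed(ds: ProcessedDataset, directory) -> list[Path]:
    """Write a processed dataset (five tables plus a small meta.json)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in ds.table_names():
        p = d / f"{name}.csv"
        _write_table(ds.table(name), PROCESSED_SCHEMAS[name], p)
        paths.append(p)
    meta = {"name": ds.name, "analysis_year": ds.analysis_year}
    (d / "meta.json").write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return paths


def read_processed(directory) -> ProcessedDataset:
    d = Path(directory)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise FormatError("missing meta.json")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    tables = {
        name: _read_table(d / f"{name}.csv", PROCESSED_SCHEMAS[name], name)
        for name in PROCESSED_SCHEMAS
    }
    return ProcessedDataset(
        name=meta["name"], analysis_year=int(meta["analysis_year"]), **tables
    )
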