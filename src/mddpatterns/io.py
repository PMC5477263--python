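"""CSV interchange and the integer day grid.

Claims data have no community-standard file format, so the pipeline defines a
documented CSV schema for its three input tables (enrollment spans, pharmacy
claims, medical claims) plus the synthetic ground-truth table. Files carry
ISO-8601 dates in UTF-8; in memory every date column is an integer day number
(proleptic Gregorian ordinal, via ``datetime.date.toordinal``), which makes
all gap/window arithmetic exact integer arithmetic.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd

# column -> dtype kind; "date" columns are ISO strings on disk, ints in memory
ENROLLMENT_COLUMNS = {
    "patient_id": "str",
    "start_date": "date",
    "end_date": "date",
    "plan_type": "str",
    "medicare_flag": "bool",
    "birth_year": "int",
    "sex": "str",
    "region": "str",
}
PHARMACY_COLUMNS = {
    "patient_id": "str",
    "fill_date": "date",
    "ingredient": "str",
    "drug_class": "str",
    "brand_generic": "str",
    "strength_mg": "float",
    "quantity": "float",
    "days_supply": "int",
    "paid_amount": "float",
}
MEDICAL_COLUMNS = {
    "patient_id": "str",
    "service_start_date": "date",
    "service_end_date": "date",
    "setting": "str",
    "dx_codes": "str",  # semicolon-joined ICD-9 codes
    "paid_amount": "float",
    "provider_mental_health_flag": "bool",
}
TRUTH_COLUMNS = {
    "patient_id": "str",
    "cohort": "str",
    "pattern": "str",
    "index_date": "date",
    "change_dates": "str",  # semicolon-joined ISO dates
}

_SCHEMAS = {
    "enrollment": ENROLLMENT_COLUMNS,
    "pharmacy": PHARMACY_COLUMNS,
    "medical": MEDICAL_COLUMNS,
    "truth": TRUTH_COLUMNS,
}


class SchemaError(ValueError):
    """An input table is missing required columns."""


def to_day(date: str | _dt.date) -> int:
    """ISO date (or date object) -> integer day number."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return date.toordinal()


def from_day(day: int) -> _dt.date:
    return _dt.date.fromordinal(int(day))


def year_of_day(day: int) -> int:
    return from_day(day).year


def read_claims_csv(path: str | Path, table: str) -> pd.DataFrame:
    """Read one of the documented claims tables, converting dates to days."""
    schema = _SCHEMAS[table]
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table at {path} is missing column(s): {', '.join(missing)}")
    for col, kind in schema.items():
        if kind == "date":
            df[col] = df[col].map(lambda v: to_day(v) if pd.notna(v) else pd.NA).astype("Int64")
        elif kind == "bool":
            df[col] = df[col].astype(bool)
        elif kind == "int":
            df[col] = df[col].astype(int)
        elif kind == "float":
            df[col] = df[col].astype(float)
        else:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_claims_csv(df: pd.DataFrame, path: str | Path, table: str) -> None:
    """Write a claims table, converting day numbers back to ISO dates."""
    schema = _SCHEMAS[table]
    out = df.copy()
    for col, kind in schema.items():
        if kind == "date" and col in out.columns:
            out[col] = out[col].map(lambda v: from_day(v).isoformat() if pd.notna(v) else "")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
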