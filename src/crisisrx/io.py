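"""File formats and calendar conventions shared by all pipeline stages.

The study window is the 96 calendar months from January 2005 through December
2012; months are indexed t = 1..96 with t = 1 meaning January 2005.  All CSV
interfaces accept either the integer index or an ISO ``YYYY-MM`` string.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = [
    "STUDY_START_YEAR",
    "N_STUDY_MONTHS",
    "CRISIS_MONTH",
    "month_to_index",
    "index_to_month",
    "parse_month_column",
    "read_table",
    "write_table",
    "SchemaError",
    "SCHEMAS",
]

STUDY_START_YEAR = 2005
N_STUDY_MONTHS = 96
#: first month of the recession period (January 2009 -> t = 49)
CRISIS_MONTH = 49

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


class SchemaError(ValueError):
    """A table does not conform to its declared column schema."""


def month_to_index(month: int | str) -> int:
    """Convert a month given as ``YYYY-MM`` or an integer index to 1..96.

    >>> month_to_index("2011-01")
    73
    """
    if isinstance(month, str):
        m = _MONTH_RE.match(month.strip())
        if m is None:
            raise ValueError(f"month {month!r} is not YYYY-MM or an integer index")
        year, mon = int(m.group(1)), int(m.group(2))
        if not 1 <= mon <= 12:
            raise ValueError(f"month {month!r} has month-of-year outside 1..12")
        idx = (year - STUDY_START_YEAR) * 12 + mon
    else:
        idx = int(month)
    if not 1 <= idx <= N_STUDY_MONTHS:
        raise ValueError(
            f"month index {idx} outside the study window 1..{N_STUDY_MONTHS}"
        )
    return idx


def index_to_month(index: int) -> str:
    """Inverse of :func:`month_to_index`: 73 -> ``'2011-01'``."""
    index = int(index)
    if not 1 <= index <= N_STUDY_MONTHS:
        raise ValueError(f"month index {index} outside 1..{N_STUDY_MONTHS}")
    year, mon = divmod(index - 1, 12)
    return f"{STUDY_START_YEAR + year}-{mon + 1:02d}"


def parse_month_column(col: pd.Series) -> pd.Series:
    """Vectorized month parsing; raises with row positions on bad values."""
    out = []
    bad = []
    for pos, v in enumerate(col):
        try:
            out.append(month_to_index(v))
        except ValueError:
            bad.append(pos)
            out.append(-1)
    if bad:
        raise SchemaError(
            f"column {col.name!r}: unparsable/out-of-range month at rows {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    return pd.Series(out, index=col.index, name=col.name, dtype="int64")


# required column -> pandas dtype ("month" gets special parsing)
SCHEMAS: dict[str, dict[str, str]] = {
    "individuals": {
        "individual_id": "int64",
        "sex": "object",
        "birth_date": "object",
        "country": "object",
        "family_in_cohort": "bool",
    },
    "prescriptions": {
        "individual_id": "int64",
        "month": "month",
        "substance": "object",
        "atc_code": "object",
        "n_packs": "int64",
        "units_per_pack": "int64",
        "amount_per_unit_mg": "float64",
    },
    "panel": {
        "individual_id": "int64",
        "month": "month",
        "n_drugs": "int64",
        "ddd": "float64",
    },
    "clinical": {
        "individual_id": "int64",
        "month": "month",
        "visits": "int64",
    },
    "registry": {
        "atc_code": "object",
        "substance": "object",
        "ddd_amount_mg": "float64",
        "version": "object",
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Load a CSV and validate it against one of the named schemas.

    Extra columns are preserved untouched; missing required columns raise
    :class:`SchemaError` naming them.
    """
    cols = SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema!r}")
    for name, dtype in cols.items():
        if dtype == "month":
            df[name] = parse_month_column(df[name])
        else:
            try:
                df[name] = df[name].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}: column {name!r} not coercible to {dtype}: {exc}")
    return df


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV such that :func:`read_table` round-trips it."""
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {path}: missing column(s) {missing}")
    df.to_csv(path, index=False)
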