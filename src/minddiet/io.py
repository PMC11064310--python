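"""Cohort CSV reading/writing with light schema validation.

CSV dialect: comma-separated, UTF-8, header row, empty cell = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["CohortCsvSchema", "SchemaError", "read_cohort_csv", "write_cohort_csv"]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class CohortCsvSchema:
    """Required columns and their kinds ("numeric" or "string")."""

    required: Mapping[str, str] = field(default_factory=dict)
    id_column: str = "id"
    version: str = "1"

    def __post_init__(self) -> None:
        for col, kind in self.required.items():
            if kind not in ("numeric", "string"):
                raise SchemaError(f"unknown column kind {kind!r} for {col!r}")


def read_cohort_csv(path, schema: CohortCsvSchema | None = None) -> pd.DataFrame:
    """Read a cohort table; missing cells become NaN, bad cells reject rows."""
    df = pd.read_csv(path, encoding="utf-8")
    schema = schema or CohortCsvSchema()
    missing_cols = [c for c in list(schema.required) + [schema.id_column] if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing_cols))}")
    if df[schema.id_column].duplicated().any():
        dupes = df.loc[df[schema.id_column].duplicated(), schema.id_column].tolist()
        raise SchemaError(f"duplicate participant id(s): {dupes[:5]}")
    bad_rows: set[int] = set()
    for col, kind in schema.required.items():
        if kind != "numeric":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_rows.update((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = coerced
    if bad_rows:
        raise SchemaError(f"unparseable required cells in file row(s): {sorted(bad_rows)}")
    return df


def write_cohort_csv(df: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    """Write with a stable column order; NaN serialises to empty cells."""
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, index=False, encoding="utf-8")
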