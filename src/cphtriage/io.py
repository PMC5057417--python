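"""Cohort CSV reading/writing and chart JSON handling.

Cohort tables travel as plain CSV with a ``#``-prefixed comment header
recording the generating seed when one is known.  Booleans are written as
0/1 and accepted as 0/1/true/false; decimals always use ".".
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .triage import ScoreChart

__all__ = ["read_cohort", "write_cohort", "read_chart", "write_chart",
           "COLUMN_ORDER", "REQUIRED_COLUMNS"]

COLUMN_ORDER = [
    "encounter_id", "center", "period", "arm",
    "sbp", "hr", "rr", "spo2", "oxygen_treatment", "minor_injury",
    "nurse_level", "dept_level", "died30", "los_days", "icu", "readmit30",
]

REQUIRED_COLUMNS = ["sbp", "hr", "rr", "spo2", "oxygen_treatment", "died30"]

_BOOL_COLUMNS = ["oxygen_treatment", "minor_injury", "died30", "icu", "readmit30"]

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _parse_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    as_str = series.astype(str).str.strip().str.lower()
    bad = ~(as_str.isin(_TRUE) | as_str.isin(_FALSE))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"column {name!r}: unparseable boolean at row {row}")
    return as_str.isin(_TRUE)


def read_cohort(path: Union[str, Path],
                required: Optional[list[str]] = None) -> pd.DataFrame:
    """Read a cohort CSV, validating columns and value types."""
    table = pd.read_csv(path, comment="#")
    for col in (required if required is not None else REQUIRED_COLUMNS):
        if col not in table.columns:
            raise ValueError(f"missing column {col}")
    for col in ("sbp", "hr", "rr", "spo2", "los_days"):
        if col in table.columns:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"non-numeric value in column {col!r} at row {row}")
            table[col] = coerced
    for col in _BOOL_COLUMNS:
        if col in table.columns:
            table[col] = _parse_bool(table[col], col)
    return table


def write_cohort(table: pd.DataFrame, path: Union[str, Path],
                 seed: Optional[int] = None) -> None:
    """Write a cohort CSV in canonical column order, booleans as 0/1."""
    out = table.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    cols = [c for c in COLUMN_ORDER if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out[cols].to_csv(fh, index=False)


def read_chart(path: Union[str, Path]) -> ScoreChart:
    return ScoreChart.from_json(Path(path).read_text())


def write_chart(chart: ScoreChart, path: Union[str, Path]) -> None:
    Path(path).write_text(chart.to_json())


def write_json(obj: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    if isinstance(value, (tuple, set)):
        return list(value)
    raise TypeError(f"not JSON-serializable: {type(value)}")
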