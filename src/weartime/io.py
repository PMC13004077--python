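"""Tabular I/O helpers: CSV and Parquet with ISO-8601 date handling.

All tables in this package travel as pandas DataFrames. Dates are
datetime64 in memory and ISO ``YYYY-MM-DD`` strings on disk (CSV);
Parquet keeps native timestamp types.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

#: columns parsed/serialized as calendar dates wherever they appear
DATE_COLUMNS = ("date", "index_date", "first_day", "last_day", "diagnosis_date")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV or Parquet table, parsing known date columns."""
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    for col in DATE_COLUMNS:
        if col in df.columns and not pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV or Parquet depending on the file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".parquet":
        df.to_parquet(path, index=False)
        return path
    out = df.copy()
    for col in DATE_COLUMNS:
        if col in out.columns and pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def read_config_file(path: str | Path) -> dict:
    """Read a YAML or JSON mapping (YAML is a superset, so one parser serves both)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
    return path
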