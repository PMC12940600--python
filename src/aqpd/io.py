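"""CSV dialects for hourly monitor records and daily aggregates.

Hourly files carry the header ``timestamp,pm10,pm25,no2,o3,so2,temp,ws,wd,
rh,pres,rad`` with ISO-8601 timestamps and empty fields for missing values.
Reading applies cell-level validity rules: unparseable or negative
concentration cells become missing and are counted per column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import HOURLY_COLUMNS, DailyDataset, HourlyDataset
from .scenario import POLLUTANTS

__all__ = ["read_hourly_csv", "write_hourly_csv", "read_daily_csv", "write_daily_csv"]

log = logging.getLogger(__name__)

#: Columns a valid hourly file must at least provide.
MANDATORY_COLUMNS = ["timestamp"] + POLLUTANTS + ["temp", "ws", "rh"]


def write_hourly_csv(data: HourlyDataset, path) -> None:
    cols = [c for c in HOURLY_COLUMNS if c in data.frame.columns]
    out = data.frame[cols].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_hourly_csv(path) -> HourlyDataset:
    """Read an hourly monitor CSV, flagging invalid cells as missing.

    Unparseable numeric cells and negative pollutant concentrations are set
    to missing; per-column counts are logged and returned on the dataset's
    ``invalid_counts``. Missing mandatory columns or duplicated timestamps
    reject the file.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory columns: {', '.join(missing_cols)}")

    ts = pd.to_datetime(df["timestamp"], errors="raise")
    invalid: dict[str, int] = {}
    out = pd.DataFrame({"timestamp": ts})
    for col in df.columns:
        if col == "timestamp":
            continue
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad_parse = vals.isna() & raw.notna() & (raw.str.strip() != "")
        if col in POLLUTANTS:
            bad_neg = vals < 0
            vals = vals.mask(bad_neg)
        else:
            bad_neg = pd.Series(False, index=vals.index)
        n_bad = int(bad_parse.sum() + bad_neg.sum())
        if n_bad:
            invalid[col] = n_bad
            log.warning("%s: %d invalid cell(s) set to missing", col, n_bad)
        out[col] = vals
    return HourlyDataset(out, invalid_counts=invalid)


def write_daily_csv(data: DailyDataset, path) -> None:
    out = data.frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_daily_csv(path, min_valid_hours: int = 18) -> DailyDataset:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for col in df.columns:
        if col.endswith("_n"):
            df[col] = df[col].astype(int)
    if "weekday" in df.columns:
        df["weekday"] = df["weekday"].astype(bool)
    return DailyDataset(df, min_valid_hours=min_valid_hours)
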