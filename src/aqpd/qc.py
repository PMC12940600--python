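"""Hourly-to-daily aggregation under a completeness rule, plus predictor prep.

A variable's daily mean is retained only when at least ``min_valid_hours``
of its 24 hourly values are valid (the guideline-recommended >=75%
completeness at the default of 18); days below the threshold are excluded
for that variable only. No imputation is performed. The daily O3 metric for
guideline comparison is the maximum rolling 8-hour mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import DailyDataset, HourlyDataset
from .phases import PhaseCalendar
from .scenario import MET_VARS, POLLUTANTS

__all__ = [
    "aggregate_daily",
    "compute_o3_8h_max",
    "assign_phase",
    "standardize_predictors",
]


def assign_phase(date, calendar: PhaseCalendar) -> str:
    """Phase label for a date; raises ``KeyError`` outside the calendar."""
    return calendar.assign(date)


def compute_o3_8h_max(data: HourlyDataset, min_valid_in_window: int = 6) -> pd.Series:
    """Daily maximum of rolling 8-hour O3 means.

    Windows end within the local day; a window is valid when at least
    ``min_valid_in_window`` of its 8 hours are present. Days with no valid
    window are missing.
    """
    if "o3" not in data.frame.columns:
        raise ValueError("hourly data has no 'o3' column")
    s = data.frame.set_index("timestamp")["o3"]
    full = s.reindex(pd.date_range(s.index[0].floor("D"), s.index[-1], freq="h"))
    roll = full.rolling(window=8, min_periods=min_valid_in_window).mean()
    daily = roll.groupby(roll.index.date).max()
    daily.index.name = "date"
    daily.name = "o3_8h_max"
    return daily


def aggregate_daily(
    data: HourlyDataset,
    min_valid_hours: int = 18,
    calendar: PhaseCalendar | None = None,
) -> DailyDataset:
    """Aggregate hourly values to QC-gated daily means.

    Daily means use available valid hours only; a variable's value is
    missing on days where its valid-hour count falls below the threshold.
    Valid-hour counts are kept alongside as ``<var>_n`` columns. When a
    calendar is given, each date is labelled with its phase.
    """
    if not 1 <= min_valid_hours <= 24:
        raise ValueError("min_valid_hours must be in 1..24")
    df = data.frame
    variables = [v for v in POLLUTANTS + MET_VARS if v in df.columns]
    grp = df.groupby(df["timestamp"].dt.date)

    out = pd.DataFrame({"date": sorted(grp.groups)})
    out = out.set_index("date")
    for v in variables:
        counts = grp[v].count()
        means = grp[v].mean()
        means[counts < min_valid_hours] = np.nan
        out[v] = means
        out[v + "_n"] = counts.astype(int)

    if "o3" in df.columns:
        o3_8h = compute_o3_8h_max(data)
        out["o3_8h_max"] = o3_8h.reindex(out.index)

    out = out.reset_index()
    out["weekday"] = pd.to_datetime(out["date"]).dt.dayofweek < 5
    if calendar is not None:
        out.insert(1, "phase", calendar.assign_series(out["date"]).to_numpy())
    return DailyDataset(out, min_valid_hours=min_valid_hours)


def standardize_predictors(
    daily: DailyDataset, variables: list[str]
) -> tuple[DailyDataset, dict[str, tuple[float, float]]]:
    """Mean-centre and scale predictors to unit sample sd (ddof=1).

    Scaling constants are computed over non-missing rows of the full window
    and returned for back-transformation. Variables with fewer than two
    values or zero variance are rejected by name.
    """
    frame = daily.frame.copy()
    scale: dict[str, tuple[float, float]] = {}
    for v in variables:
        if v not in frame.columns:
            raise KeyError(f"no such variable: {v!r}")
        vals = frame[v].astype(float)
        n = vals.notna().sum()
        if n < 2:
            raise ValueError(f"{v!r}: need >=2 non-missing values, have {n}")
        m = vals.mean()
        s = vals.std(ddof=1)
        if not s > 0:
            raise ValueError(f"{v!r}: zero variance, cannot standardize")
        frame[v] = (vals - m) / s
        scale[v] = (float(m), float(s))
    return DailyDataset(frame, min_valid_hours=daily.min_valid_hours), scale
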