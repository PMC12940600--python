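"""In-memory containers: hourly monitoring records and QC-gated daily data.

Both are thin validated wrappers around a pandas DataFrame; the frame is the
working surface, the wrapper enforces the container invariants once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scenario import POLLUTANTS, MET_VARS

__all__ = ["HourlyDataset", "DailyDataset", "HOURLY_COLUMNS"]

HOURLY_COLUMNS = ["timestamp"] + POLLUTANTS + MET_VARS


@dataclass
class HourlyDataset:
    """Timestamped hourly pollutant and meteorology records.

    Invariants: timestamps unique, strictly increasing, on the hour;
    pollutant concentrations non-negative where present.
    """

    frame: pd.DataFrame
    invalid_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        if "timestamp" not in df.columns:
            raise ValueError("hourly frame needs a 'timestamp' column")
        ts = pd.to_datetime(df["timestamp"])
        if ts.duplicated().any():
            dup = ts[ts.duplicated()].iloc[0]
            raise ValueError(f"duplicated timestamp: {dup}")
        if not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if ((ts.dt.minute != 0) | (ts.dt.second != 0)).any():
            raise ValueError("timestamps must be on the hour")
        df = df.copy()
        df["timestamp"] = ts
        for pol in POLLUTANTS:
            if pol in df.columns:
                neg = df[pol] < 0
                if neg.any():
                    raise ValueError(f"negative {pol} concentration at row {int(neg.idxmax())}")
        self.frame = df.reset_index(drop=True)

    @property
    def variables(self) -> list[str]:
        return [c for c in self.frame.columns if c != "timestamp"]

    @property
    def dates(self) -> pd.Series:
        return self.frame["timestamp"].dt.date

    def __len__(self) -> int:
        return len(self.frame)

    def equals(self, other: "HourlyDataset") -> bool:
        return self.frame.equals(other.frame)


@dataclass
class DailyDataset:
    """QC-gated daily means with phase labels and valid-hour counts.

    One row per date; a variable's daily mean is present iff its valid-hours
    count met the completeness threshold during aggregation.
    """

    frame: pd.DataFrame
    min_valid_hours: int = 18

    def __post_init__(self):
        df = self.frame
        if "date" not in df.columns:
            raise ValueError("daily frame needs a 'date' column")
        if df["date"].duplicated().any():
            raise ValueError("more than one row per date")
        self.frame = df.reset_index(drop=True)

    @property
    def variables(self) -> list[str]:
        return [
            c for c in self.frame.columns
            if c not in ("date", "phase", "weekday") and not c.endswith("_n")
        ]

    def __len__(self) -> int:
        return len(self.frame)

    def phase_values(self, variable: str, phase: str) -> np.ndarray:
        """Non-missing daily values of ``variable`` within ``phase``."""
        sub = self.frame.loc[self.frame["phase"] == phase, variable]
        return sub.dropna().to_numpy()
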