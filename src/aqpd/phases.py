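"""Intervention-phase calendar: ordered, non-overlapping named date intervals.

The 2020 Ilo study window is split into six phases by government decree,
with the Pre-Pandemic interval serving as the reference category for every
contrast downstream (percent changes, regression indicators, HIA deltas).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = ["PhaseInterval", "PhaseCalendar", "default_ilo_calendar"]


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


@dataclass(frozen=True)
class PhaseInterval:
    """A named calendar interval, inclusive on both ends."""

    name: str
    start: dt.date
    end: dt.date

    def __post_init__(self):
        object.__setattr__(self, "start", _as_date(self.start))
        object.__setattr__(self, "end", _as_date(self.end))
        if self.end < self.start:
            raise ValueError(f"phase {self.name!r}: end {self.end} before start {self.start}")

    def __contains__(self, date) -> bool:
        return self.start <= _as_date(date) <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class PhaseCalendar:
    """Chronologically ordered, non-overlapping phase intervals.

    Parameters
    ----------
    phases
        Ordered intervals. Must not overlap and must be sorted by start date.
    reference_phase
        Name of the baseline phase used as reference in all contrasts.
    """

    phases: list[PhaseInterval] = field(default_factory=list)
    reference_phase: str = "Pre-Pandemic"

    def __post_init__(self):
        self.phases = [
            p if isinstance(p, PhaseInterval) else PhaseInterval(*p) for p in self.phases
        ]
        if not self.phases:
            raise ValueError("calendar needs at least one phase")
        names = [p.name for p in self.phases]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phase names")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start <= a.end:
                raise ValueError(f"phases {a.name!r} and {b.name!r} overlap or are out of order")
        if self.reference_phase not in names:
            raise ValueError(f"reference phase {self.reference_phase!r} not in calendar")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.phases]

    @property
    def start(self) -> dt.date:
        return self.phases[0].start

    @property
    def end(self) -> dt.date:
        return self.phases[-1].end

    def assign(self, date) -> str:
        """Return the phase label containing ``date``.

        Raises
        ------
        KeyError
            If the date falls outside every interval.
        """
        d = _as_date(date)
        for p in self.phases:
            if d in p:
                return p.name
        raise KeyError(f"date {d} outside the phase calendar ({self.start}..{self.end})")

    def assign_series(self, dates: pd.Series | pd.Index) -> pd.Series:
        """Vectorised phase assignment; dates outside the calendar raise."""
        d = pd.to_datetime(pd.Series(np.asarray(dates))).dt.date
        starts = np.array([p.start for p in self.phases])
        idx = np.searchsorted(starts, d.to_numpy(), side="right") - 1
        if (idx < 0).any():
            bad = d[idx < 0].iloc[0]
            raise KeyError(f"date {bad} outside the phase calendar")
        labels = np.array(self.names, dtype=object)[idx]
        ends = np.array([p.end for p in self.phases])[idx]
        over = d.to_numpy() > ends
        if over.any():
            raise KeyError(f"date {d[over].iloc[0]} outside the phase calendar")
        out = pd.Series(labels, index=getattr(dates, "index", None))
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reference_phase": self.reference_phase,
            "phases": [
                {"name": p.name, "start": p.start.isoformat(), "end": p.end.isoformat()}
                for p in self.phases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseCalendar":
        phases = [PhaseInterval(e["name"], e["start"], e["end"]) for e in d["phases"]]
        return cls(phases=phases, reference_phase=d.get("reference_phase", phases[0].name))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhaseCalendar":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_ilo_calendar() -> PhaseCalendar:
    """The six 2020 decree-defined phases used throughout the analysis."""
    return PhaseCalendar(
        phases=[
            PhaseInterval("Pre-Pandemic", dt.date(2020, 1, 1), dt.date(2020, 3, 15)),
            PhaseInterval("Strict Lockdown", dt.date(2020, 3, 16), dt.date(2020, 5, 3)),
            PhaseInterval("Phase 1", dt.date(2020, 5, 4), dt.date(2020, 6, 4)),
            PhaseInterval("Phase 2", dt.date(2020, 6, 5), dt.date(2020, 6, 30)),
            PhaseInterval("Phase 3", dt.date(2020, 7, 1), dt.date(2020, 9, 26)),
            PhaseInterval("Phase 4", dt.date(2020, 9, 27), dt.date(2020, 12, 31)),
        ],
        reference_phase="Pre-Pandemic",
    )
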