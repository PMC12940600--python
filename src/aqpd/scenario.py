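"""Scenario configuration for the synthetic hourly monitoring record.

A :class:`ScenarioConfig` holds every data-generating assumption: the phase
calendar, per-phase pollutant mean levels, seasonal and diurnal meteorology,
wind–PM dispersion coupling, point-source SO2 spikes, the NO2 weekday traffic
signal, per-pollutant noise, block missingness, and the RNG seed. The default
configuration targets the statistical structure of the Ilo 2020 monitoring
year: phase means equal the published per-phase daily means, meteorology
follows the austral seasonal cycle (warmest in January), and SO2/O3 lose
coverage late in the year through instrument-outage blocks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import yaml

from .phases import PhaseCalendar, default_ilo_calendar

__all__ = ["ScenarioConfig", "MissingBlock", "default_ilo_config", "POLLUTANTS", "MET_VARS"]

POLLUTANTS = ["pm10", "pm25", "no2", "o3", "so2"]
MET_VARS = ["temp", "ws", "wd", "rh", "pres", "rad"]

#: Published per-phase daily means (µg/m³) used as generator targets.
ILO_PHASE_MEANS: dict[str, dict[str, float]] = {
    "pm10": {
        "Pre-Pandemic": 50.93, "Strict Lockdown": 53.04, "Phase 1": 43.90,
        "Phase 2": 50.00, "Phase 3": 35.07, "Phase 4": 42.74,
    },
    "pm25": {
        "Pre-Pandemic": 12.60, "Strict Lockdown": 14.51, "Phase 1": 16.91,
        "Phase 2": 15.04, "Phase 3": 10.91, "Phase 4": 11.96,
    },
    "no2": {
        "Pre-Pandemic": 5.81, "Strict Lockdown": 4.77, "Phase 1": 4.81,
        "Phase 2": 4.88, "Phase 3": 4.73, "Phase 4": 5.06,
    },
    "o3": {
        "Pre-Pandemic": 14.59, "Strict Lockdown": 16.18, "Phase 1": 21.15,
        "Phase 2": 26.09, "Phase 3": 30.31, "Phase 4": 25.47,
    },
    "so2": {
        "Pre-Pandemic": 25.57, "Strict Lockdown": 24.17, "Phase 1": 18.90,
        "Phase 2": 14.00, "Phase 3": 10.18, "Phase 4": 8.85,
    },
}


@dataclass(frozen=True)
class MissingBlock:
    """A block of forced missingness for one variable over a date interval."""

    variable: str
    start: dt.date
    end: dt.date

    def __post_init__(self):
        for f in ("start", "end"):
            v = getattr(self, f)
            if not isinstance(v, dt.date):
                object.__setattr__(self, f, dt.date.fromisoformat(str(v)))
        if self.end < self.start:
            raise ValueError(f"missing block for {self.variable!r}: end before start")


@dataclass
class ScenarioConfig:
    """All parameters of the synthetic data-generating process.

    Noise is modelled as a day-level Gaussian component with standard
    deviation ``noise_sd[v]`` shared by all hours of a day, plus independent
    hourly jitter with half that spread; hourly values are truncated at zero.
    The day-level component carries the day-to-day (synoptic) variability
    that daily summary statistics see, while the jitter provides sub-daily
    texture; with pollutant levels well above zero the truncation bias is
    negligible, so configured phase means remain the expected daily means.
    """

    calendar: PhaseCalendar = field(default_factory=default_ilo_calendar)
    phase_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(m) for p, m in ILO_PHASE_MEANS.items()}
    )

    # meteorology: seasonal sinusoids with austral phase (maxima in January
    # unless peak_doy says otherwise), plus diurnal cycles
    temp_mean: float = 21.0          # °C
    temp_seasonal_amp: float = 4.0   # °C (median ~25 in summer, ~17 in winter)
    temp_diurnal_amp: float = 3.0    # °C, afternoon maximum
    temp_peak_doy: int = 15          # mid-January
    rh_mean: float = 70.0            # %
    rh_seasonal_amp: float = 5.0     # %, peaking in austral winter
    rad_mean: float = 250.0          # W/m², daily-mean scale
    rad_seasonal_amp: float = 120.0  # W/m²
    pres_mean: float = 1010.0        # hPa
    pres_seasonal_amp: float = 2.0   # hPa, winter maximum

    wind_mean: float = 3.0           # m/s
    wind_sd: float = 1.0             # m/s, day-to-day
    wind_pm_slope: float = -2.0      # µg/m³ per m/s, applied to PM10 & PM2.5

    so2_spike_rate: float = 0.1      # events/day in the reference phase
    so2_spike_mean: float = 40.0     # µg/m³ magnitude in the reference phase
    so2_spike_hours: int = 3         # duration of one plume passage

    no2_weekday_uplift: float = 0.15  # fractional weekday traffic uplift

    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "pm10": 14.0, "pm25": 4.0, "no2": 0.7, "o3": 4.0, "so2": 5.0,
            "temp": 1.2, "ws": 0.3, "rh": 4.0, "pres": 1.0, "rad": 30.0,
        }
    )

    #: AR(1) coefficient on the day-level noise; 0 disables autocorrelation.
    ar1_rho: float = 0.0

    missing_blocks: list[MissingBlock] = field(default_factory=list)
    seed: int = 123

    def __post_init__(self):
        for pol, means in self.phase_means.items():
            for ph, m in means.items():
                if not m > 0:
                    raise ValueError(f"phase mean for {pol}/{ph} must be > 0, got {m}")
            missing = set(self.calendar.names) - set(means)
            if missing:
                raise ValueError(f"{pol}: no phase mean for {sorted(missing)}")
        for v, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{v!r}] must be >= 0")
        if self.wind_pm_slope > 0:
            raise ValueError("wind_pm_slope must be <= 0 (stronger wind disperses PM)")
        self.missing_blocks = [
            b if isinstance(b, MissingBlock) else MissingBlock(*b) for b in self.missing_blocks
        ]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calendar"] = self.calendar.to_dict()
        d["missing_blocks"] = [
            {"variable": b.variable, "start": b.start.isoformat(), "end": b.end.isoformat()}
            for b in self.missing_blocks
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["calendar"] = PhaseCalendar.from_dict(d["calendar"])
        d["missing_blocks"] = [
            MissingBlock(b["variable"], b["start"], b["end"]) for b in d.get("missing_blocks", [])
        ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_ilo_config(seed: int = 123) -> ScenarioConfig:
    """Default scenario emulating the Ilo 2020 monitoring year.

    Per-phase pollutant means are the published daily means; instrument
    outages truncate SO2 coverage in Phase 4 to its first nine days
    (27 Sep–5 Oct) and O3 coverage to its first 19 days.
    """
    return ScenarioConfig(
        seed=seed,
        missing_blocks=[
            MissingBlock("so2", dt.date(2020, 10, 6), dt.date(2020, 12, 31)),
            MissingBlock("o3", dt.date(2020, 10, 16), dt.date(2020, 12, 31)),
        ],
    )
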