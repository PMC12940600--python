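"""Synthetic hourly monitoring record generator.

Generates an hourly pollutant + meteorology series with the statistical
structure the downstream analysis assumes: per-phase mean levels, austral
seasonal cycles in meteorology, a negative wind–PM dispersion coupling,
Poisson-timed SO2 point-source spikes, a weekday traffic uplift in NO2,
day-level plus hourly Gaussian noise truncated at zero, and block
missingness emulating instrument outages. A fixed seed yields bit-identical
output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import HourlyDataset
from .scenario import MET_VARS, POLLUTANTS, MissingBlock, ScenarioConfig

__all__ = ["generate_scenario", "inject_missingness"]

_TWO_PI = 2.0 * np.pi
_YEAR = 365.25


def _seasonal(doy: np.ndarray, mean: float, amp: float, peak_doy: float) -> np.ndarray:
    return mean + amp * np.cos(_TWO_PI * (doy - peak_doy) / _YEAR)


def _day_noise(rng: np.random.Generator, n_days: int, sd: float, rho: float) -> np.ndarray:
    """Day-level noise, optionally AR(1) with stationary sd equal to ``sd``."""
    eps = rng.normal(0.0, 1.0, n_days)
    if rho == 0.0 or sd == 0.0:
        return sd * eps
    x = np.empty(n_days)
    x[0] = eps[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n_days):
        x[t] = rho * x[t - 1] + scale * eps[t]
    return sd * x


def generate_scenario(config: ScenarioConfig) -> HourlyDataset:
    """Simulate the hourly record over the configured calendar window.

    The expected daily mean of every pollutant equals its configured phase
    mean: structural signals (SO2 spikes, NO2 weekday uplift, wind–PM
    coupling) are mean-centred so they add variance, not bias.
    """
    cal = config.calendar
    n_days = (cal.end - cal.start).days + 1
    if n_days < 1:
        raise ValueError("simulation window must cover at least one day")

    ts = pd.date_range(
        start=pd.Timestamp(cal.start),
        end=pd.Timestamp(cal.end) + pd.Timedelta(hours=23),
        freq="h",
    )
    n_hours = len(ts)
    day_idx = ((ts - ts[0]).days).to_numpy()
    doy = ts.dayofyear.to_numpy().astype(float)
    hour = ts.hour.to_numpy().astype(float)
    dates = pd.Series(ts.date)
    # Mon..Fri flag per hour
    weekday = np.asarray(ts.dayofweek < 5)

    phase_per_day = cal.assign_series(pd.Series(pd.date_range(cal.start, cal.end, freq="D")))
    phase_hourly = phase_per_day.to_numpy()[day_idx]

    rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray] = {}

    # --- meteorology ------------------------------------------------------
    sd = config.noise_sd
    rho = config.ar1_rho

    temp = (
        _seasonal(doy, config.temp_mean, config.temp_seasonal_amp, config.temp_peak_doy)
        + config.temp_diurnal_amp * np.cos(_TWO_PI * (hour - 14.0) / 24.0)
        + _day_noise(rng, n_days, sd.get("temp", 0.0), rho)[day_idx]
        + rng.normal(0.0, sd.get("temp", 0.0) / 2.0, n_hours)
    )
    cols["temp"] = temp

    wind_day = np.clip(
        config.wind_mean + _day_noise(rng, n_days, config.wind_sd, rho), 0.1, None
    )
    ws = np.clip(wind_day[day_idx] + rng.normal(0.0, sd.get("ws", 0.0), n_hours), 0.0, None)
    cols["ws"] = ws
    cols["wd"] = rng.uniform(0.0, 360.0, n_hours)

    rh_peak = config.temp_peak_doy + _YEAR / 2.0  # humid austral winter
    rh = (
        _seasonal(doy, config.rh_mean, config.rh_seasonal_amp, rh_peak)
        + _day_noise(rng, n_days, sd.get("rh", 0.0), rho)[day_idx]
        + rng.normal(0.0, sd.get("rh", 0.0) / 2.0, n_hours)
    )
    cols["rh"] = np.clip(rh, 0.0, 100.0)

    pres = (
        _seasonal(doy, config.pres_mean, config.pres_seasonal_amp, rh_peak)
        + _day_noise(rng, n_days, sd.get("pres", 0.0), rho)[day_idx]
    )
    cols["pres"] = pres

    # solar radiation: seasonal daily-mean level shaped by a daylight profile
    # normalised so the daily mean matches the seasonal level
    daylight = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
    daylight /= daylight[:24].mean()
    rad_level = _seasonal(doy, config.rad_mean, config.rad_seasonal_amp, config.temp_peak_doy)
    rad = rad_level * daylight + rng.normal(0.0, sd.get("rad", 0.0), n_hours) * (daylight > 0)
    cols["rad"] = np.clip(rad, 0.0, None)

    # --- pollutants -------------------------------------------------------
    mean_of = {
        pol: np.array([config.phase_means[pol][ph] for ph in phase_hourly])
        for pol in POLLUTANTS
    }
    ref = cal.reference_phase

    for pol in POLLUTANTS:
        base = mean_of[pol].copy()

        if pol in ("pm10", "pm25"):
            base = base + config.wind_pm_slope * (wind_day[day_idx] - config.wind_mean)

        if pol == "no2" and config.no2_weekday_uplift != 0.0:
            # centred at the long-run weekday fraction so phase means hold
            mult = 1.0 + config.no2_weekday_uplift * (weekday.astype(float) - 5.0 / 7.0)
            base = base * mult

        spike = np.zeros(n_hours)
        if pol == "so2" and config.so2_spike_rate > 0.0 and config.so2_spike_mean > 0.0:
            ref_mean = config.phase_means["so2"][ref]
            phase_scale = {
                ph: config.phase_means["so2"][ph] / ref_mean for ph in cal.names
            }
            n_events = rng.poisson(config.so2_spike_rate, n_days)
            for d in np.nonzero(n_events)[0]:
                scale = phase_scale[phase_per_day.iloc[d]]
                for _ in range(n_events[d]):
                    start_h = int(rng.integers(0, 24))
                    mag = rng.exponential(config.so2_spike_mean * scale)
                    lo = d * 24 + start_h
                    spike[lo: lo + config.so2_spike_hours] += mag
            # remove the expected spike contribution so phase means hold
            exp_daily = (
                config.so2_spike_rate
                * config.so2_spike_mean
                * config.so2_spike_hours
                / 24.0
            )
            scale_hourly = np.array([phase_scale[ph] for ph in phase_hourly])
            base = base - exp_daily * scale_hourly

        noise = (
            _day_noise(rng, n_days, sd.get(pol, 0.0), rho)[day_idx]
            + rng.normal(0.0, sd.get(pol, 0.0) / 2.0, n_hours)
        )
        cols[pol] = np.clip(base + spike + noise, 0.0, None)

    frame = pd.DataFrame({"timestamp": ts})
    for c in POLLUTANTS + MET_VARS:
        frame[c] = cols[c]
    data = HourlyDataset(frame)
    if config.missing_blocks:
        data = inject_missingness(data, config.missing_blocks)
    return data


def inject_missingness(
    data: HourlyDataset, blocks: list[MissingBlock | tuple]
) -> HourlyDataset:
    """Blank one variable over each date interval; other cells untouched."""
    frame = data.frame.copy()
    dates = frame["timestamp"].dt.date
    for block in blocks:
        if not isinstance(block, MissingBlock):
            block = MissingBlock(*block)
        if block.variable not in frame.columns:
            raise KeyError(f"unknown variable {block.variable!r}")
        mask = (dates >= block.start) & (dates <= block.end)
        frame.loc[mask, block.variable] = np.nan
    return HourlyDataset(frame, invalid_counts=dict(data.invalid_counts))
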