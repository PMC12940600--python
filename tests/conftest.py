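import dataclasses

import pytest

from aqpd import aggregate_daily, default_ilo_config, generate_scenario


@pytest.fixture(scope="session")
def default_config():
    return default_ilo_config(seed=123)


@pytest.fixture(scope="session")
def default_hourly(default_config):
    return generate_scenario(default_config)


@pytest.fixture(scope="session")
def default_daily(default_config, default_hourly):
    return aggregate_daily(default_hourly, 18, default_config.calendar)


def make_quiet_config(seed: int = 123, **overrides):
    """Default scenario with every stochastic/structural effect disabled:
    zero noise, no SO2 spikes, no wind-PM coupling, no weekday uplift, no
    missingness. Daily means then equal configured phase means exactly."""
    cfg = default_ilo_config(seed=seed)
    quiet = dict(
        noise_sd={k: 0.0 for k in cfg.noise_sd},
        so2_spike_rate=0.0,
        wind_sd=0.0,
        wind_pm_slope=0.0,
        no2_weekday_uplift=0.0,
        missing_blocks=[],
    )
    quiet.update(overrides)
    return dataclasses.replace(cfg, **quiet)


@pytest.fixture(scope="session")
def quiet_config():
    return make_quiet_config()


@pytest.fixture(scope="session")
def quiet_daily(quiet_config):
    return aggregate_daily(generate_scenario(quiet_config), 18, quiet_config.calendar)
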