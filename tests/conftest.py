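import numpy as np
import pandas as pd
import pytest

from ttherm import Individual, SyntheticConfig
from ttherm.synthetic import simulate_activity, simulate_core_temperature, simulate_environment


@pytest.fixture(scope="session")
def fast_config() -> SyntheticConfig:
    """Small, quiet trial used by most unit tests."""
    return SyntheticConfig(days=4, seed=11)


@pytest.fixture(scope="session")
def quiet_config() -> SyntheticConfig:
    """Noise-free sinusoidal environment for closed-form checks."""
    return SyntheticConfig(
        days=6, noise_sd=0.0, day_effect_sd=0.0, sun_excess_peak=0.0, seed=0
    )


@pytest.fixture(scope="session")
def small_env(fast_config):
    return simulate_environment(fast_config)


@pytest.fixture(scope="session")
def small_trial(fast_config, small_env):
    shade, sun = small_env
    states, bursts = simulate_activity(shade, fast_config)
    core = simulate_core_temperature(
        shade, sun, states, Individual("T01", 70.0), fast_config
    )
    return {"shade": shade, "sun": sun, "states": states, "bursts": bursts, "core": core}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_series(values, start="2014-04-01 00:00", freq="15min") -> pd.Series:
    return pd.Series(
        np.asarray(values, float),
        index=pd.date_range(start, periods=len(values), freq=freq),
    )
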