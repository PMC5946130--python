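import dataclasses

import numpy as np
import pandas as pd
import pytest

from antnest_seep import scenario
from antnest_seep.synthetic_data import ScenarioConfig, SourceEvent


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scenario():
    """Two-hour, 0.5-Hz campaign with one boxcar source — fast everywhere."""
    return ScenarioConfig(
        duration=7200.0,
        gas_rate=0.5,
        sources=(SourceEvent(d13c_source=-69.0, start=2400.0,
                             duration=1200.0, peak_excess=1.0,
                             shape="boxcar"),),
        ch4_noise_sd=0.0,
        d13c_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def noisy(small_scenario):
    return dataclasses.replace(small_scenario, ch4_noise_sd=0.005,
                               d13c_noise_sd=0.8)


def noiseless(config: ScenarioConfig) -> ScenarioConfig:
    return dataclasses.replace(config, ch4_noise_sd=0.0, d13c_noise_sd=0.0)


@pytest.fixture
def mixing_points():
    """Exact two-reservoir mixing samples: background 1.82 ppm at -47
    permil plus a -69 permil source, no noise."""
    c_a, d_a, d_s = 1.82, -47.0, -69.0
    excess = np.linspace(0.05, 1.0, 40)
    c = c_a + excess
    d = (c_a * d_a + excess * d_s) / c
    return c, d


@pytest.fixture
def weather_8d():
    return pd.DataFrame(
        np.random.default_rng(0).normal(size=(300, 6)),
        columns=["temperature", "pressure", "dewpoint", "humidity",
                 "rainfall", "windspeed"],
    )
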