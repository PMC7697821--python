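import numpy as np
import pandas as pd
import pytest

from optdeg import ScenarioConfig, default_layout


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180110)


@pytest.fixture
def small_scenario():
    """Tiny deterministic scenario: 4 sensors, 2 h, minute cadence."""
    layout = default_layout().iloc[[0, 5, 10, 15]].reset_index(drop=True)
    return ScenarioConfig(
        name="tiny", layout=layout, start="2018-01-10 06:00",
        duration_min=120, sunrise_hour=7.0, sunset_hour=17.0,
        t_night_base=16.0, t_day_amplitude=8.0,
        noise_sd_t=0.2, noise_sd_rh=0.5, dropout=0.0, seed=42)


@pytest.fixture
def readings_csv(tmp_path):
    """Well-formed 3-row readings file."""
    p = tmp_path / "readings.csv"
    p.write_text(
        "timestamp,sensor_id,T,RH,light\n"
        "2018-01-10T06:00:00,S01,15.2,74.1,0\n"
        "2018-01-10T06:01:00,S01,15.3,74.0,0\n"
        "2018-01-10T06:00:00,S02,16.0,72.5,0\n")
    return p


@pytest.fixture
def layout_csv(tmp_path):
    p = tmp_path / "layout.csv"
    default_layout().to_csv(p, index=False)
    return p
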