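import numpy as np
import pytest

from haze_ccdea.panel import IndicatorPanel
from haze_ccdea.synthetic import WeatherGenConfig, gen_daily_met, gen_pm25


@pytest.fixture
def two_dmu_panel() -> IndicatorPanel:
    """A(x=1, y=2) dominates B(x=1, y=1); deterministic."""
    z = np.zeros((2, 1))
    return IndicatorPanel(
        dmu_ids=("A", "B"),
        input_names=("x",),
        output_names=("y",),
        input_mean=np.array([[1.0], [1.0]]),
        input_sd=z,
        output_mean=np.array([[2.0], [1.0]]),
        output_sd=z,
    )


@pytest.fixture(scope="session")
def met_year():
    """One synthetic city-year of daily weather, fixed seed."""
    return gen_daily_met(WeatherGenConfig(n_days=365), seed=123)


@pytest.fixture(scope="session")
def air_year(met_year):
    return gen_pm25(met_year, seed=456)
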