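import numpy as np
import pandas as pd
import pytest

from microfutures import bias
from microfutures.fixtures import (FixtureConfig, gen_dem, gen_logger_obs,
                                   gen_weather_series)


@pytest.fixture(scope="session")
def cfg():
    return FixtureConfig(seed=7, years=(2001,))


@pytest.fixture(scope="session")
def landscape(cfg):
    return gen_dem(cfg)


@pytest.fixture(scope="session")
def weather(cfg):
    """One year of daily weather for the south-western coarse cell."""
    return gen_weather_series(cfg, "observed")[(0, 0)]


@pytest.fixture(scope="session")
def hourly_month(cfg, weather):
    """One disaggregated month of hourly weather."""
    return bias.disaggregate_series(weather.iloc[:30], cfg.lat, cfg.lon, seed=3)


@pytest.fixture(scope="session")
def logger_fixture(cfg, landscape, hourly_month):
    dem, mask = landscape
    return gen_logger_obs(cfg, dem, mask, hourly_month)


def two_bowl_dem(n=16, cell=100.0):
    """Two depressions joined by a saddle; the western bowl floor is higher,
    so its pour point spills east across the saddle."""
    from microfutures.rasters import RasterGrid

    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    u, v = jj / (n - 1), ii / (n - 1)
    z = 100.0 * np.ones((n, n))
    z -= 55.0 * np.exp(-(((u - 0.3) / 0.18) ** 2 + ((v - 0.5) / 0.25) ** 2))
    z -= 80.0 * np.exp(-(((u - 0.72) / 0.18) ** 2 + ((v - 0.5) / 0.25) ** 2))
    return RasterGrid(z.astype(np.float32), 0.0, n * cell, cell)
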