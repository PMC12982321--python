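import numpy as np
import pandas as pd
import pytest

import phenoselect as ps
from phenoselect.synthetic import SyntheticConfig, three_covariate_truth


@pytest.fixture(scope="session")
def small_bundle():
    """Single-covariate truth, 4 stations x 10 years (~36 environments)."""
    cfg = SyntheticConfig(n_stations=4, n_years=10, seed=20240901)
    return ps.generate_bundle(cfg)


@pytest.fixture(scope="session")
def multi_bundle():
    """Three-covariate spring-phase truth, 6 stations x 12 years."""
    cfg = SyntheticConfig(
        n_stations=6, n_years=12, seed=20240902, truth=three_covariate_truth()
    )
    return ps.generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return ps.WeatherIndex(small_bundle.weather)


@pytest.fixture(scope="session")
def multi_index(multi_bundle):
    return ps.WeatherIndex(multi_bundle.weather)


@pytest.fixture()
def flat_weather():
    """One station, two years, constant covariates (tas at 25 deg C)."""
    dates = pd.date_range("2000-01-01", "2001-12-31", freq="D")
    return pd.DataFrame(
        {
            "station_id": "S1",
            "date": dates,
            "tasmin": 20.0,
            "tas": 25.0,
            "tasmax": 30.0,
            "RH": 70.0,
            "pr": 1.0,
            "GR": 1500.0,
        }
    )
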