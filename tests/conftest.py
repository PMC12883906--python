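import numpy as np
import pandas as pd
import pytest

from algaecast import (
    ClimateSpec,
    HourlyMeteoSeries,
    SiteInfo,
    generate_archive,
)


def make_hourly_frame(start, n_hours, **overrides):
    """Constant-valued hourly forcing frame, overridable per column."""
    index = pd.date_range(start, periods=n_hours, freq="h")
    data = {
        "air_temp": 20.0,
        "dewpoint": 10.0,
        "wind_speed": 2.0,
        "pressure": 97.0,
        "shortwave": 0.0,
        "precip": 0.0,
    }
    data.update(overrides)
    return pd.DataFrame(
        {k: (v if np.ndim(v) else np.full(n_hours, float(v))) for k, v in data.items()},
        index=index,
    )


@pytest.fixture
def constant_series():
    def _make(start="2021-06-01", n_hours=24, **overrides):
        return HourlyMeteoSeries(make_hourly_frame(start, n_hours, **overrides),
                                 site=SiteInfo())
    return _make


@pytest.fixture(scope="session")
def climate_spec():
    return ClimateSpec(seed=20240915)


@pytest.fixture(scope="session")
def two_year_archive(climate_spec):
    """Hourly archive for 2020-2021 shared across tests (generation is slow)."""
    return generate_archive(climate_spec, 2020, 2021)
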