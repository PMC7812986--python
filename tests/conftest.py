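import numpy as np
import pandas as pd
import pytest

from demandcast import CovariateCalendar, DemandSeries, SyntheticConfig, generate


def flat_calendar(start, n_days, **overrides):
    """All-zero covariate calendar (no holidays, dry, mild, no flu)."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    frame = pd.DataFrame(
        {
            "bank_holiday": False,
            "school_holiday": False,
            "precipitation": 0.0,
            "tmax": 15.0,
            "tmin": 8.0,
            "flu_hits": 10.0,
            "carnival": False,
            "christmas": False,
        },
        index=dates,
    )
    for key, value in overrides.items():
        frame[key] = value
    return CovariateCalendar(frame)


@pytest.fixture
def toy_series():
    """Counts 1..14 on consecutive days (day 1 = 2020-01-06, a Monday)."""
    return DemandSeries("2020-01-06", np.arange(1, 15))


@pytest.fixture
def toy_calendar(toy_series):
    return flat_calendar(toy_series.start_date, len(toy_series))


@pytest.fixture(scope="session")
def small_world():
    """A 260-day simulated hospital with default structure (seed 11)."""
    config = SyntheticConfig(n_days=260, seed=11)
    series, calendar = generate(config)
    return config, series, calendar


@pytest.fixture(scope="session")
def small_matrix(small_world):
    from demandcast import build_model_matrix

    _, series, calendar = small_world
    return build_model_matrix(series, calendar, 1)
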