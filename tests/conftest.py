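import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stormexcess as se

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_quiet_panel():
    """3 counties x 6 years, no storms."""
    cfg = se.SimConfig(n_counties=3, n_years=6, storm_rate=0.0, seed=42)
    panel, calendar, truth = se.generate_panel(cfg)
    return cfg, panel, calendar, truth


@pytest.fixture(scope="session")
def stormy_panel():
    """5 counties x 8 years with storms and injected excess."""
    cfg = se.SimConfig(
        n_counties=5, n_years=8, storm_rate=0.6, seed=7,
        excess_multiplier_month0=1.3, excess_multiplier_month1=1.2,
    )
    panel, calendar, truth = se.generate_panel(cfg)
    return cfg, panel, calendar, truth


def wind_df(rows):
    """rows: (county, iso-date, storm, knots)."""
    return pd.DataFrame(rows, columns=["county_id", "date", "storm_name", "wind_knots"])


@pytest.fixture()
def make_wind():
    return wind_df
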