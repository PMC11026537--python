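import logging

import numpy as np
import pandas as pd
import pytest

from reefstress import fixture_table1, table1_ahs_lookup

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return fixture_table1()


@pytest.fixture(scope="session")
def ahs_lookup() -> dict:
    return table1_ahs_lookup()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20190315)


def make_constant_day_series(temp: float = 29.5, n_days: int = 1,
                             start: str = "2019-02-01"):
    """A gap-free 20-min series at constant temperature (local UTC-10)."""
    from reefstress import TemperatureSeries
    idx = pd.date_range(start=pd.Timestamp(start, tz="Etc/GMT+10"),
                        periods=72 * n_days, freq="20min")
    return TemperatureSeries(site="LTER 1", depth_m=10.0,
                             samples=pd.Series(temp, index=idx))


@pytest.fixture()
def weekly_frame():
    """Builder for weekly-mean frames with all-valid weeks."""
    def build(means, valid=None, start="2018-08-01"):
        import datetime as dt
        means = list(means)
        start_d = dt.date.fromisoformat(start)
        return pd.DataFrame({
            "week_start": [start_d + dt.timedelta(days=7 * i)
                           for i in range(len(means))],
            "weekly_mean": means,
            "n_complete_days": 7,
            "valid": valid if valid is not None else [True] * len(means),
        })
    return build
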