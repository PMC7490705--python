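import numpy as np
import pandas as pd
import pytest

from seedflux.influx import ArrivalSchedule, RateSeries

BASE = pd.Timestamp("2015-08-13")


def day(n: int) -> pd.Timestamp:
    """Day-of-season n as a calendar date."""
    return BASE + pd.Timedelta(days=n)


def make_series(points, taxon="t") -> RateSeries:
    """RateSeries from (day-of-season, seeds-per-container) pairs."""
    days, vals = zip(*points)
    return RateSeries(
        taxon=taxon,
        dates=pd.DatetimeIndex([day(d) for d in days]),
        seeds_per_container=np.array(vals, dtype=float),
        n_containers=np.ones(len(days), dtype=np.int64),
    )


def make_arrivals(points) -> ArrivalSchedule:
    """ArrivalSchedule from (day-of-season, containers) pairs."""
    days, counts = zip(*points)
    return ArrivalSchedule(
        dates=pd.DatetimeIndex([day(d) for d in days]),
        containers=np.array(counts, dtype=np.int64),
    )


@pytest.fixture
def three_point_series() -> RateSeries:
    return make_series([(10, 2.0), (20, 4.0), (40, 10.0)])
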