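"""Seasonal seed-influx estimation by K-nearest-neighbours regression.

Surveillance visits every ~2 weeks measure seeds per container for a subset of
arrivals; container arrivals themselves are recorded daily.  Seeds per
container on every arrival date is predicted as the unweighted mean of the
K = 2 nearest sampling dates (nearest in calendar days), and the seasonal
total influx is

    N = sum_i s_hat_i * c_i

over arrival dates i, where s_hat_i is the predicted seeds-per-container and
c_i the number of containers arriving that date.  Models are independent per
taxon and season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrivalSchedule",
    "RateSeries",
    "InfluxEstimate",
    "aggregate_samples",
    "knn_predict",
    "estimate_total_influx",
]


def _as_days(dates) -> np.ndarray:
    """Coerce anything date-like to integer days since epoch."""
    arr = pd.to_datetime(pd.Index(np.atleast_1d(dates)))
    return arr.values.astype("datetime64[D]").astype(np.int64)


@dataclass(frozen=True)
class ArrivalSchedule:
    """Container arrivals: one row per arrival date.

    Dates must be unique and counts nonnegative.
    """

    dates: pd.DatetimeIndex
    containers: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dates", pd.DatetimeIndex(self.dates))
        object.__setattr__(
            self, "containers", np.asarray(self.containers, dtype=np.int64))
        if len(self.dates) != len(self.containers):
            raise ValueError("dates and containers differ in length")
        if self.dates.has_duplicates:
            raise ValueError("arrival dates must be unique")
        if (self.containers < 0).any():
            raise ValueError("container counts must be nonnegative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ArrivalSchedule":
        return cls(pd.DatetimeIndex(pd.to_datetime(frame["date"])),
                   frame["containers"].to_numpy())

    @property
    def total_containers(self) -> int:
        return int(self.containers.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "containers": self.containers})


@dataclass(frozen=True)
class RateSeries:
    """Observed seeds-per-container by sampling date for one taxon.

    ``seeds_per_container`` is the per-visit mean over all sampled containers,
    zero-seed containers included in the denominator.
    """

    taxon: str
    dates: pd.DatetimeIndex
    seeds_per_container: np.ndarray
    n_containers: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dates", pd.DatetimeIndex(self.dates))
        object.__setattr__(self, "seeds_per_container",
                           np.asarray(self.seeds_per_container, dtype=float))
        object.__setattr__(self, "n_containers",
                           np.asarray(self.n_containers, dtype=np.int64))
        if self.dates.has_duplicates:
            raise ValueError("sampling dates must be unique within a taxon")
        if (self.seeds_per_container < 0).any():
            raise ValueError("seeds per container must be nonnegative")
        if (self.n_containers <= 0).any():
            raise ValueError("each retained visit must have sampled containers")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon": self.taxon,
            "date": self.dates,
            "seeds_per_container": self.seeds_per_container,
            "n_containers": self.n_containers,
        })


@dataclass(frozen=True)
class InfluxEstimate:
    """Per-date predictions and the seasonal total N = sum(s_hat * c)."""

    taxon: str
    dates: pd.DatetimeIndex
    s_hat: np.ndarray
    containers: np.ndarray
    total: float = field(init=False)
    total_rounded: int = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.s_hat, dtype=float)
        c = np.asarray(self.containers, dtype=np.int64)
        object.__setattr__(self, "s_hat", s)
        object.__setattr__(self, "containers", c)
        object.__setattr__(self, "total", float(np.dot(s, c)))
        object.__setattr__(self, "total_rounded", int(np.rint(np.dot(s, c))))

    def predictions(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon": self.taxon,
            "date": self.dates,
            "s_hat": self.s_hat,
            "containers": self.containers,
        })


def aggregate_samples(samples: pd.DataFrame, taxon: str) -> RateSeries:
    """Per-visit mean seeds per container for one taxon.

    ``samples`` has one row per (sampling date, container, taxon) with the
    seed count for that container; explicit zeros count toward the
    denominator.  Visits with no sampled containers for the taxon are simply
    absent from the grouped frame; a visit present with zero seeds yields a
    0.0 observation and is retained.
    """
    sub = samples.loc[samples["taxon"] == taxon]
    if sub.empty:
        raise ValueError(f"no sample records for taxon {taxon!r}")
    grouped = (sub.assign(date=pd.to_datetime(sub["date"]))
               .groupby("date")["seed_count"]
               .agg(total="sum", n="count")
               .sort_index())
    return RateSeries(
        taxon=taxon,
        dates=pd.DatetimeIndex(grouped.index),
        seeds_per_container=(grouped["total"] / grouped["n"]).to_numpy(),
        n_containers=grouped["n"].to_numpy(),
    )


def _neighbour_indices(train_days: np.ndarray, query_day: int, k: int) -> np.ndarray:
    dist = np.abs(train_days - query_day)
    # ties at equal distance resolve to the earlier sampling date
    order = np.lexsort((train_days, dist))
    return order[:k]


def knn_predict(series: RateSeries, query_date, k: int = 2) -> float:
    """Seeds per container on ``query_date``: mean of the k nearest visits.

    Distance is absolute calendar days; at equal distance the earlier
    sampling date is preferred, which makes the prediction deterministic.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if len(series) < k:
        raise ValueError(
            f"need at least k={k} sampling dates, have {len(series)}")
    train_days = _as_days(series.dates)
    (query_day,) = _as_days(query_date)
    idx = _neighbour_indices(train_days, int(query_day), k)
    return float(series.seeds_per_container[idx].mean())


def estimate_total_influx(series: RateSeries, arrivals: ArrivalSchedule,
                          k: int = 2) -> InfluxEstimate:
    """Predict seeds per container for every arrival date and total them.

    Arrival dates outside the sampled window still use the k nearest visits
    (one-sided nearest-neighbour extrapolation).  An empty schedule yields
    N = 0 with a warning.
    """
    if len(arrivals.dates) == 0:
        warnings.warn("empty arrival schedule: total influx is 0", stacklevel=2)
        return InfluxEstimate(series.taxon, arrivals.dates,
                              np.empty(0), np.empty(0, dtype=np.int64))
    s_hat = np.array([knn_predict(series, d, k=k) for d in arrivals.dates])
    return InfluxEstimate(series.taxon, arrivals.dates, s_hat, arrivals.containers)
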