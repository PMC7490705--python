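"""Synthetic shipping seasons, surveillance samples and germination trials.

The generator reproduces the statistical structure the estimators assume: a
roughly 32-week shipping season with near-steady container arrivals
(~1,900 per season), strongly seasonal seeds-per-container intensities
(Gaussian bumps, optionally multimodal, typically peaking mid-season),
overdispersed per-container counts (negative binomial), and biweekly
surveillance visits that sample ~16 % of arrivals.  Ground truth — the exact
seed deposit of every container — is retained so that influx-recovery tests
can compare the K-nearest-neighbours estimate against the true total.

Everything is driven by one integer seed; identical seeds give identical
output (reproducibility contract).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonSpec",
    "SeasonSpec",
    "GroundTruth",
    "SeasonData",
    "generate_season",
    "generate_trials",
]


@dataclass(frozen=True)
class TaxonSpec:
    """Seasonal seed-deposit profile of one taxon.

    The intensity over the season is a Gaussian bump at ``peak_day`` (days
    from season start) of width ``peak_width_days``; ``extra_peaks`` adds
    (day, width, weight) bumps for the multimodal profiles seen in real
    counts.  ``mean_total_seeds`` is the expected season-wide deposit summed
    over every arriving container, and ``dispersion`` the negative-binomial
    overdispersion alpha (variance = mu + alpha * mu^2; 0 = Poisson).
    """

    name: str
    peak_day: float = 95.0
    peak_width_days: float = 20.0
    mean_total_seeds: float = 10_000.0
    dispersion: float = 1.0
    germination_true: float = 0.2
    survival_true: float = 0.5
    extra_peaks: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.peak_width_days <= 0:
            raise ValueError(f"{self.name}: peak_width_days must be positive")
        if self.mean_total_seeds < 0 or self.dispersion < 0:
            raise ValueError(
                f"{self.name}: mean_total_seeds and dispersion must be >= 0")
        for p in (self.germination_true, self.survival_true):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: proportions must lie in [0, 1]")

    def intensity(self, day: np.ndarray) -> np.ndarray:
        """Unnormalised seasonal intensity at day-of-season ``day``."""
        day = np.asarray(day, dtype=float)
        out = np.exp(-0.5 * ((day - self.peak_day) / self.peak_width_days) ** 2)
        for peak, width, weight in self.extra_peaks:
            if width <= 0:
                raise ValueError(f"{self.name}: extra peak width must be > 0")
            out = out + weight * np.exp(-0.5 * ((day - peak) / width) ** 2)
        return out


@dataclass(frozen=True)
class SeasonSpec:
    """One shipping season's layout and surveillance design.

    Weekly container counts default to near-constant at ``1,900 / n_weeks``
    (arrivals at the port were steady); visits every ``sampling_interval_days``
    record seed counts for a random ``sampled_fraction`` of the containers
    arrived since the previous visit — zero-seed containers are recorded
    explicitly, since they belong in the per-visit denominator.
    """

    season_start: dt.date = dt.date(2015, 8, 13)
    n_weeks: int = 32
    weekly_containers: tuple[int, ...] | None = None
    taxa: tuple[TaxonSpec, ...] = (TaxonSpec("taxon_a"),)
    sampling_interval_days: int = 14
    sampled_fraction: float = 0.16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        if not 0.0 <= self.sampled_fraction <= 1.0:
            raise ValueError("sampled_fraction must lie in [0, 1]")
        if self.sampling_interval_days < 1:
            raise ValueError("sampling_interval_days must be >= 1")
        if self.weekly_containers is not None:
            wc = tuple(int(c) for c in self.weekly_containers)
            if len(wc) != self.n_weeks:
                raise ValueError("weekly_containers must have n_weeks entries")
            if any(c < 0 for c in wc):
                raise ValueError("weekly_containers must be nonnegative")
            object.__setattr__(self, "weekly_containers", wc)

    def resolve_weekly_containers(self) -> np.ndarray:
        if self.weekly_containers is not None:
            return np.asarray(self.weekly_containers, dtype=np.int64)
        base, extra = divmod(1900, self.n_weeks)
        counts = np.full(self.n_weeks, base, dtype=np.int64)
        counts[:extra] += 1
        return counts


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-container seed deposits for one taxon, all containers."""

    taxon: str
    per_container_counts: np.ndarray
    true_total_influx: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.per_container_counts, dtype=np.int64)
        if (counts < 0).any():
            raise ValueError("seed counts must be nonnegative")
        object.__setattr__(self, "per_container_counts", counts)
        object.__setattr__(self, "true_total_influx", int(counts.sum()))


@dataclass(frozen=True)
class SeasonData:
    """Everything one generated season produces.

    arrivals: date, containers (one row per arrival date)
    samples:  date, container_id, taxon, seed_count (one row per sampled
              container x taxon, date = the surveillance visit date)
    containers: container_id, arrival_date plus one count column per taxon
    truth:    taxon -> GroundTruth
    """

    arrivals: pd.DataFrame
    samples: pd.DataFrame
    containers: pd.DataFrame
    truth: dict[str, GroundTruth]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"taxon": t, "true_total_influx": gt.true_total_influx}
             for t, gt in self.truth.items()])


def _draw_counts(mu: np.ndarray, alpha: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with mean mu and variance mu + alpha*mu^2."""
    mu = np.asarray(mu, dtype=float)
    counts = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not pos.any():
        return counts
    if alpha == 0:
        counts[pos] = rng.poisson(mu[pos])
        return counts
    shape = 1.0 / alpha  # gamma-Poisson mixture
    lam = rng.gamma(shape, scale=mu[pos] * alpha)
    counts[pos] = rng.poisson(lam)
    return counts


def _visit_dates(spec: SeasonSpec, last_arrival: pd.Timestamp) -> list[pd.Timestamp]:
    start = pd.Timestamp(spec.season_start)
    step = pd.Timedelta(days=spec.sampling_interval_days)
    visits = []
    t = start + step
    while t <= last_arrival:
        visits.append(t)
        t += step
    if not visits or visits[-1] < last_arrival:
        visits.append(last_arrival)  # final visit covers the season tail
    return visits


def generate_season(spec: SeasonSpec) -> SeasonData:
    """Generate one season: arrivals, ground-truth deposits, and samples.

    Each week's containers are scattered multinomially over its seven days.
    Every container receives, per taxon, a negative-binomial seed count whose
    mean follows the taxon's seasonal intensity normalised so the expected
    season total is ``mean_total_seeds``.  Surveillance visits then observe a
    random subset of the containers arrived since the previous visit.
    """
    rng = np.random.default_rng(spec.rng_seed)
    weekly = spec.resolve_weekly_containers()
    start = pd.Timestamp(spec.season_start)

    day_offsets = []
    for week, n in enumerate(weekly):
        per_day = rng.multinomial(int(n), np.full(7, 1 / 7))
        for d, c in enumerate(per_day):
            day_offsets.extend([week * 7 + d] * int(c))
    day_offsets = np.array(sorted(day_offsets), dtype=np.int64)
    n_containers = len(day_offsets)
    arrival_dates = start + pd.to_timedelta(day_offsets, unit="D")
    container_ids = np.array([f"C{i:05d}" for i in range(n_containers)])

    containers = pd.DataFrame({
        "container_id": container_ids,
        "arrival_date": arrival_dates,
    })
    truth: dict[str, GroundTruth] = {}
    for taxon in spec.taxa:
        w = taxon.intensity(day_offsets.astype(float))
        total_w = w.sum()
        mu = (taxon.mean_total_seeds * w / total_w) if total_w > 0 else np.zeros_like(w)
        counts = _draw_counts(mu, taxon.dispersion, rng)
        containers[taxon.name] = counts
        truth[taxon.name] = GroundTruth(taxon.name, counts)

    arrivals = (containers.groupby("arrival_date").size()
                .rename("containers").reset_index()
                .rename(columns={"arrival_date": "date"}))

    taxon_cols = [t.name for t in spec.taxa]
    frames = []
    if n_containers:
        prev = start - pd.Timedelta(days=1)
        for visit in _visit_dates(spec, arrival_dates.max()):
            in_window = (containers["arrival_date"] > prev) & \
                        (containers["arrival_date"] <= visit)
            pool = containers.loc[in_window]
            prev = visit
            if pool.empty:
                continue
            take = rng.random(len(pool)) < spec.sampled_fraction \
                if spec.sampled_fraction < 1.0 else np.ones(len(pool), bool)
            sampled = pool.loc[take]
            if sampled.empty:
                continue
            melted = sampled.melt(id_vars=["container_id"],
                                  value_vars=taxon_cols, var_name="taxon",
                                  value_name="seed_count")
            melted.insert(0, "date", visit)
            frames.append(melted)
    samples = (pd.concat(frames, ignore_index=True) if frames else
               pd.DataFrame(columns=["date", "container_id", "taxon",
                                     "seed_count"]))
    return SeasonData(arrivals=arrivals, samples=samples,
                      containers=containers, truth=truth)


def generate_trials(taxon: str, n_seeds: int, g: float, v: float,
                    rng_seed: int = 0) -> pd.DataFrame:
    """Germination/survival trials: seeds plated ten per dish.

    Germination is Bernoulli(g) per seed and survival Bernoulli(v) per
    germinated seedling; the last dish may hold fewer than ten seeds.
    Returns one row per dish: taxon, dish_id, seeds_plated, germinated,
    survived_transplant.
    """
    if n_seeds < 0:
        raise ValueError("n_seeds must be nonnegative")
    if not (0.0 <= g <= 1.0 and 0.0 <= v <= 1.0):
        raise ValueError("g and v must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    rows = []
    remaining = int(n_seeds)
    dish = 0
    while remaining > 0:
        plated = min(10, remaining)
        germinated = int(rng.binomial(plated, g))
        survived = int(rng.binomial(germinated, v))
        rows.append((taxon, dish, plated, germinated, survived))
        remaining -= plated
        dish += 1
    return pd.DataFrame(rows, columns=[
        "taxon", "dish_id", "seeds_plated", "germinated", "survived_transplant"])
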