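"""Mean-field simulation of nonnative plant establishment around a port.

The model tracks 'invaded sites': 1-m^2 patches of port greenspace holding at
least one reproductive individual, out of S available sites (1,000 by
default, i.e. a 250 m x 4 m strip).  Four processes act multiplicatively on
seed numbers:

    escape from containers (e) -> germination (g) -> seedling survival (v)
        -> reproduction (f seeds per established individual per year)

Year 1 is fed solely by the seasonal container influx N, thinned by the
escape rate e.  From year 2 on, the seed pool is local reproduction by the
invaded sites (no escape filter), and established individuals never die
(clonal persistence), so trajectories are non-decreasing and bounded by S.

Two modes share the same parameterisation:

deterministic
    propagates expected counts as real numbers; new invasions per year are
    ``seed_pool * g * v`` capped at the remaining sites.  Fractional states
    are deliberate — with about one expected founder, rounding would erase
    the dynamics of interest.
stochastic
    draws binomial fates per seed and scatters survivors uniformly over
    sites; a site keeps its invaded status forever.  Site identity never
    matters beyond occupancy (mean-field: all sites equally susceptible).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonLifeHistory",
    "SimConfig",
    "Trajectory",
    "simulate_establishment",
    "run_replicates",
    "run_sweep",
    "stage_flow_report",
    "DEFAULT_ESCAPE_GRID",
    "DEFAULT_SURVIVAL_GRID",
]

#: escape rates swept in the risk analysis: 0.01 % to 10 %
DEFAULT_ESCAPE_GRID: tuple[float, ...] = (
    0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1)
#: survival rates swept; "empirical" resolves to the trial-derived rate,
#: which is treated as an upper bound on field survival
DEFAULT_SURVIVAL_GRID: tuple[float | str, ...] = (
    0.05, 0.10, 0.25, 0.50, "empirical")


@dataclass(frozen=True)
class TaxonLifeHistory:
    """Demographic rates for one taxon.

    germination and survival are proportions in [0, 1]; fecundity is seeds
    per established individual per year (lowest literature value).
    """

    taxon: str
    germination: float
    survival: float
    fecundity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.germination <= 1.0 and 0.0 <= self.survival <= 1.0):
            raise ValueError(f"{self.taxon}: rates must lie in [0, 1]")
        if self.fecundity < 1:
            raise ValueError(f"{self.taxon}: fecundity must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """One simulation's knobs.

    influx is the seasonal container seed total N (applied in year 1 only);
    escape_rate is the fraction of those seeds reaching a suitable site.
    """

    influx: float
    escape_rate: float
    sites: int = 1000
    years: int = 10
    mode: str = "deterministic"
    replicates: int = 1
    rng_seed: int = 0
    #: deterministic mode only: replace the min() cap with the balls-in-bins
    #: occupancy expectation empty * (1 - (1 - 1/S)**(pool*g*v))
    collision_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_rate <= 1.0:
            raise ValueError("escape_rate must lie in [0, 1]")
        if self.sites < 1 or self.years < 1 or self.replicates < 1:
            raise ValueError("sites, years and replicates must be >= 1")
        if self.influx < 0:
            raise ValueError("influx must be nonnegative")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Trajectory:
    """Invaded sites per year (year 1 = the influx season)."""

    invaded: np.ndarray
    sites: int
    fully_established_year: int | None = field(init=False)

    def __post_init__(self) -> None:
        inv = np.asarray(self.invaded, dtype=float)
        object.__setattr__(self, "invaded", inv)
        full = np.flatnonzero(inv >= self.sites - 1e-9)
        object.__setattr__(self, "fully_established_year",
                           int(full[0]) + 1 if full.size else None)

    def invaded_after(self, year: int) -> float:
        """Invaded sites at the end of simulated year ``year`` (1-based)."""
        return float(self.invaded[year - 1])


def _substream(master_seed: int, *key) -> np.random.Generator:
    """Reproducible per-cell RNG derived from a master seed and a cell key."""
    digest = zlib.crc32("|".join(map(str, key)).encode())
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, digest])


def _simulate_deterministic(cfg: SimConfig, life: TaxonLifeHistory):
    g, v, f, S = life.germination, life.survival, life.fecundity, cfg.sites
    invaded = np.zeros(cfg.years)
    rows = []
    state = 0.0
    for year in range(1, cfg.years + 1):
        if year == 1:
            influx = float(cfg.influx)
            escaped = influx * cfg.escape_rate
        else:
            influx = state * f
            escaped = influx  # local seeds face no container-escape filter
        germinated = escaped * g
        survived = germinated * v
        if cfg.collision_correction and S > 1:
            new = (S - state) * -np.expm1(survived * np.log1p(-1.0 / S))
        else:
            new = min(S - state, survived)
        state = min(float(S), state + new)
        invaded[year - 1] = state
        rows.append((year, influx, escaped, germinated, survived, state * f, state))
    return invaded, rows


def _scatter_survivors(occupied: np.ndarray, m: int,
                       rng: np.random.Generator) -> None:
    """Mark sites hit by m uniformly scattered surviving seeds, in place."""
    S = occupied.size
    if m >= 50 * S:
        # every site is hit with probability 1 - (1-1/S)^m >= 1 - e^-50
        occupied[:] = True
    elif m > 0:
        occupied[rng.integers(0, S, size=m)] = True


def _simulate_stochastic(cfg: SimConfig, life: TaxonLifeHistory,
                         rng: np.random.Generator):
    g, v, f, S = life.germination, life.survival, life.fecundity, cfg.sites
    occupied = np.zeros(S, dtype=bool)
    invaded = np.zeros(cfg.years)
    rows = []
    for year in range(1, cfg.years + 1):
        if year == 1:
            influx = int(cfg.influx)
            escaped = int(rng.binomial(influx, cfg.escape_rate))
        else:
            influx = int(invaded[year - 2]) * int(f)
            escaped = influx
        germinated = int(rng.binomial(escaped, g))
        survived = int(rng.binomial(germinated, v))
        _scatter_survivors(occupied, survived, rng)
        n_inv = int(occupied.sum())
        invaded[year - 1] = n_inv
        rows.append((year, influx, escaped, germinated, survived, n_inv * f, n_inv))
    return invaded, rows


_STAGE_COLS = ["year", "seeds_influx", "seeds_escaped", "germinated",
               "survived", "seeds_reproduced", "invaded_sites"]


def simulate_establishment(cfg: SimConfig, life: TaxonLifeHistory
                           ) -> tuple[Trajectory, pd.DataFrame]:
    """Run one trajectory and return it with its per-year stage flows.

    In stochastic mode this is a single realisation drawn from
    ``cfg.rng_seed``; use :func:`run_replicates` for ensembles.
    """
    if cfg.mode == "deterministic":
        invaded, rows = _simulate_deterministic(cfg, life)
    else:
        rng = _substream(cfg.rng_seed, life.taxon, "single")
        invaded, rows = _simulate_stochastic(cfg, life, rng)
    flow = pd.DataFrame(rows, columns=_STAGE_COLS)
    flow.insert(0, "taxon", life.taxon)
    return Trajectory(invaded, cfg.sites), flow


def run_replicates(cfg: SimConfig, life: TaxonLifeHistory) -> np.ndarray:
    """Stochastic ensemble: array of shape (replicates, years) of invaded sites."""
    out = np.zeros((cfg.replicates, cfg.years))
    for r in range(cfg.replicates):
        rng = _substream(cfg.rng_seed, life.taxon, cfg.escape_rate,
                         cfg.sites, "rep", r)
        out[r], _ = _simulate_stochastic(cfg, life, rng)
    return out


def _resolve_v(v: float | str, life: TaxonLifeHistory) -> float:
    if isinstance(v, str):
        if v != "empirical":
            raise ValueError(f"unknown survival grid entry {v!r}")
        return life.survival
    return float(v)


def run_sweep(life_histories: Mapping[str, TaxonLifeHistory],
              influxes: Mapping[tuple[str, str], float],
              e_grid: Iterable[float] = DEFAULT_ESCAPE_GRID,
              v_grid: Iterable[float | str] = DEFAULT_SURVIVAL_GRID,
              s_values: Sequence[int] = (1000, 100),
              years: int = 10,
              mode: str = "deterministic",
              replicates: int = 1,
              rng_seed: int = 0) -> pd.DataFrame:
    """Grid sweep over escape rate, survival rate and available sites.

    ``influxes`` maps (taxon, season label) to the seasonal seed total N.
    Survival entries above the taxon's empirical trial estimate are flagged
    (field survival should not exceed greenhouse survival).  Stochastic cells
    report the median trajectory across replicates.
    """
    rows = []
    for (taxon, season), n_seeds in influxes.items():
        life = life_histories[taxon]
        for e in e_grid:
            for v in v_grid:
                v_used = _resolve_v(v, life)
                swept = TaxonLifeHistory(taxon, life.germination, v_used,
                                         life.fecundity)
                for S in s_values:
                    cfg = SimConfig(influx=n_seeds, escape_rate=e, sites=S,
                                    years=years, mode=mode,
                                    replicates=replicates, rng_seed=rng_seed)
                    if mode == "deterministic":
                        traj, _ = simulate_establishment(cfg, swept)
                        inv = traj.invaded
                    else:
                        inv = np.median(run_replicates(cfg, swept), axis=0)
                    traj = Trajectory(inv, S)
                    rows.append({
                        "taxon": taxon,
                        "season": season,
                        "escape_rate": e,
                        "v_used": v_used,
                        "v_above_empirical": v_used > life.survival,
                        "sites": S,
                        "invaded_after_4y": traj.invaded_after(min(4, years)),
                        "invaded_final": traj.invaded_after(years),
                        "fully_established": traj.fully_established_year is not None,
                        "fully_established_year": traj.fully_established_year,
                    })
    return pd.DataFrame(rows)


def stage_flow_report(life_histories: Mapping[str, TaxonLifeHistory],
                      influxes: Mapping[tuple[str, str], float],
                      escape_rate: float = 0.01,
                      sites: int = 1000,
                      years: int = 10) -> pd.DataFrame:
    """Deterministic influx -> escaped -> germinated -> survived -> reproduced
    chains per taxon and season (alluvial-plot input) at one escape rate."""
    flows = []
    for (taxon, season), n_seeds in influxes.items():
        cfg = SimConfig(influx=n_seeds, escape_rate=escape_rate, sites=sites,
                        years=years, mode="deterministic")
        _, flow = simulate_establishment(cfg, life_histories[taxon])
        flow.insert(1, "season", season)
        flow.insert(2, "escape_rate", escape_rate)
        flows.append(flow)
    return pd.concat(flows, ignore_index=True)
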