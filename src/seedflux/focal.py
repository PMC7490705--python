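"""Empirical inputs for the four focal taxa from the Port of Savannah study system.

Seeds were vacuum-sampled from the air-intake grilles of refrigerated shipping
containers at the Garden City Terminal over two shipping seasons (August
through February).  The four monocotyledonous taxa with the most seeds —
*Saccharum spontaneum* (a Federal Noxious Weed), *Typha* sp(p)., *Phragmites*
sp(p). and *Andropogon* sp(p). — were carried through germination trials,
transplant-survivorship scoring and establishment simulations.  This module
records the published per-taxon numbers (estimated and observed seasonal seed
totals, trial tallies, literature fecundities) and the season-level sampling
effort, so every downstream computation can be driven from the printed inputs
without the raw collection tables.

Fecundities are the lowest literature value for each taxon (seeds per
established individual per year), a deliberately conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass

from .establishment import TaxonLifeHistory
from .trials import TrialTally

__all__ = [
    "FocalTaxon",
    "FOCAL_TAXA",
    "SEASONS",
    "SeasonEffort",
]


@dataclass(frozen=True)
class FocalTaxon:
    """Published parameter set for one focal taxon."""

    name: str
    #: KNN-estimated total seed influx per season (seeds).
    influx: dict[str, int]
    #: raw seeds counted in the samples per season (seeds).
    observed: dict[str, int]
    #: germination-trial tally: seeds plated, germinated, survived transplant.
    seeds_plated: int
    germinated: int
    survived_transplant: int
    #: lowest literature estimate of seeds per established individual per year.
    fecundity: int

    @property
    def tally(self) -> TrialTally:
        return TrialTally(
            taxon=self.name,
            seeds_plated=self.seeds_plated,
            germinated=self.germinated,
            survived_transplant=self.survived_transplant,
        )

    def life_history(self) -> TaxonLifeHistory:
        """Life history with trial-derived germination and survival rates."""
        return TaxonLifeHistory(
            taxon=self.name,
            germination=self.germinated / self.seeds_plated,
            survival=self.survived_transplant / self.germinated,
            fecundity=self.fecundity,
        )


FOCAL_TAXA: dict[str, FocalTaxon] = {
    "Saccharum spontaneum": FocalTaxon(
        name="Saccharum spontaneum",
        influx={"season1": 24_065, "season2": 17_375},
        observed={"season1": 3_945, "season2": 2_053},
        seeds_plated=1_690,
        germinated=160,
        survived_transplant=75,
        fecundity=2_000,
    ),
    "Typha": FocalTaxon(
        name="Typha",
        influx={"season1": 68, "season2": 360},
        observed={"season1": 10, "season2": 38},
        seeds_plated=923,
        germinated=164,
        survived_transplant=149,
        fecundity=250_000,
    ),
    "Phragmites": FocalTaxon(
        name="Phragmites",
        influx={"season1": 2_941, "season2": 9_898},
        observed={"season1": 635, "season2": 1_001},
        seeds_plated=697,
        germinated=180,
        survived_transplant=160,
        fecundity=500,
    ),
    "Andropogon": FocalTaxon(
        name="Andropogon",
        influx={"season1": 351, "season2": 2_440},
        observed={"season1": 64, "season2": 171},
        seeds_plated=170,
        germinated=63,
        survived_transplant=39,
        fecundity=100,
    ),
}


@dataclass(frozen=True)
class SeasonEffort:
    """Season-level container arrivals and surveillance effort."""

    label: str
    total_containers: int
    sampled_containers: int
    n_visits: int


SEASONS: dict[str, SeasonEffort] = {
    "season1": SeasonEffort("season1", total_containers=1_858,
                            sampled_containers=331, n_visits=15),
    "season2": SeasonEffort("season2", total_containers=1_925,
                            sampled_containers=297, n_visits=14),
}
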