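"""Germination and transplant-survivorship rates from trial tallies.

Seeds are plated ten to a petri dish for a 14-day chamber trial; germinated
seedlings are transplanted and scored for survival to the 4-inch-pot stage.
Rates are pooled across dishes per taxon:

    germination g = germinated / seeds plated
    survival    v = survived to transplant / germinated

Percentages are rounded half away from zero, matching how the pooled counts
round to the published integer percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TrialTally",
    "RateEstimate",
    "NoGerminationError",
    "round_half_away",
    "percent",
    "tabulate_germination",
    "tabulate_survival",
    "tabulate_rates",
    "pool_dishes",
    "rates_table",
]


class NoGerminationError(ValueError):
    """Survivorship is undefined for a taxon with zero germinated seedlings."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage of numerator/denominator, half away from zero.

    Used both for trial rates and for surveillance coverage figures
    (e.g. 331 of 1,858 containers sampled -> 18 %).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return round_half_away(100.0 * numerator / denominator)


@dataclass(frozen=True)
class TrialTally:
    """Pooled per-taxon trial counts."""

    taxon: str
    seeds_plated: int
    germinated: int
    survived_transplant: int

    def __post_init__(self) -> None:
        if not (0 <= self.survived_transplant <= self.germinated <= self.seeds_plated):
            raise ValueError(
                f"{self.taxon}: require survived <= germinated <= plated, got "
                f"{self.survived_transplant}/{self.germinated}/{self.seeds_plated}"
            )


@dataclass(frozen=True)
class RateEstimate:
    """Germination and survivorship rates for one taxon.

    Raw fractions live in [0, 1]; integer percents are the display form.
    Survival fields are None when no seed germinated.
    """

    taxon: str
    germination_raw: float
    germination_pct: int
    survival_raw: float | None
    survival_pct: int | None


def tabulate_germination(tally: TrialTally) -> RateEstimate:
    """Germination rate only; survival fields left unset."""
    if tally.seeds_plated == 0:
        raise ValueError(f"{tally.taxon}: germination undefined, no seeds plated")
    raw = tally.germinated / tally.seeds_plated
    return RateEstimate(tally.taxon, raw, percent(tally.germinated, tally.seeds_plated),
                        None, None)


def tabulate_survival(tally: TrialTally) -> RateEstimate:
    """Transplant-survivorship rate only; germination fields from the tally."""
    if tally.germinated == 0:
        raise NoGerminationError(
            f"{tally.taxon}: no germination, survivorship undefined")
    raw = tally.survived_transplant / tally.germinated
    germ = tabulate_germination(tally)
    return RateEstimate(tally.taxon, germ.germination_raw, germ.germination_pct,
                        raw, percent(tally.survived_transplant, tally.germinated))


def tabulate_rates(tally: TrialTally) -> RateEstimate:
    """Both rates; survival fields None for taxa that did not germinate."""
    germ = tabulate_germination(tally)
    if tally.germinated == 0:
        return germ
    return tabulate_survival(tally)


def pool_dishes(dishes: pd.DataFrame) -> list[TrialTally]:
    """Pool per-dish records (taxon, dish_id, seeds_plated, germinated,
    survived_transplant) into one tally per taxon.

    Per-dish percentages exist in the raw records, but published taxon-level
    rates are pooled counts, so pooling is the canonical reduction.
    """
    out = []
    for taxon, grp in dishes.groupby("taxon", sort=True):
        out.append(TrialTally(
            taxon=str(taxon),
            seeds_plated=int(grp["seeds_plated"].sum()),
            germinated=int(grp["germinated"].sum()),
            survived_transplant=int(grp["survived_transplant"].sum()),
        ))
    return out


def rates_table(tallies: list[TrialTally]) -> pd.DataFrame:
    """Tabulate rates for many taxa into a tidy frame (rates.csv schema)."""
    rows = []
    for t in tallies:
        r = tabulate_rates(t)
        rows.append({
            "taxon": t.taxon,
            "seeds_plated": t.seeds_plated,
            "germinated": t.germinated,
            "survived_transplant": t.survived_transplant,
            "germination_raw": r.germination_raw,
            "germination_pct": r.germination_pct,
            "survival_raw": r.survival_raw,
            "survival_pct": r.survival_pct,
        })
    return pd.DataFrame(rows)
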