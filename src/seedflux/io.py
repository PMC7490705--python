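"""Validated CSV readers and writers for the analysis tables.

Schemas (all UTF-8 CSV with headers, ISO-8601 dates):

    arrivals.csv     date, containers
    samples.csv      date, container_id, taxon, seed_count
    trials.csv       taxon, dish_id, seeds_plated, germinated, survived_transplant
    truth.csv        taxon, true_total_influx
    life_history.csv taxon, germination_pct, survival_pct, fecundity
    influx.csv       taxon, season, n_real, n_rounded
    rates.csv        output of trials.rates_table

Malformed rows are reported with their 1-based data row number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .establishment import TaxonLifeHistory
from .influx import ArrivalSchedule, InfluxEstimate

__all__ = [
    "SchemaError",
    "read_arrivals", "write_arrivals",
    "read_samples", "write_samples",
    "read_trials", "write_trials",
    "read_life_history", "write_life_history",
    "read_influx", "write_influx",
]


class SchemaError(ValueError):
    """A table failed validation; the message names the offending row."""


def _read(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return frame


def _parse_dates(frame: pd.DataFrame, col: str, path) -> pd.DataFrame:
    parsed = pd.to_datetime(frame[col], errors="coerce")
    bad = parsed.isna() & frame[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise SchemaError(
            f"{path}: row {row}: unparseable date {frame[col][bad.idxmax()]!r}")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 1
        raise SchemaError(f"{path}: row {row}: missing date")
    return frame.assign(**{col: parsed})


def _check_nonneg_int(frame: pd.DataFrame, col: str, path) -> None:
    vals = pd.to_numeric(frame[col], errors="coerce")
    bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise SchemaError(
            f"{path}: row {row}: {col} must be a nonnegative integer, "
            f"got {frame[col][bad.idxmax()]!r}")


def read_arrivals(path) -> ArrivalSchedule:
    frame = _parse_dates(_read(path, ["date", "containers"]), "date", path)
    _check_nonneg_int(frame, "containers", path)
    return ArrivalSchedule.from_frame(frame)


def write_arrivals(schedule: ArrivalSchedule, path) -> None:
    frame = schedule.to_frame()
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    frame = _parse_dates(
        _read(path, ["date", "container_id", "taxon", "seed_count"]),
        "date", path)
    _check_nonneg_int(frame, "seed_count", path)
    return frame


def write_samples(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    cols = ["taxon", "dish_id", "seeds_plated", "germinated",
            "survived_transplant"]
    frame = _read(path, cols)
    for col in cols[2:]:
        _check_nonneg_int(frame, col, path)
    bad = (frame["survived_transplant"] > frame["germinated"]) | \
          (frame["germinated"] > frame["seeds_plated"])
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise SchemaError(
            f"{path}: row {row}: require survived <= germinated <= plated")
    return frame


def write_trials(dishes: pd.DataFrame, path) -> None:
    dishes.to_csv(path, index=False)


def read_life_history(path) -> dict[str, TaxonLifeHistory]:
    frame = _read(path, ["taxon", "germination_pct", "survival_pct",
                         "fecundity"])
    out = {}
    for i, row in frame.iterrows():
        try:
            out[row["taxon"]] = TaxonLifeHistory(
                taxon=row["taxon"],
                germination=float(row["germination_pct"]) / 100.0,
                survival=float(row["survival_pct"]) / 100.0,
                fecundity=float(row["fecundity"]))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {int(i) + 1}: {exc}") from exc
    return out


def write_life_history(lifes: dict[str, TaxonLifeHistory], path) -> None:
    pd.DataFrame([{
        "taxon": lh.taxon,
        "germination_pct": 100.0 * lh.germination,
        "survival_pct": 100.0 * lh.survival,
        "fecundity": lh.fecundity,
    } for lh in lifes.values()]).to_csv(path, index=False)


def read_influx(path) -> dict[tuple[str, str], float]:
    frame = _read(path, ["taxon", "season", "n_real"])
    return {(row["taxon"], row["season"]): float(row["n_real"])
            for _, row in frame.iterrows()}


def write_influx(estimates: dict[str, dict[str, InfluxEstimate]], path) -> None:
    """``estimates`` maps season label -> taxon -> InfluxEstimate."""
    pd.DataFrame([{
        "taxon": est.taxon,
        "season": season,
        "n_real": est.total,
        "n_rounded": est.total_rounded,
    } for season, per_taxon in estimates.items()
        for est in per_taxon.values()]).to_csv(path, index=False)
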