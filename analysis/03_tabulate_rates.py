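#!/usr/bin/env python
"""Tabulate germination and survivorship rates.

Two inputs are tabulated side by side: the published focal-taxon trial
tallies (the empirical rates that parameterise the risk model) and, when
present, the synthetic trials written by 01_generate_seasons.py (a check
that the generator's tallies recover their true rates).  Writes
results/rates/rates.csv (focal) and results/rates/rates_synthetic.csv.
"""

import argparse
from pathlib import Path

from seedflux.focal import FOCAL_TAXA, SEASONS
from seedflux.io import read_trials
from seedflux.trials import percent, pool_dishes, rates_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--synthetic", type=Path,
                        default=Path("results/synthetic/trials.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results/rates"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    focal = rates_table([t.tally for t in FOCAL_TAXA.values()])
    print("focal-taxon trial rates (pooled dishes):")
    print(focal[["taxon", "seeds_plated", "germinated", "survived_transplant",
                 "germination_pct", "survival_pct"]].to_string(index=False))
    focal.to_csv(args.outdir / "rates.csv", index=False)

    for label, s in SEASONS.items():
        print(f"{label}: {s.sampled_containers} of {s.total_containers} "
              f"containers sampled "
              f"({percent(s.sampled_containers, s.total_containers)} %) "
              f"over {s.n_visits} visits")

    if args.synthetic.exists():
        synth = rates_table(pool_dishes(read_trials(args.synthetic)))
        print("synthetic trial rates:")
        print(synth[["taxon", "seeds_plated", "germination_pct",
                     "survival_pct"]].to_string(index=False))
        synth.to_csv(args.outdir / "rates_synthetic.csv", index=False)
    else:
        print(f"(no synthetic trials at {args.synthetic}; run "
              "01_generate_seasons.py first)")
    print(f"wrote rate tables under {args.outdir}")


if __name__ == "__main__":
    main()
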