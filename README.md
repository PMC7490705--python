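# seedflux

Invasion-risk analysis for plant seeds hitchhiking on refrigerated shipping
containers. Seeds lodge on the air-intake grilles of reefer containers and
arrive by the thousand at ports of entry; `seedflux` quantifies that
propagule pressure and asks whether it is enough for nonnative plants to
establish in the greenspaces around a container terminal. The study system
is the Garden City Terminal at the Port of Savannah, where biweekly
vacuum-sampling of container grilles over two August–February shipping
seasons yielded four focal monocot taxa — *Saccharum spontaneum* (a Federal
Noxious Weed), *Typha* sp(p)., *Phragmites* sp(p). and *Andropogon* sp(p). —
with measured germination and transplant-survivorship rates.

The package is aimed at biosecurity and invasion-ecology analysts who have
interception-style surveillance data (arrival schedules plus per-container
counts on a subset of sampling dates) and want defensible influx totals and
establishment-risk sweeps.

## Methods at a glance

**Seasonal influx.** Seeds per container on each arrival date *i* is
predicted with K-nearest-neighbours regression over sampling dates
(unweighted mean of the K = 2 nearest visits in calendar days), and the
seasonal total is

    N = Σᵢ ŝᵢ · cᵢ

with cᵢ the containers arriving on date *i*.

**Trial rates.** Pooled over 10-seed dishes: germination g = germinated /
plated; survivorship v = survived-to-transplant / germinated.

**Establishment.** A mean-field, annual-step model of S available 1-m²
sites (1,000 default). Four processes act multiplicatively: escape from
containers (rate e, swept 0.01 %–10 %), germination g, seedling survival v,
and reproduction (f seeds per established individual per year, lowest
literature value). Year 1 is seeded by N·e container escapees; later years
by local reproduction of invaded sites, which persist indefinitely
(clonal). Deterministic mode propagates expected counts; stochastic mode
draws binomial fates per seed and scatters survivors over sites.

A synthetic-data module generates seasons with the same structure
(near-steady arrivals, Gaussian-bump seasonal intensities, negative-binomial
per-container counts, biweekly ~16 % sampling) with exact ground truth, so
the estimators can be validated by parameter recovery.

## Worked example

```sh
$ seedflux simulate --influx 24065 --escape 0.005 --germination 0.09 \
      --survival 0.10 --fecundity 2000 --years 5
taxon  year  seeds_influx  seeds_escaped  germinated  survived  seeds_reproduced  invaded_sites
  cli     1      24065.00         120.33       10.83      1.08           2165.85           1.08
  cli     2       2165.85        2165.85      194.93     19.49          41151.15          20.58
  cli     3      41151.15       41151.15     3703.60    370.36         781871.85         390.94
  cli     4     781871.85      781871.85    70368.47   7036.85        2000000.00        1000.00
  cli     5    2000000.00     2000000.00   180000.00  18000.00        2000000.00        1000.00
fully established in year 4
```

This is the headline *S. spontaneum* scenario: the Season-1 influx estimate
of 24,065 seeds, an escape rate of only 0.5 %, and survival capped at 10 %
(well below the 47 % greenhouse estimate) still saturate all 1,000 sites in
four years — about one expected founder in year 1, multiplied by
f·g·v = 18 new invaded sites per invaded site per year.

The numbered drivers under `analysis/` run the full study flow on synthetic
data and the published parameters:

```sh
python analysis/01_generate_seasons.py --seed 1   # seasons + trials, with truth
python analysis/02_estimate_influx.py             # KNN totals vs ground truth
python analysis/03_tabulate_rates.py              # trial rates + coverage
python analysis/04_establishment_risk.py          # sweeps + stage flows
```

Each prints what it found (e.g. per-taxon influx recovery errors, typically
5–20 % under 16 % biweekly sampling) and writes its tables under `results/`.

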