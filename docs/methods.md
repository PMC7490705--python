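# Methods

## Problem and data model

Refrigerated ("reefer") shipping containers accumulate wind-dispersed seeds
on their air-intake grilles in transit. At the receiving terminal, a
surveillance programme records every container arrival date and, on roughly
biweekly visits, vacuum-samples a subset of recently arrived containers and
counts seeds per taxon. Three questions follow, and the package answers
each with a dedicated module:

1. how many seeds of a taxon entered over a season (`seedflux.influx`);
2. how viable are they (`seedflux.trials`);
3. could the escaped fraction found a persistent population in the port's
   greenspaces (`seedflux.establishment`).

`seedflux.synth` generates data with the structure the estimators assume,
with exact ground truth; `seedflux.io`, `seedflux.pipeline` and
`seedflux.cli` provide validated CSV schemas and a reproducible end-to-end
driver. `seedflux.focal` records the published per-taxon inputs (seasonal
influx estimates, trial tallies, lowest-literature fecundities, season
coverage) so analyses can be parameterised without the raw collection
tables, which are not public.

## Influx estimation

Observed seeds-per-container is aggregated per sampling date as the mean
over all sampled containers that date, explicitly counting zero-seed
containers in the denominator — dropping zeros would bias every rate
upward. The per-date series (not individual containers) is the KNN
training set: the prediction for an arrival date is the unweighted mean of
the K = 2 nearest sampling dates by absolute calendar-day distance. Ties at
equal distance prefer the earlier date, and when a tie would admit more
than K neighbours the list is truncated after sorting by (distance, date);
both rules exist purely to make predictions deterministic. Arrival dates
outside the sampled window use the K nearest dates one-sidedly. The
seasonal total is the exact identity N = Σ ŝᵢ·cᵢ, reported both as a real
and rounded to the nearest integer.

Consequences tested as invariants: predictions are bounded by the observed
series range; K = (number of visits) degenerates to the global mean;
scaling all counts scales N identically.

K is fixed at 2 by design; cross-validated choice of K, distance-weighted
variants and uncertainty intervals on N are out of scope.

## Trial rates

Germination g = germinated / plated and survivorship v = survived-to-
transplant / germinated, pooled over 10-seed dishes per taxon (per-dish
rates are retained in the records but taxon-level rates are pooled counts).
Percentages round half away from zero, the convention consistent with every
published pair (e.g. 149/164 = 90.85 → 91 %). A taxon with zero germination
raises a typed error rather than reporting a 0 % survivorship that the data
cannot support. The same rounding helper produces season coverage figures
(331/1,858 → 18 %; 297/1,925 → 15 %).

## Establishment model

State: the number of invaded sites I_t among S equal 1-m² sites (mean-field
— no spatial structure, so any site relabelling leaves every output
unchanged). Annual census, year 1 = the influx season:

- year 1 seed pool: N·e (container seeds thinned by the escape rate);
- later pools: I_{t−1}·f (local reproduction; no escape filter);
- pool × g × v survivors become new invaded sites; established sites never
  revert (clonal persistence), so I_t is non-decreasing and ≤ S.

Deterministic mode keeps I_t real-valued: with roughly one expected founder
in the headline scenarios, integer rounding would erase the dynamics.
New invasions are min(S − I, pool·g·v); an optional collision-corrected
update (S − I)·(1 − (1 − 1/S)^{pool·g·v}) is available behind
`collision_correction=True`, but the two differ only near saturation where
both hit the cap, so the simpler cap is the default. A corollary worth
remembering: deterministic expectations never go extinct — any positive
expected founder count grows at factor 1 + f·g·v — so establishment
*probability* is a stochastic-mode question, while the deterministic mode
answers "how fast, in expectation".

Stochastic mode draws escaped ~ Binomial(N, e), then Binomial fates for
germination and survival, and scatters survivors uniformly over all S sites
(already-invaded sites waste seeds); a site with ≥ 1 survivor is invaded
thereafter. When a year's survivors exceed 50·S the occupancy update marks
all sites invaded (per-site miss probability < e⁻⁵⁰). Ensembles derive
per-replicate RNG substreams from one master seed by hashing the cell key
(taxon, escape, sites, replicate), so sweeps are reproducible cell-by-cell.
With λ = N·e·g·v expected founders, the probability of zero establishment
is (1 − e·g·v)^N ≈ exp(−λ), the Poisson-thinning oracle the tests use; in
the collision-free regime the ensemble mean tracks the deterministic
trajectory, the other cross-mode check.

Sweeps cover e ∈ {0.01 %, …, 10 %} × v ∈ {5 %, 10 %, 25 %, 50 %, empirical}
× S ∈ {1000, 100} per taxon and season, flagging survival values above the
trial estimate (greenhouse survival is an upper bound on field survival)
and recording invaded sites after 4 and 10 years. "Year 4" counts the
influx season as year 1. Stochastic sweep cells summarise by the median
across replicates (robust to the heavy upper tail near saturation).

Out of scope by design: competition and density dependence beyond site
saturation, seed banks and dormancy (no carryover between years), spatial
dispersal kernels, multi-season influx accumulation (a single season's
pulse is the question being asked), and mortality of established clones.

## Synthetic seasons

The generator emulates: ~32-week seasons with near-constant weekly arrivals
summing to ~1,900 containers (arrivals at the terminal were steady);
per-taxon seasonal intensity as a Gaussian bump (mid-season peak, ~day 95),
optionally multimodal via extra bumps; per-container counts drawn
negative-binomially with variance μ + αμ², α defaulting to 1 — strong
overdispersion of the kind heterogeneous grille loads show, while keeping
the per-visit mean informative (the distribution family is a modelling
choice; the source data report only totals); biweekly visits sampling each
inter-visit cohort uniformly at random at fraction 0.16, recording explicit
zeros. Trial generation plates seeds ten per dish (last dish partial) with
independent Bernoulli germination and survival.

What passing recovery tests therefore show: under unbiased uniform sampling
of cohorts and smooth-ish unimodal/bimodal intensities, KNN-2 totals land
within 25 % of truth in at least 90 % of replicates (the tested bound). What they cannot show:
robustness to opportunistic (non-random) container access, to seed loss or
damage in transit, or to intensity shapes sharper than the sampling
cadence — a peak narrower than the 14-day visit interval can be missed
entirely, and no estimator from these data could see it.

## Numerical and testing choices

- All rates validated to [0, 1] at construction; schedules and series
  reject duplicate dates and negative counts with row-numbered errors at
  the CSV boundary.
- The influx identity is asserted to 1e-9 absolute; simulator trajectories
  to 1e-9 relative against an independently written recurrence oracle.
- Monte-Carlo assertions use 3-standard-error bands at 600 replicates;
  problem sizes throughout (200 recovery replicates, 600-member ensembles,
  12-week seasons in I/O tests) are chosen so the full suite exercises
  every stochastic claim in well under a minute per test.
- The KNN implementation is cross-checked against scikit-learn's
  `KNeighborsRegressor` on tie-free queries; ties are excluded because the
  library does not define a calendar tie-break.

## Known limitations

The deterministic sweep declares "fully established" for any cell with
positive expected founders given enough years and high fecundity (see the
extinction note above); interpret 4-year invaded-site counts, or stochastic
establishment probabilities, not the 10-year deterministic flag alone, for
low-influx taxa. Influx totals inherit any bias in which containers were
accessible for sampling. Fecundities are lowest-literature values, so
risk is conservative with respect to reproduction but not with respect to
the unknown escape rate, which remains the swept free parameter.
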