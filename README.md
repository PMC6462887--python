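# hotspot-mapper

Venue-based programmatic mapping and key population size estimation for
HIV prevention programs.

HIV prevention programs for key populations — here, female sex workers
(FSW) and adolescent girls and young women (AGYW, ages 14–24) engaging
in transactional or casual sex — need to know **where** their
populations congregate and **how many** people they must reach.
Programmatic mapping answers both by (1) collecting an exhaustive list
of candidate venues ("hotspots") from secondary/tertiary key informants
(level one), (2) visiting each venue to validate it and count the
population on site (level two), and (3) aggregating per-venue counts
into subcounty- and county-level size estimates.  This package
implements the data-analysis side of that method, including the
modification that extends it from sex work to transactional and casual
sex, together with a fully synthetic county generator so every stage
can be exercised and validated offline.

## The estimator

For each validated-active venue *i* the level-two team records a
minimum and maximum head count; the venue estimate is the midpoint
*Eᵢ = (minᵢ + maxᵢ)/2*.  The **crude** county estimate sums these:

    Cr = Σᵢ Eᵢ ,  i = 1 … n venues

Because an FSW who solicits at several venues is counted once per
venue, the crude sum overcounts.  With *p* the proportion of
respondents who visit other venues and *m* the mean number of venues
visited (index venue included) among them, the **mobility-adjusted**
estimate is

    Ni = Cr·(1 − p) + Cr·p/m

applied per subcounty and summed to the county.  Since
(1 − p) + p/m ≤ 1 for m ≥ 1, adjustment never increases an estimate;
on a homogeneous population the adjusted estimate brackets the true
deduplicated size from above (proven and tested in
`tests/test_estimation.py`).  Transactional/casual estimates use the
peak-day midpoint summed without adjustment, since mobility of these
women across venues is assumed limited.

The analysis side classifies venues by which partnership types co-occur
there, tabulates typology × subcounty counts, tests heterogeneity with
Pearson's chi-square (with a small-expected-count warning and an
optional fixed-margin Monte-Carlo p-value), and splits the register
into venues already known to the program versus newly identified.

## Worked example

```python
from hotspot_mapper import GeneratorConfig, PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(simulate=GeneratorConfig(seed=1)))
reg = report["register"]
county = report["estimates"]["fsw_all"]["county-1"]
truth = report["ground_truth_comparison"]
print(f"mentions: {reg['n_mentions']}, register: {reg['n_register_total']}, "
      f"validated active: {reg['n_validated_active']}")
print(f"crude FSW estimate: {county['crude']['point_reported']} "
      f"(range {county['crude']['low_reported']} to {county['crude']['high_reported']})")
print(f"adjusted FSW estimate: {county['adjusted']['point_reported']} "
      f"(range {county['adjusted']['low_reported']} to {county['adjusted']['high_reported']})")
print(f"true FSW population: {truth['true_population_county']['fsw_all']}")
```

prints

```
mentions: 108, register: 99, validated active: 96
crude FSW estimate: 2317 (range 2025 to 2610)
adjusted FSW estimate: 1479 (range 1292 to 1666)
true FSW population: 1200
```

The synthetic county has 100 venues and 1200 women, 60 % of whom visit
on average 2.5 venues.  The 108 noisy level-one mentions collapse to a
99-venue register (96 active on validation).  The crude sum (2317)
overcounts the 1200 women because mobile women appear at every venue
they visit; the mobility adjustment brings the estimate down to 1479,
which — as the theory predicts for this heuristic — lies between the
true population and the crude count.

The same stages are available from the shell:

```bash
hotspot-mapper simulate --seed 1 --out data/
hotspot-mapper dedupe --mentions data/mentions.csv --geography data/geography.csv \
    --listing data/program_listing.csv --level-two data/level_two.csv --out register.csv
hotspot-mapper estimate --register register.csv --level-two data/level_two.csv \
    --geography data/geography.csv --group fsw_all --out estimates
hotspot-mapper tables --register register.csv --geography data/geography.csv --out tables/
hotspot-mapper run --config pipeline.yaml --out report/
```

File column contracts are documented in `docs/schemas.md`; the model
and its conventions in `docs/methods.md`.

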