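# Methods

## The mapping-and-estimation procedure

The package models the data products of a two-stage venue mapping
exercise for key population size estimation.

**Level one.**  Key informants name venues where female sex workers
(FSW) meet clients.  Reports are noisy: the same venue is named by
several informants with variant spellings, and some venues are missed
entirely.  `dedup.dedupe_mentions` collapses mentions to one register
entry per venue.  Matching is *zone-scoped* (identical names in
different data collection zones are different venues; venues are never
merged across zones) on a normalized key — case-folded, apostrophes
deleted, other punctuation to spaces, whitespace collapsed — with
optional fuzzy merging of keys whose `difflib` edit similarity reaches
a threshold (default **0.9**).  The method itself prescribes no
matching rule, so the conservative default favours under-merging:
distinct venues should never collapse, at the cost of an occasional
unmerged misspelling.  Clustering is computed from the sorted set of
keys with union–find over all similar pairs, which makes the register
a deterministic, order-independent function of the mention multiset,
and monotone in the threshold (lowering it can only merge more).  The
canonical name of a cluster is its most frequent raw spelling (ties
broken lexicographically).

**Program listing and snowball closure.**  Register entries are
flagged `known_to_program` when a zone-scoped key match exists in the
program's venue listing.  Venues named by level-two respondents
("snowball" referrals) that match nothing in the register are added as
`named` entries with `source=level_two_snowball`, and the pass is
iterated to a fixpoint because a newly added venue's own record may
refer to further venues.

**Level two.**  Each discovered venue is visited; the record carries
the validation outcome (active/inactive), the on-site typology (which
overrides any level-one guess), min/max head counts per population
group on a normal and a peak day, mobility responses, and snowball
referrals.  Only validated-active venues enter estimation or any
table.

## Estimation

Per venue the point estimate is the min/max midpoint; per geography
the crude estimate is the triple (Σ min, Σ midpoint, Σ max), so the
point is always the midpoint of the bounds.  The mobility adjustment

    Ni = Cr·(1 − p) + Cr·p/m

is applied to all three components, which preserves that identity.
Properties, all asserted in the test suite:

* (1 − p) + p/m ≤ 1 for m ≥ 1, hence adjusted ≤ crude always;
* p = 0 gives Ni = Cr and p = 1 gives Ni = Cr/m exactly;
* in a homogeneous population of N women where a fraction p attend
  exactly m venues and the rest one, Cr = N[(1 − p) + pm], exact
  deduplication recovers N, and Ni/N = [(1 − p) + pm][(1 − p) + p/m]
  ≥ 1 with equality iff p ∈ {0, 1} or m = 1 — i.e. the heuristic
  *overestimates* between its exact limits, so the adjusted estimate
  brackets truth from above while the crude estimate bounds it from
  further above.

Adjustment is performed at subcounty level and the adjusted subcounty
estimates are summed to the county.  Subcounties with no mobility
responses borrow county-pooled (p, m).

Conventions the field data leave open, fixed here and recorded in
every report:

* **Day.**  The level-two form collects normal- and peak-day counts but
  the procedure does not say which feeds the FSW estimate.  Default is
  the **peak day**, matching the explicit peak-day rule for the
  transactional/casual estimator; configurable to `normal`.
* **m-convention.**  `total_hotspots_visited` includes the index venue
  (a respondent visiting 2 *other* venues contributes m = 3).  This
  choice makes Ni = Cr/m exact when every woman attends the same m
  venues; it implies m ≥ 2 whenever p > 0, which the
  `MobilityParams` type enforces.
* **Range adjustment.**  The adjustment is applied to the low/high
  bounds as well as the point, preserving midpoint consistency.
* **Reporting.**  Final integer point estimates truncate toward zero
  (a county midpoint of 11777.5 is reported as 11777), matching the
  published convention for the FSW estimates; intermediate arithmetic
  is never rounded.  Percentages use decimal round-half-up, 2 decimals
  in estimate tables and 1 decimal in typology tables.
* **Overlap presence.**  A venue counts as visited by
  transactional/casual partners iff the reported peak-day maximum for
  that group is ≥ 1.

Transactional/casual estimates (ages 14–24) are peak-day midpoint sums
and are never mobility-adjusted; the women are assumed venue-local.

## Statistical analysis

Typology × subcounty and known/new × typology tables are tested with
Pearson's chi-square without continuity correction.  Expected counts
below 5 raise a warning flag on the result, and a fixed-margin
Monte-Carlo p-value (sampling tables with `scipy.stats.random_table`
under the given margins, add-one estimator) is available for sparse
tables.  All-zero rows/columns are dropped before testing; a zero
margin in an otherwise informative table is an error because expected
counts vanish.

## The synthetic county

The generator (`synthetic.GeneratorConfig`, `generate_county`) emulates
one county with known ground truth.  Defaults describe a scaled-down
county of 100 venues and 1200 FSW; `mombasa_scale()` is the ~1025-venue,
12 000-woman analogue, and `noise_free()` switches off every
observation-noise channel for exact end-to-end recovery tests.

Structure and key defaults (chosen once, as plausible values for a
coastal urban mapping round of this design):

* 4 subcounties, 2 zones each (the full-scale preset uses 9 zones);
  venues uniform over zones; typology mix dominated by local brew dens
  (0.309) and bars/restaurants (0.264).
* Each woman has a home venue; with probability `p_mobile = 0.6` she is
  mobile and visits m = 2 + Poisson(0.5) venues (mean 2.5) inside her
  subcounty — mobility is confined within subcounties to match the
  subcounty-level adjustment.  A configuration whose m exceeds the
  venues available in a subcounty is rejected as infeasible.
* 52 % of women are 14–24, so the young-FSW counts nest inside the
  all-ages counts by construction.
* Venue overlap categories: 4.6 % exclusive sex work, 10 %
  transactional-only, 0.6 % casual-only, remainder both; transactional
  and casual peak attendance are zero-truncated Poisson draws (means
  5.2 and 4.1) at venues whose category allows them.
* Observation noise: venues silently missed with probability 0.05;
  reported venues receive 1 + Poisson(0.2) mentions with a 10 % chance
  of a spelling perturbation per mention; 8 % of venues are inactive on
  validation ("hotspot turnover"); reported min/max brackets the true
  attendance with relative dispersion 0.2, using shared per-venue/day
  factors so subgroup nesting survives noise; 41 % of venues are on the
  program listing.
* Missed active venues are revealed through snowball referral with
  probability 0.7 when a discovered venue exists in their zone.

**Mobility respondent sampling.**  Respondents at a venue are drawn
from the women *based* there (up to 5 per venue by default; all of
them in noise-free mode), not from all attendees.  Sampling attendees
would select mobile women once per venue they visit and bias p upward
by construction; home-based sampling makes the recovered (p, m)
consistent estimates of the population parameters, which the test
suite checks at ~500 respondents.

Separate RNG streams per stage (landscape, mentions, level two) keep
the landscape — and hence all ground-truth identities — invariant when
only observation-noise settings change.  Everything is deterministic
under a fixed seed.

**What the generator does not model**, and what passing tests
therefore do not show about field data: informant knowledge correlated
with venue size or typology; cross-subcounty and cross-county
mobility; geographic heterogeneity of the typology mix (synthetic
typology is independent of subcounty, so the synthetic typology
chi-square is typically non-significant — unlike real counties);
seasonal/temporal venue turnover within a round; deliberate
misreporting; and count noise that is biased rather than bracketing.
Estimates on real data inherit none of the generator's guarantees
beyond the algebraic invariants.

## Problem sizes

Default test and example configurations use the 100-venue county
(fractions of a second per run); the full-scale ~1025-venue pipeline,
exercised in the test suite and the acceptance script, completes in a
few seconds.  Monte-Carlo p-values default to 2000 table draws.

## Known limitations

* Venue name matching is string-based only; there is no address or
  coordinate evidence to separate same-name venues within a zone or to
  join differently named duplicates across a zone boundary.
* The min/max "range" is a reporting range, not a confidence interval;
  no sampling uncertainty is propagated.
* The mobility adjustment is a first-moment heuristic: it ignores
  heterogeneity in m beyond the mean among movers and provably
  overestimates between its exact limits (see above).
* Counts of men frequenting venues are ingested and stored but never
  analysed, mirroring the design of the level-two instrument.
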