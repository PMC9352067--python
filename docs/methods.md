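# Methods

## Scope and data model

The pipeline consumes *stationary estimates*: one record per stop —
location (decimal degrees), arrival and departure timestamps (UTC), with
a stop defined upstream as a stay of ≥ 2 days. An individual's ordered
stop sequence for one tracking year is a *track*; tracks are complete
(the tag recorded the whole annual cycle) or partial (tag died en
route). All raw light-level processing (twilight detection, calibration,
state-space position estimation) is out of scope: the stationary table
is the interface.

All distances are great-circle on a sphere of radius 6371.0 km
(haversine). The decision thresholds downstream (250-km merge radius,
700-km diameter rule) are 500–1400 times the ≤ 0.5% error an ellipsoid
would remove, so ellipsoidal geodesy would add complexity without
changing a single decision. Coordinate averages are computed on 3-D unit
vectors and projected back to the sphere, which is exact under rotation
and immune to antimeridian wrap-around — the flyway crosses 180°
longitude, where naive longitude means fail. Turning angles are the
absolute wrapped difference of the two initial bearings at the vertex
(spherical, not planar: legs reach thousands of km).

## Track refinement

Three rules, reflecting the error structure of solar geolocation:

1. **Proximity merging.** Consecutive stops < 250 km apart are
   aggregates of one biological stop seen through positional noise; a
   maximal chain of pairwise-close stops collapses to its spherical
   centroid (unweighted by default; duration weighting is an option),
   spanning earliest arrival to latest departure. Merging repeats until
   stable, since a new centroid can fall within 250 km of its neighbor.
2. **Prefix drops.** Leading stops are removed until the bird has moved
   > 250 km from its breeding site (routine local movements, not
   migration) and until it is south of 66.7°N (continuous daylight makes
   light-level positions meaningless). Both boundaries are strict
   (`>`/`<`), matching the rules' wording. Later near-breeding or
   high-latitude stops are untouched.
3. **Turning filter.** An interior stop whose prior and subsequent stops
   subtend an angle < 60° is an out-and-back artifact; it is removed and
   its time interval absorbed into the spatially nearest surviving
   neighbor (ties to the earlier one). One stop is removed per
   iteration — smallest angle first — and angles are recomputed, which
   is deterministic and removes the sharpest artifacts first. The
   *protected stop* — the farthest from the breeding site among stops of
   ≥ 42 days — is exempt: a genuine winter terminus is a genuine
   reversal. If no stop lasts 42 days the overall farthest is used and
   the track is flagged for review; flagged tracks are carried through
   the parameter tables but excluded from network construction.

The full rule sequence is iterated to a fixed point. A single pass
cannot guarantee its own postconditions: removing a sharp-turn stop can
leave its two former neighbors closer than 250 km, and a merged centroid
can drift back inside the breeding buffer. Each pass strictly shrinks
the stop sequence, so termination is immediate, and the fixed-point
formulation buys two clean invariants — refinement is idempotent, and no
two consecutive refined stops are ever closer than the merge radius.

Every mutation is logged as a provenance event (merge with member
indices and result; drop with index; turning-removal with absorbing
neighbor). Replaying the log against the raw track reproduces the
refined track bit-for-bit; the tests assert this on every corrupted
track they touch.

## Annual-cycle segmentation

South migration begins at the departure toward the first stop south of
66.7°N and > 250 km from the breeding site. When that first stop is
itself beyond the buffer (always true for high-Arctic breeders, whose
near-breeding stops are invisible to the tag), the departure instant is
back-calculated as `arrival − distance / 58 km h⁻¹`; initiation dates
are therefore the latest possible. Winter begins at arrival at the first
stop south of 45.5°N lasting ≥ 42 days and ends at the departure from
the **last** stop (at or after winter arrival) meeting the same
condition. This look-ahead formalization is the unique reading
consistent with both halves of the boundary rule: short stops
sandwiched between long southern stays belong to winter, while a
trailing short southern stop before heading north opens north
migration. North migration ends at arrival at the first stop < 250 km
from the breeding site, else it is forward-calculated at 58 km h⁻¹ from
the final stop's departure. Stops after the return, inside the breeding
buffer, are left unlabeled (breeding period). Partial tracks yield a
partial segmentation with explicit missing-period markers rather than an
error.

**Parameters.** Minimum migration distance per period is the sum of
great-circle legs between that period's consecutive stops. The south sum
includes the breeding-site → first-stop leg and the last-south-stop →
winter-arrival leg; the north sum mirrors this. With those legs included
the totals describe the full journey between breeding and wintering
grounds and are directly comparable across subspecies with different
stop counts (a direct breeding → winter flight yields zero stops but the
single-leg distance); a switch restricts sums to within-period legs.
Speed is distance over period duration in days and thus includes fueling
time. Between-individual speed comparisons confound distance with
fueling demands, so the statistics battery deliberately excludes speed;
within-individual north/south ratios are provided instead. Dates are
compared on ordinal days 1–365, year-independent, with Feb 29 mapped to
Feb 28's index and later days shifted down one; parameters straddling
the calendar boundary are unwrapped by pushing early-year values forward
a year whenever the raw spread exceeds half a year.

## Flyway regionalization

Stops from complete, unflagged tracks are clustered jointly across
seasons (the shared region numbering across seasonal networks implies a
single regionalization), then each region's seasonal usage is classified
from its members' period labels: any winter member makes a winter
region; south/north use without winter makes a migration-only region.

The clusterer is classic PAM — greedy BUILD initialization, then
best-improvement SWAP until no single medoid↔non-medoid exchange lowers
the summed member-to-medoid great-circle cost. Everything is
deterministic and seed-free: for instances of n ≤ 200 three
deterministic starts are run (BUILD, farthest-first, quantile-spaced
over the row-sum order) and the cheapest solution kept, which on small
instances removes nearly all local optima (verified against exhaustive
enumeration in the tests); for larger n a single BUILD start suffices,
because the k-selection rule below depends on the median diameter, not
on the final few km of cost. Assignment ties break to the lower region
id, and region ids are ordered by medoid latitude then longitude so they
are stable under input permutation.

k is not chosen a priori: the search ascends k = 1, 2, 3, … and accepts
the first clustering whose **median** cluster diameter (maximum pairwise
member distance; a mean-pairwise option exists) is < 700 km — the
typical positional accuracy of a geolocator stationary estimate. The
ascending search yields the coarsest regionalization consistent with the
accuracy rule, and k = n always satisfies it, so it terminates.

## Networks and occupancy

Per season, an individual's stop sequence maps to a region sequence
(cluster membership, or nearest medoid for new points) with consecutive
duplicates collapsed. A region counts once per individual toward its
node weight; each ordered consecutive region pair counts once per
individual toward a directed edge. Weights are proportions of each
subspecies' complete-track count, so an edge weight can never exceed
either endpoint's node weight, and repeat visits or self-loops never
inflate anything. Daily occupancy marks every ordinal day in a stop's
[arrival, departure] interval, inclusive; a calendar day split between
two stops is credited to the earlier stop only, so a bird occupies at
most one region per day and per-day proportions across regions sum to
≤ 1 (travel days count toward no region, uninterpolated).

## Statistics

Fisher exact tests are two-sided by the probability-mass criterion (sum
of hypergeometric probabilities of all same-margin tables no more likely
than the observed), the convention of the standard R implementation; a
zero margin returns p = 1 with a warning. The scipy implementation is
used and is cross-checked in the tests against a from-scratch
hypergeometric enumeration over every table with margins ≤ 15 (agreement
to 1e-12). Region-use tests run per region per subspecies pair with both
samples ≥ 25 individuals.

Rank-sum tests are exact (null enumeration) for n₁+n₂ ≤ 20 without ties,
otherwise normal approximation with tie and continuity corrections;
exact p-values are cross-checked against full permutation enumeration.
The shift estimate is the Hodges–Lehmann median of pairwise differences
(first sample − second), with a 95% CI by inversion of the rank-sum
statistic: the exact path uses the null U-distribution (computed by a
subset-sum dynamic program) to pick the order statistics of the sorted
pairwise differences, matching R's `wilcox.test(conf.int=TRUE)`; the
approximate path uses the normal quantile. Parameter tests run per
parameter × period × pair among subspecies with ≥ 5 individuals; a bird
missing a parameter drops out of that test only. Reported p-values are
raw, as is conventional for descriptive pairwise comparisons; a Holm
step-down adjustment is available but off by default.

## Synthetic populations

The generator emulates the study conditions so that every stage is
testable against known truth:

* **Population.** Default bird counts mirror the published tag
  recoveries per breeding site (59 *arcticola* across three Alaskan
  sites, 35 *sakhalina* across three Chukotkan sites, 5 *kistchinski*,
  1 *actites*; overall 16% of tracks truncated to partial).
* **Itineraries.** Each subspecies draws a route variant (weighted):
  ordered staging regions, wintering region(s), and return staging,
  spanning shared core regions (NE Sea of Okhotsk, N Sakhalin Island,
  Yellow Sea) and exclusive edge regions (W Alaska for *arcticola*;
  inland China for 46% of *sakhalina*, the published proportion).
  Waypoint geography was fixed once so that the truth reproduces the
  published seasonal summaries — staggered south initiations (5 Jul /
  15 Aug / 31 Aug medians), south distances near 7,100 / 5,100 / 4,160
  km for *arcticola* / *sakhalina* / *kistchinski*, single-stop winters
  for most *arcticola* versus mobile multi-stop winters for *sakhalina*
  (~1.4 × 10³ km) — and so that a corruption-free track is a fixed point
  of the refinement rules: consecutive true stops clear the merge radius
  (a within-region redraw enforces ≥ 280 km), every non-terminal turning
  angle is ≥ 60°, and each route's farthest ≥ 42-day stop is its true
  winter terminus, so mid-winter V-shaped excursions (e.g., into inland
  China) survive exactly through the protection clause.
* **Timing.** South initiation is Gaussian per subspecies; travel
  between stops runs at the same 58 km h⁻¹ the segmentation assumes (so
  back-calculation is exactly invertible on clean data); stop durations
  are log-normal (positive, right-skewed, matching the asymmetric IQRs
  of real stop data), with wintering stays resampled to ≥ 42 days —
  a wintering stop that fails the wintering definition would make the
  truth labels internally inconsistent.
* **Corruption**, applied after truth is recorded: isotropic Gaussian
  positional noise (default sd 150 km; a latitude multiplier exists for
  anisotropic stress tests, since real solar geolocation inflates
  latitude error near equinoxes); spurious 2–4-day stops at jittered leg
  midpoints whose days are carved from an adjacent long stay (real
  arrival timestamps stay intact, as artifacts steal time rather than
  create it); out-and-back reversal spikes 350–550 km behind a stop
  (angle ≈ 0, the turning filter's target); deletion of estimates north
  of 66.7°N; an optional pre-departure stop at the breeding site; and
  random suffix truncation marking the track partial.
* One `numpy` Generator seeded once drives every draw: identical seed
  and config give byte-identical output.

**What passing tests show — and don't.** Under these conditions the
pipeline recovers true south initiation within ±2 days for ≥ 90% of
birds and the exact winter-arrival stop for ≥ 95% (measured: ~97% and
~99% at sd 150 km, spurious rate 0.15). The generator's noise is
isotropic and stationary; real geolocator error is latitude-inflated
near equinoxes and habitat-dependent, and real birds are not mixtures of
a few route variants. Passing therefore demonstrates that the *rules are
implemented correctly and are robust at the stated noise scale*, not
that the biological conclusions of any particular field dataset are
reproduced; that check requires ingesting the deposited stationary
estimates themselves (supported via the XLSX reader and
`--skip-refinement` for pre-refined rows).

## Numerical and interface choices

* Thresholds live in one overridable record: 250 km merge/buffer,
  66.7°N, 45.5°N, 42 d, 60°, 58 km h⁻¹, 700 km, 2 d, n ≥ 25 (Fisher),
  n ≥ 5 (rank-sum).
* Summaries report median and IQR (25th/75th percentile, linear
  interpolation) with per-group n.
* CSV is the canonical interchange (RFC-4180, UTF-8, exact header
  `bird_id, subspecies, site_id, breeding_lat, breeding_lon, lat, lon,
  arrival, departure, complete`); a declared alias table accepts the
  supplementary-workbook vocabulary, and XLSX ingestion skips
  README-style tabs. Input errors are reported per record with the row
  number. Timestamps are UTC; date-only values coerce to midnight.
* Networks export as GeoJSON FeatureCollections (nodes as Points at
  medoids, edges as 2-point LineStrings, per-subspecies proportions in
  properties); occupancy as long-format CSV.
* The pipeline writes a run manifest (config hash, input digests, output
  digests, warnings, versions); identical config + seed reproduce
  identical digests.

## Problem sizes

Defaults keep everything interactive: the shipped population is 100
birds (~600 stops; regionalization over all complete-track stops takes
a few seconds), property checks use 200–500 simulated tracks, PAM is
verified against exhaustive enumeration at n ≤ 12, and exact-test oracles
sweep all 2×2 tables with margins ≤ 15 and rank-sum samples with
n₁+n₂ ≤ 12. The full test suite and the acceptance script each run in
well under a minute.

## Known limitations

* Refinement boundary conventions (strict inequalities, min-arrival /
  max-departure date combining, smallest-angle-first removal) are
  declared choices where the verbal rules are ambiguous; the golden-file
  regression pins them.
* The diameter-constrained k search is greedy-ascending; a different
  schedule (e.g., bisection) could return a different k when several
  satisfy the median rule — ascending returns the smallest.
* Edges connect flyway regions only; no virtual breeding or wintering
  terminus nodes are added.
* The rank-sum CI in the tied/large-sample regime uses the normal
  quantile rather than iterative inversion; for the small exact-path
  samples the interval matches R's to the printed precision.
* Ingesting pre-refined data trusts the provider's refinement; the
  review flag (no ≥ 42-day stop) is recomputed either way.
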