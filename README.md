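# flywaynet

Migratory-network analysis of light-level geolocator tracking data for
Dunlin (*Calidris alpina*) subspecies on the East Asian–Australasian
Flyway — and, more generally, for any long-distance migrant tracked as a
sequence of *stationary estimates* (a location plus arrival/departure
timestamps for every stop of two days or longer).

Light-level geolocation is cheap enough for 50-g shorebirds but coarse:
positional error routinely reaches hundreds of kilometers and the
upstream state-space model can emit spurious stops. This package
implements the downstream analysis chain that turns such noisy stop
sequences into population-level migration structure:

1. **Track refinement** — merge consecutive stops < 250 km apart
   (spherical coordinate averaging, dates combined), drop estimates
   before the bird moved > 250 km from its breeding site or south of
   66.7°N (24-h polar daylight), and remove sharp-turn artifacts
   (interior angle < 60°), sparing the presumed winter terminus (the
   farthest stop with a stay ≥ 42 days). The rule set is iterated to a
   fixed point, with a full provenance log of every merge and drop.
2. **Annual-cycle segmentation** — label stops as south migration,
   winter, or north migration. Winter starts at the first stop south of
   45.5°N lasting ≥ 42 days and ends at the departure from the last such
   stop; departures from and arrivals at high-Arctic breeding sites are
   back/forward-calculated at an assumed 58 km h⁻¹ over the great-circle
   distance.
3. **Migration parameters** — per bird and period: initiation and
   arrival dates, duration, minimum migration distance (sum of
   great-circle legs), stop counts and stop durations, and speed
   (km day⁻¹), summarized as median and IQR per subspecies.
4. **Flyway regionalization** — deterministic PAM (k-medoids, BUILD +
   SWAP on great-circle distances), with k grown from 1 until the median
   cluster diameter falls below 700 km — the typical accuracy of a
   geolocator stationary estimate.
5. **Migratory networks** — per season, nodes (flyway regions) and
   directed edges (between-region movements) weighted by the proportion
   of individuals using them, per subspecies; plus daily occupancy
   profiles on ordinal days 1–365.
6. **Comparison statistics** — pairwise two-tailed Fisher exact tests on
   region use (subspecies with ≥ 25 individuals) and pairwise Wilcoxon
   rank-sum tests with Hodges–Lehmann shift estimates and 95% CIs on
   migration parameters (subspecies with ≥ 5 individuals).

A ground-truth-annotated synthetic population generator
(`flywaynet.synthetic`) emulates the study system — four subspecies
breeding from northern Alaska to Sakhalin Island, staggered south
migrations, shared core staging regions, geolocator-grade positional
noise, spurious stops, reversals, polar data gaps, and dead-tag
truncation — so the whole pipeline is testable end-to-end with no data
download.

## Worked example

Run the full pipeline on a simulated population with the default
study-like configuration (100 birds: 59 *arcticola*, 35 *sakhalina*,
5 *kistchinski*, 1 *actites*, matching the published tag recoveries):

```bash
flywaynet run --outdir out --seed 4
```

This writes 13 artifacts (tracks, refined tracks, segmentation,
parameters, summary, regions, three seasonal GeoJSON networks,
occupancy, stats, manifest). The south-migration block of
`out/summary.csv` from that exact command:

| subspecies  |  n | initiation (ordinal day) | duration (d) | distance (km) | speed (km/d) |
|-------------|---:|---:|---:|---:|---:|
| arcticola   | 55 | 241 | 62.6 | 7,276 | 115 |
| sakhalina   | 31 | 227 | 33.9 | 5,417 | 163 |
| kistchinski |  5 | 185 | 19.9 | 4,158 | 211 |
| actites     |  1 | 249 |  1.7 | 2,385 | 1,392 |

Medians per subspecies: *kistchinski* departs in early July, *sakhalina*
in mid-August, *arcticola* at the end of August — the staggered
south-migration pattern — while southbound *arcticola* travel ~7,300 km
over two months. The 605 refined stops cluster into 17 flyway regions
(median diameter 655 km, under the 700-km rule), and `out/stats.csv`
reports, e.g., the *arcticola*–*sakhalina* difference in south-migration
initiation as a Hodges–Lehmann shift of 17 days later (95% CI 13–21,
rank-sum p ≈ 2 × 10⁻¹⁰).

Each stage is also available separately (`flywaynet simulate | refine |
segment | parameters | regionalize | network | stats`) and as library
functions. Ingesting real stationary-estimate tables works via the same
CSV schema (or XLSX with the supplementary-table column vocabulary);
pass `--skip-refinement` for data that is already refined.

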