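# Methods

This package implements a transect-based, process-motivated index of the
coastal-protection capacity of mangrove belts — the Mangrove Coastal
Protection Index (MCPI) — together with the sampling, trend, clustering and
storm-validation machinery around it, all exercisable on a synthetic scene
generator with known ground truth.

## The index

Per analysis region (a grid cell along the coast), three factors are
extracted and combined multiplicatively:

    MCPI_k = A_k · B_k · NDVI_k · S ,   S = 1000

- **A — width-based wave attenuation.** A belt of cross-shore width `W`
  (km) attenuates incident wave/current energy approximately exponentially:
  `A = 1 − exp(−r·W)` with `r = 0.29 km⁻¹`, fitted to field and model
  current-attenuation results. `A(0) = 0`; the curve reaches one half near
  2.39 km and ~74% at 4.6 km, saturating toward 1 for very wide belts.
- **B — biomass-based frontal barrier.** Classic mangrove allometry gives
  above-ground biomass ∝ `d²h` with stem diameter `d` roughly proportional
  to height `h` below about 10 m, hence biomass ∝ `h^2.55` (using the 0.85
  exponent of the allometric fit: `(d²h)^0.85 = d^1.7·h^0.85 ~ h^2.55`).
  Normalizing at the 10 m validity limit yields `B = (h/10)^2.55` for
  `h ≤ 10 m` and `B = 1` above. The cap is deliberate and conservative; it
  also means the index is *flat* in height beyond 10 m, so destruction of
  very tall stands can be invisible to MCPI until height falls below the
  cap (asserted literally in the tests).
- **NDVI — greenness.** `(ρ_NIR − ρ_red)/(ρ_NIR + ρ_red)` as a vegetation
  condition proxy. Raw NDVI (clipped to [0, 1]) enters the product by
  default; negative values (water-contaminated cells) clip to 0 so the
  index stays non-negative. An optional `minmax_ndvi` switch rescales NDVI
  across the record set instead — both conventions appear in practice and
  the default keeps the factor on its native physical scale.

All three factors lie in [0, 1], so `0 ≤ MCPI ≤ S`, monotone
non-decreasing in each factor, and zero whenever any factor is zero.

## Transect sampling

The working coastline is the seaward outer envelope of the mangrove band:
per raster column, the seaward edge of the seaward-most mangrove cell,
simplified by Douglas–Peucker with a tolerance parameter (default one
pixel). This automates what is, on real data, a manual coastline
adjustment; the tolerance is the only tuning knob.

Transects are cast at equal arc-length spacing (default 1 km) along the
working coastline, perpendicular to it, oriented landward using the ocean
mask (the scene generator guarantees an unambiguous ocean side). Transect
length defaults to 30 km, enough to span the widest belts on record.
Each transect is walked at pixel-size steps (30 m default) placed at the
midpoints of successive pixel-length intervals, with nearest-cell lookup;
this makes the mangrove step count `N` equal the summed length (in cells)
of the mangrove segments the line crosses, gaps excluded.

Per region:

- `AMW = mean over transects of (C · N)` — by default only over
  mangrove-containing transects (effective width of the mangrove portion);
  an `include_empty_transects` switch exposes the alternative convention.
- `ACH`, `NDVI` = means over mangrove-containing transects of the
  *per-transect* means (a mean of transect means, not a pooled pixel mean
  — the two differ when transects sample unequal numbers of cells, and the
  tests pin the implemented convention).

Transects are attributed to the region polygon covering their anchor. The
synthetic regions are full-height alongshore strips, so a transect never
straddles two regions; on more general tilings the anchor rule is a
documented approximation.

## Trends and change rates

Width trends are ordinary least squares of AMW against calendar year
(years are unevenly spaced, so the regressor is the year itself and the
slope is in m/yr), with the classical two-sided t test of the slope;
series with `p ≥ 0.05` are deemed trendless. No autocorrelation correction
is applied. Two change summaries are exposed and deliberately kept apart:
the endpoint difference (last − first observation) and the fitted change
(slope × span) — they differ under noise and published tables are often
ambiguous about which was used. The annual percent rate divides the
endpoint change by the initial width and the span. The two-epoch
single-factor dynamic change rate is `K = (U_b − U_a)/U_a · 1/T · 100`
(%/yr) for any attribute `U`.

## Cluster exchange network analysis

Region–epoch rows (both epochs pooled) of min-max-normalized AMW, ACH and
NDVI are partitioned once into `k = 8` clusters (configurable) by
k-medoids — PAM with greedy build and best-swap iterations — under the
cosangle distance `d = 1 − cos(x, y)` (a `sqrt(2(1−cos))` chord variant is
selectable, since ordered-partitioning implementations differ on this
point). Pooled normalization is what makes cluster labels comparable
across epochs; per-epoch scaling would re-center each year separately.
One-level k-medoids captures exactly the functionality used of the
hierarchical ordered-partitioning family when only a single level of k
clusters is requested.

Numerical choices: the PAM build starts at the most central row and all
tie-breaks go to the lowest index, so the fit is deterministic. Cluster
labels are re-ordered by mean normalized ACH, descending, making cluster 1
"tallest" reproducibly. Rows with zero norm after normalization (a region
at the pooled minimum of all three factors) have no direction under an
angle metric; they are excluded from the fit with a warning and assigned
to the Euclidean-nearest medoid.

Fuzzy cluster allegiances come from a non-parametric bootstrap: each
replicate resamples rows with replacement, re-fits the k medoids, matches
them to the original clusters greedily by medoid-to-medoid distance, and
re-assigns every original row; membership probabilities are assignment
frequencies (rows sum to 1 exactly).

The exchange matrix cross-tabulates the common region set by epoch-A
cluster (rows) against epoch-B cluster (columns). Marginals are conserved
by construction — row sums are epoch-A cluster sizes, column sums epoch-B
sizes, the grand total the common-region count — and the off-diagonal
entries are the directed flows of the exchange network (exported as an
edge list and a networkx digraph; plotting aesthetics are out of scope).

## Storm-response validation

Severe storms are those with peak sustained wind strictly above 64 kn
whose track intersects the coastline. Each track is buffered (default
5 km) into an impact zone; a region is impacted when a mangrove cell
centre falls inside the zone. The NDVI response of each (storm × region)
area-event is the mean NDVI over the zone's mangrove cells in an *after*
snapshot minus a *before* snapshot, cells at nodata in either snapshot
excluded pairwise; temporal compositing of imagery stacks is out of scope,
the two snapshots are inputs. Responses are rank-correlated with the
regions' pre-storm MCPI by tie-corrected Spearman ρ (Pearson correlation
of mid-ranks), with the classical t-approximation p-value and an exact
permutation p available for n ≤ 10.

`run_protection_experiment` wires this end to end on a synthetic world in
which the protective hypothesis is planted: the NDVI drop inside each
impact zone is `−0.30 · (1 − MCPI/1000)` plus Gaussian noise (σ = 0.03).
It uses 53 regions of 1.5 km alongshore width, one storm per region, and a
500 m buffer so adjacent zones stay disjoint and damage never compounds —
a desk-scale choice; the 5 km default remains on the general machinery.
A positive, significant ρ on this world shows the machinery can detect a
planted protection effect; it says nothing about real imagery.

## The synthetic scene generator

Scenes are planar (projected metres), 30 m cells by default, with the
ocean on the decreasing-y side by convention and an explicit ocean mask so
samplers never guess the seaward direction. The generator emulates: a
shore-parallel band with per-region (and optionally log-normal per-column)
cross-shore width; straight or sinusoidal coastlines; constant, per-region
or gradient height fields; greenness realized by fixing red reflectance
and solving the NDVI definition for NIR (so the reflectance→NDVI path is
exercised, and an unreachable target — implied NIR > 1 — is a
configuration error); band fragmentation as i.i.d. gap cells; multi-epoch
change via per-region multiplicative factors drawn from one random stream
(so factor-1 structures are bit-identical across epochs); dieback patches;
and storm tracks crossing the coastline with winds uniform in a given
range. Everything is deterministic per (config, seed), byte for byte.

What it does *not* emulate: tides, sediment transport, species
composition, cloud artifacts, geographic (lat/lon) geometry, real
spatial autocorrelation of widths and heights, or sensor noise — the
inputs' noise model is unspecified in the source material, so synthetic
noise levels are free parameters, not calibrated claims. Passing tests
therefore demonstrate correctness of the *computations* (closure on known
truth, conservation, planted-effect recovery), not fidelity to any real
coastline.

Persistence is text-only: ESRI ASCII grids for rasters, GeoJSON for
coastline/storm tracks, CSV for truth and records.

## Pipeline

`run_pipeline` executes simulate → sample → index → trend → cena →
validate from one YAML config. A single global seed derives per-stage
seeds by hashing the stage name (blake2s, masked below 2³¹), so adding a
stage never shifts another stage's draws. Outputs are content-hashed into
a JSON-lines manifest; identical config + seed reproduces identical
hashes. Stage failures abort with the stage name; the trend stage writes
an empty table when fewer than three epochs are configured (a two-point
regression is not a trend).

## Default problem sizes

Tests and examples run on scenes of roughly 200–700 × 80–120 cells with
4–12 regions, 200–500 m transect spacing, bootstrap replicates in the
tens, and Monte-Carlo suites of 200–500 replicates — sizes chosen so the
whole suite exercises every code path on a laptop in seconds while leaving
sampling error well inside the asserted tolerances. The validation
experiment uses n = 53 area-events, matching the scale of the archival
storm analysis it mirrors.

## Known limitations

- The coastline wrap is per-column and assumes a single, roughly
  shore-parallel band; islands-in-lagoons topologies and strongly re-entrant
  coasts are out of scope, as is sub-pixel width estimation.
- Oblique transects on curved coasts may revisit cells; step counting (not
  cell de-duplication) is the implemented convention.
- The 10 m barrier cap hides height dynamics above it, by design.
- k-medoids is fit once per dataset; with very overlapping profiles the
  swap search can settle in local optima (the bootstrap membership spread
  is the diagnostic for this).
- MCPI of summary statistics is not the statistic of MCPI: quartiles of
  A, B, NDVI do not multiply into quartiles of MCPI.
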