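# Methods

## Scope and model of the analysis

habrange implements a geographic-range conservation assessment for a
species known from a handful of georeferenced collection events. The
chain is: occurrence parsing → equal-area projection → range metrics
(EOO, AOO, localities) → habitat-model inference → Area-of-Habitat
(AOH) mapping → hypergeometric map validation → Red List criterion-B
classification → KBA scoping → protected-area overlap. Each stage is a
pure function of its inputs; the pipeline driver only sequences them and
records provenance, so every reported number is recomputable from one
stage call.

## Projection and planar geometry

All areas and grids live on a Lambert azimuthal equal-area (LAEA)
projection of the *authalic sphere* (R = 6,371,007.181 m — the sphere
with the WGS84 ellipsoid's surface area). Spherical LAEA is exactly
equal-area on the sphere; against the ellipsoid the residual distortion
at the scale of a Mediterranean island (≈200 km from the projection
center) is well below 0.5 %, which the test suite checks against a
spherical-quadrangle closed form and a haversine distance oracle. The
projection center defaults to the occurrence centroid and is part of
the provenance record. Geodesic (on-ellipsoid) polygon areas are out of
scope.

EOO is the shoelace area of the convex hull of the projected records
(hull via shapely, vertices always a subset of the inputs). Hulls with
fewer than three distinct vertices, or with area under 1 m² — the
round-off envelope of the projection for collinear inputs — are flagged
degenerate with area 0. Per IUCN guidance, the reported EOO is floored
at the AOO.

Grids (2 km occupancy, 10 km KBA scan, 100 m rasters) are half-open:
cell (i, j) covers [i·s, (i+1)·s) × [j·s, (j+1)·s) from a configurable
origin, so the plane is partitioned exactly and an edge point belongs
to the higher-index cell. AOO and KBA triggering both depend on grid
placement; the origin defaults to the projection origin and a different
anchoring can shift AOO by one cell (±4 km²).

Locality counting uses single-linkage clustering: records closer than
the linkage distance (great-circle, default 10 km) are joined and
connected components counted. The published assessment states a count
of five "clearly distinct localities" without a delimitation rule;
10 km single linkage reproduces that count on the printed coordinates
and is exposed as a parameter.

## The bundled occurrence set and its sensitivity

The seven *Nesodexia corsicana* collection sites ship as a CSV with the
coordinate strings as printed on the labels (mixed DMS and decimal
forms; the parser accepts both, with hemisphere letters on either side
and fractional seconds). Two data choices matter:

- **Type locality.** The 1907 "Campo di Loro" syntypes carry no
  coordinates. The default georeference is the Campo dell'Oro plain
  near Ajaccio (41.93° N, 8.79° E), overridable in
  `corsica_occurrences()`. This point is a hull vertex: sweeping it
  across the plausible extent of the plain (±0.03–0.04°) moves the EOO
  by roughly 75–150 km², and the Sisco record's one-arc-minute
  precision adds ±1 km more. The package computes EOO ≈ 3,183 km²
  against the published 3,012 km² (≈6 %), inside that georeference
  envelope; the acceptance test therefore uses ±300 km² for EOO while
  AOO (24 km²) and the locality count (5) are asserted exactly.
- **Sisco elevation.** The label prints a 25–300 m trap-line range; the
  record carries the lower bound, making the occurrence elevation band
  25–1,244 m.

## Habitat model and AOH

The habitat model is deliberately minimal: the set of land-cover class
codes observed at the record cells plus the min–max elevation band of
the records (raster-sampled where a record lacks a printed elevation).
No buffer is applied to the band by default (`elevation_buffer_m` for
sensitivity analysis). The pipeline infers the model from contemporary
records only (year ≥ 1950 by default): land cover sampled today at a
century-old site describes the modern landscape, not the habitat that
supported the species then — which is exactly why such a record can
fall outside the mapped habitat and signal decline. Historical records
still enter the range metrics and the validation.

The AOH mask is (class suitable) ∧ (elevation in band) ∧ (cell center
inside the boundary polygon), built island-wide and clipped to the EOO
hull; the clipped map nests inside the island-wide one by construction.
Cell-center membership is used for all polygon clipping (boundary,
protected areas), so every area is a multiple of one raster cell.

## Hypergeometric validation

Records are de-duplicated to distinct occupied raster cells within the
map's domain before testing — the sampling unit is the cell, which
guards against pseudo-replication when several records share a cell.
With N domain cells, K habitat, n occupied, k in habitat, the reported
p-value is the exact upper tail P[X ≥ k], X ~ Hypergeometric(N, K, n)
(scipy), i.e. the probability that cells drawn at random without
replacement would match the occurrences' habitat hit-rate. Tests verify
exactness against full enumeration of all C(N, n) samples for N ≤ 12
and the monotone-in-k property. `better_than_random` is just the flag
p ≤ α (α = 0.05 default); no multiple-testing machinery is implied.
Records off the raster or outside the domain are excluded and counted
in the result.

## Criterion-B classifier

The threshold table: B1 on EOO (CR 100 / EN 5,000 / VU 20,000 km²), B2
on AOO (CR 10 / EN 500 / VU 2,000 km²), location caps 1 / 5 / 10 for
subcriterion a. Thresholds are inclusive (≤), following the published
assessment's wording. A level is awarded under a criterion when the
range condition and at least two subcriteria hold at that level;
subcriterion c (extreme fluctuations) is not implemented, so in
practice a (fragmentation flag or location count) and b (decline flag)
must both hold. Missing flags are treated as unmet and noted in the
output rather than guessed. The criteria string lists each criterion
triggered at the final category with its subcriteria (e.g.
`B1ab+B2ab`).

## KBA scoping

The species' global population is proxied by AOH area (the standard
move when abundance is unknown), with the EOO-clipped AOH as the
denominator — the published site total and percentage are mutually
consistent only under that choice. Each 100 m habitat cell is assigned
to the 10 km scan cell containing its center; a scan cell triggers A1
at ≥ 0.5 % of global AOH (CR/EN species; 1 % for VU) and B1 at ≥ 10 %,
thresholds that are not printed in the source analysis and follow the
KBA Standard — they are explicit config. Site boundaries are the
habitat cells inside triggering scan cells, at raster resolution. A
consequence checked as a property: any AOH larger than
cell_area/b1_fraction (1,000 km² for 10 km cells at 10 %) cannot
trigger B1 anywhere — consistent with the published null B1 result.
Reproductive-unit minima of the KBA Standard are not evaluated.

## Synthetic landscapes

The generator emulates the structure of the real inputs, not their
ecology:

- **Elevation**: white noise convolved with an isotropic Gaussian
  kernel (σ = min(n_rows, n_cols)/12 cells by default), thresholded at
  the sea_fraction quantile — so the land fraction is exact by
  construction — and rescaled to 0–2,000 m of relief (Corsica-like).
- **Land cover**: equal-width elevation bands perturbed by a rougher
  smoothed field (class_noise = 0.8 band-widths), giving a patchy
  CORINE-like mosaic whose classes correlate with, but are not
  determined by, elevation. Codes are 1..n_classes; sea is nodata.
- **Coastline**: the sub-cell sea-level contour of the smoothed field
  (union of all closed rings; interior depressions are filled).
- **Occurrences**: uniform over true-habitat cells with probability
  p_in_habitat (else uniform over land), sub-cell jitter, year 2021;
  optional historical outliers (year 1900–1949) forced outside habitat
  — emulating a record from since-converted habitat.
- **Protected area**: the part of the island on one side of a
  random-orientation line swept inland by bisection until it encloses
  the requested fraction of the coastline polygon's area (continuous
  and monotone, so any interior fraction is attainable on any island
  shape; the contract is ±2 % against the polygon area — the land-cell
  count differs from it by boundary half-cells).

Default study conditions for the end-to-end run: 500 × 500 cells at
100 m, 8 classes, 40 % sea, truth classes {3, 4} with a 100–1,400 m
band, 30 records with one historical outlier, p_in_habitat = 1, park
coverage 40 % of the island. Seeding: one integer seed; every component
draws from its own `SeedSequence([seed, k])` child stream, so adding a
generator never perturbs the others, and identical seeds give
bit-identical outputs.

What passing synthetic tests do **not** show: realism of class
semantics (no CORINE legend), land-cover succession, sampling bias of
real collection records, or the behaviour of the AOH stages on the real
CLC2018/SRTM layers — the published island-scale figures (3,559 km²
island AOH, 1,443 km² KBA, 99.7 % of AOH, 60 % park overlap) need those
external downloads and are treated as documentation examples; the
corresponding pipeline stages are instead pinned by constructed
fixtures (half-cover protected area, half-habitat triggering) exact to
one cell.

## Numerical choices and degenerate inputs

- Areas in km² = shoelace(m²)/10⁶; vertex order and translation
  invariance are property-tested.
- Antipodal points are rejected by the projection; round-trips are
  accurate to ≪1 m over the tested window.
- Empty record sets, empty habitat, empty KBA masks, header mismatches
  between rasters, and infeasible protected-area fractions raise
  `ValueError` with the offending item named; off-raster records are
  named in inference errors and counted in validation.
- p-values are clamped to (0, 1]; fractions in KBA scoping sum to 1
  over habitat-holding cells (asserted to 1e-9).
- File formats are text: Esri ASCII grid for rasters, GeoJSON for
  polygons, CSV for occurrences, JSON for reports.

## Problem sizes

The test suite runs islands up to 500 × 500 cells (2,500 km² of
landscape at 100 m), 600-record recovery samples, and exhaustive
hypergeometric enumeration to N = 12; the full synthetic end-to-end
assessment completes in a couple of seconds, and the whole suite in
under a minute on one CPU.

## Known limitations

- Spherical (authalic) rather than ellipsoidal equal-area projection:
  ≲0.3 % area bias at island scale, far below the georeference
  uncertainty of the data.
- AOO and KBA triggering depend on grid anchoring; only the default
  anchoring (projection origin) is asserted in tests, and a one-cell
  shift is the documented uncertainty.
- The locality rule (10 km single linkage) is a reconstruction; the
  source assessment did not publish its delimitation rule.
- Subcriterion c and Red List criteria A/C/D/E are not implemented;
  the classifier's "LC" means only "no criterion-B listing".
- The habitat model is presence-only and binary; no species
  distribution modelling is attempted or intended.
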