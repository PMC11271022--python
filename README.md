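# habrange

Desk-scale conservation assessment for data-poor species: IUCN
criterion-B range metrics, Area-of-Habitat (AOH) mapping with exact
hypergeometric validation, and Key Biodiversity Area (KBA) scoping —
with a synthetic-island simulator so the whole chain is testable without
downloading any land-cover, elevation or protected-area layer.

The package grew out of the assessment of *Nesodexia corsicana*, an
endangered blow fly endemic to Corsica known from seven collection
sites, and ships those occurrence records as its worked dataset. The
pipeline is species-agnostic: any occurrence table plus (optionally) a
categorical land-cover raster and an elevation raster can be assessed
the same way.

## What it computes

Given occurrence points \(p_1, \dots, p_n\) projected onto an equal-area
plane (Lambert azimuthal equal-area on the authalic sphere):

- **EOO** (extent of occurrence): the area of the minimum convex polygon
  around the points, `EOO = area(MCP)` in km².
- **AOO** (area of occupancy): `AOO = 4 · |occupied cells|` km² on a
  2 × 2 km grid (half-open cells, configurable origin).
- **Localities**: connected components of the graph joining records
  closer than a linkage distance (default 10 km, single linkage).
- **Criterion B**: the Red List threshold table — B1 on EOO
  (CR ≤ 100, EN ≤ 5,000, VU ≤ 20,000 km²), B2 on AOO (CR ≤ 10,
  EN ≤ 500, VU ≤ 2,000 km²), each requiring subcriteria
  a (severe fragmentation or ≤ 1/5/10 locations) and
  b (continuing decline).
- **AOH**: habitat mask = (land-cover class ∈ classes observed at the
  records) ∧ (elevation within the records' band) ∧ (inside the range
  boundary), at land-cover resolution (100 m cells).
- **Validation**: with N domain cells, K habitat cells, and n distinct
  record cells of which k are habitat,
  `p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n)` — the upper-tail
  hypergeometric probability of doing at least as well by drawing cells
  at random without replacement.
- **KBA scoping**: a 10 × 10 km grid scans the AOH; a cell holding a
  fraction of the global AOH ≥ 0.5 % triggers criterion A1 (threatened
  species; 1 % for VU), ≥ 10 % triggers B1 (restricted range). Site
  area, percentage of AOH inside triggering cells, and protected-area
  overlap are reported.

## Worked example

```python
import habrange as hr

records = hr.corsica_occurrences()          # 7 printed collection sites
summary, eoo = hr.summarize_range(records, linkage_km=10.0)
assessment = hr.classify_criterion_B(summary, decline_observed=True)
print(f"EOO  = {summary.eoo_km2:,.0f} km2")
print(f"AOO  = {summary.aoo_km2:,.0f} km2  "
      f"({len(summary.occupied_cells)} occupied 2x2 km cells)")
print(f"localities = {summary.n_localities}")
print(f"category = {assessment.category}  ({assessment.criteria_string})")
```

prints

```
EOO  = 3,183 km2
AOO  = 24 km2  (6 occupied 2x2 km cells)
localities = 5
category = EN  (B1ab+B2ab)
```

AOO (24 km² — six occupied 2-km cells from seven records: the two Zonza
seeps share a cell) and the locality count (5: Sisco merges with Chioso,
the Zonza pair merges) land exactly on the published assessment; EOO is
within ~6 % of the published 3,012 km², the gap being dominated by the
georeference chosen for the 1907 type locality, which has no printed
coordinates and is a vertex of the hull (see `docs/methods.md`). With a
continuing decline in habitat observed, the species classifies as
Endangered under B1 and B2ab.

The raster stages run the same way on a simulated island:

```sh
habrange assess --synthetic --seed 1 --out run/
```

```
Range metrics
  EOO: 1,585.8 km2
  AOO: 108.0 km2 (27 occupied 2x2 km cells)
  Localities (single linkage): 5

Red List (criterion B): EN B1ab+B2ab
  note: fragmentation flag unknown: locality count alone decides subcriterion a

Area of Habitat
  EOO-clipped: 254.4 km2
  island-wide: 366.9 km2

Habitat-map validation (hypergeometric)
  26 of 26 occupied cells in habitat (domain 92888 cells, 25436 habitat); p = 2.35e-15; better than random: True

Potential KBAs
  total area: 254.3 km2 (100.0% of AOH)
  triggering cells: A1 20, B1 3
  protected-area overlap: 33.3%
```

Here the simulator placed all 30 records in true habitat (one historical
outlier excluded from the EOO-clipped domain), so every occupied cell
validates and the inferred decline flag comes from the outlier sitting
outside today's habitat. Other CLI subcommands (`simulate`, `eoo`,
`aoo`, `aoh`, `validate`, `kba`, `report`) expose the individual stages;
`habrange <cmd> --help` lists their options.

Applying the AOH and KBA stages to the real island requires the CORINE
CLC2018 land-cover raster, SRTM elevation and the regional-park
boundary, which are external downloads; the published island-scale
figures (3,559 km² island-wide AOH, 1,443 km² of potential KBAs covering
99.7 % of the AOH, 60 % park overlap) are therefore documentation
examples here, not package outputs.

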