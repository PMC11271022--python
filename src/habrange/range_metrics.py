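"""IUCN criterion-B range metrics and Red List classifier.

Extent of occurrence (EOO) is the area of the minimum convex polygon
around all occurrence points, computed on an equal-area plane.  Area of
occupancy (AOO) is 4 km² times the number of occupied cells of a 2 × 2
km grid.  Localities are delimited by single-linkage clustering of the
records at a configurable distance.  The classifier applies the
criterion-B threshold table (subcriteria a: fragmentation / number of
locations, and b: continuing decline; extreme fluctuations, subcriterion
c, are not evaluated).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .geo import (
    GridSpec,
    ProjectionSpec,
    cell_index,
    convex_hull,
    haversine_km,
    polygon_area_km2,
    project,
)

__all__ = [
    "OccurrenceRecord",
    "RangeSummary",
    "RedListAssessment",
    "EooResult",
    "compute_eoo",
    "compute_aoo",
    "count_localities",
    "classify_criterion_B",
    "summarize_range",
]

AOO_CELL_SIZE_M = 2_000.0
DEFAULT_LINKAGE_KM = 10.0

# Criterion-B range thresholds, km² (category: strict upper bound).
B1_EOO_THRESHOLDS = {"CR": 100.0, "EN": 5_000.0, "VU": 20_000.0}
B2_AOO_THRESHOLDS = {"CR": 10.0, "EN": 500.0, "VU": 2_000.0}
# Subcriterion a: maximum number of locations per category.
LOCATION_THRESHOLDS = {"CR": 1, "EN": 5, "VU": 10}
_CATEGORY_ORDER = ["CR", "EN", "VU"]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced collection event."""

    id: str
    lon: float
    lat: float
    year: int | None = None
    elevation_m: float | None = None
    georeference_note: str = ""

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"record {self.id!r}: longitude {self.lon} out of range")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"record {self.id!r}: latitude {self.lat} out of range")
        if self.year is not None and self.year > datetime.date.today().year:
            raise ValueError(f"record {self.id!r}: year {self.year} is in the future")


@dataclass
class EooResult:
    """Minimum convex polygon and its equal-area extent."""

    hull_xy: np.ndarray          # (m, 2) CCW ring, projected meters
    eoo_km2: float
    degenerate: bool             # < 3 non-collinear records
    projection: ProjectionSpec


@dataclass
class RangeSummary:
    eoo_km2: float
    aoo_km2: float
    n_localities: int
    occupied_cells: set[tuple[int, int]]
    n_records: int
    eoo_degenerate: bool = False

    def __post_init__(self) -> None:
        assert self.aoo_km2 == 4 * len(self.occupied_cells)


@dataclass
class RedListAssessment:
    """Criterion-B outcome: category plus the criteria string.

    ``category`` is one of LC/NT/VU/EN/CR ("LC" here meaning only that
    no criterion-B listing applies; other criteria are out of scope).
    ``triggered_thresholds`` records, per criterion, the threshold bin
    that was crossed.
    """

    category: str
    criteria_string: str
    triggered_thresholds: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _records_lonlat(records) -> tuple[np.ndarray, np.ndarray]:
    if len(records) == 0:
        raise ValueError("no occurrence records")
    lons = np.array([r.lon for r in records], dtype=float)
    lats = np.array([r.lat for r in records], dtype=float)
    return lons, lats


def compute_eoo(records, projection: ProjectionSpec | None = None) -> EooResult:
    """Extent of occurrence: minimum convex polygon area in km².

    With fewer than three non-collinear records the polygon is
    degenerate (a point or a segment) and the area is 0, flagged in the
    result.  The IUCN floor (EOO may not be smaller than AOO) is applied
    downstream in :func:`summarize_range`, where AOO is known.
    """
    lons, lats = _records_lonlat(records)
    if projection is None:
        projection = ProjectionSpec.for_points(lons, lats)
    x, y = project(lons, lats, projection)
    hull = convex_hull(np.column_stack([x, y]))
    area = polygon_area_km2(hull)
    # hulls under 1 m2 are point/collinear sets up to projection round-off
    degenerate = hull.shape[0] < 3 or area < 1e-9
    if degenerate:
        area = 0.0
    return EooResult(hull_xy=hull, eoo_km2=area, degenerate=degenerate, projection=projection)


def compute_aoo(
    records,
    projection: ProjectionSpec | None = None,
    grid: GridSpec | None = None,
) -> tuple[set[tuple[int, int]], float]:
    """Area of occupancy on a 2 × 2 km grid: 4 km² per occupied cell.

    The grid is anchored at the projection origin by default; AOO can
    shift by one cell under a different anchoring (documented
    sensitivity, configurable via ``grid``).
    """
    lons, lats = _records_lonlat(records)
    if projection is None:
        projection = ProjectionSpec.for_points(lons, lats)
    if grid is None:
        grid = GridSpec(cell_size=AOO_CELL_SIZE_M)
    x, y = project(lons, lats, projection)
    cells = cell_index(x, y, grid)
    occupied = {(int(i), int(j)) for i, j in np.atleast_2d(cells)}
    return occupied, 4.0 * len(occupied)


def count_localities(records, linkage_km: float = DEFAULT_LINKAGE_KM) -> int:
    """Number of distinct localities by single-linkage clustering.

    Two records closer than ``linkage_km`` (great-circle) are joined;
    localities are the connected components of the resulting graph.
    """
    if linkage_km <= 0:
        raise ValueError("linkage_km must be positive")
    lons, lats = _records_lonlat(records)
    n = lons.size
    if n == 1:
        return 1
    pts = np.column_stack([lons, lats])
    dist = squareform(
        pdist(pts, metric=lambda a, b: haversine_km(a[0], a[1], b[0], b[1]))
    )
    adj = csr_matrix(dist < linkage_km)
    n_comp, _ = connected_components(adj, directed=False)
    return int(n_comp)


def summarize_range(
    records,
    projection: ProjectionSpec | None = None,
    linkage_km: float = DEFAULT_LINKAGE_KM,
    aoo_grid: GridSpec | None = None,
) -> tuple[RangeSummary, EooResult]:
    """EOO, AOO and locality count in one pass, with the IUCN EOO floor
    (EOO is raised to AOO when the hull area falls below it)."""
    lons, lats = _records_lonlat(records)
    if projection is None:
        projection = ProjectionSpec.for_points(lons, lats)
    eoo = compute_eoo(records, projection)
    occupied, aoo_km2 = compute_aoo(records, projection, aoo_grid)
    eoo_km2 = max(eoo.eoo_km2, aoo_km2)
    summary = RangeSummary(
        eoo_km2=eoo_km2,
        aoo_km2=aoo_km2,
        n_localities=count_localities(records, linkage_km),
        occupied_cells=occupied,
        n_records=len(records),
        eoo_degenerate=eoo.degenerate,
    )
    return summary, eoo


def classify_criterion_B(
    summary: RangeSummary,
    decline_observed: bool | None = None,
    severely_fragmented: bool | None = None,
) -> RedListAssessment:
    """Apply the criterion-B threshold table.

    A category is triggered under B1 (EOO) or B2 (AOO) at a level when
    the range metric is below that level's threshold *and* at least two
    subcriteria hold at that level.  Implemented subcriteria:
    a — severe fragmentation or number of locations at or below the
    level's cap; b — continuing decline observed.  Subcriterion c is not
    evaluated, so in practice both a and b must hold.  ``None`` flags
    are treated as unmet and noted in the output.
    """
    notes: list[str] = []
    if decline_observed is None:
        notes.append("decline flag missing: subcriterion b treated as unmet")
        decline_observed = False
    if severely_fragmented is None:
        notes.append("fragmentation flag unknown: locality count alone decides subcriterion a")
        severely_fragmented = False

    triggered: dict[str, str] = {}
    per_criterion: dict[str, dict[str, str]] = {}
    for crit, thresholds, value in (
        ("B1", B1_EOO_THRESHOLDS, summary.eoo_km2),
        ("B2", B2_AOO_THRESHOLDS, summary.aoo_km2),
    ):
        for cat in _CATEGORY_ORDER:
            if value > thresholds[cat]:
                continue
            sub_a = severely_fragmented or summary.n_localities <= LOCATION_THRESHOLDS[cat]
            sub_b = bool(decline_observed)
            if sub_a and sub_b:
                triggered[crit] = cat
                per_criterion[crit] = {"range": f"<= {thresholds[cat]:g} km2", "subcriteria": "ab"}
                break

    if not triggered:
        return RedListAssessment(
            category="LC",
            criteria_string="",
            triggered_thresholds={},
            notes=notes + ["no criterion-B threshold met"],
        )

    best = min(triggered.values(), key=_CATEGORY_ORDER.index)
    parts = [
        f"{crit}{per_criterion[crit]['subcriteria']}"
        for crit in ("B1", "B2")
        if triggered.get(crit) == best
    ]
    return RedListAssessment(
        category=best,
        criteria_string="+".join(parts),
        triggered_thresholds={c: triggered[c] for c in triggered},
        notes=notes,
    )
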