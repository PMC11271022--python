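"""Key Biodiversity Area scoping on a 10 × 10 km grid.

The species' global population is proxied by its Area of Habitat.  A
coarse grid scans the range; each cell's share of the global AOH area is
its estimated share of the global population.  A cell becomes a
potential KBA under criterion A1 (threatened species) or B1
(geographically restricted species) when its share reaches the
criterion's threshold.  Site boundaries are the habitat cells, at the
land-cover resolution, inside triggering grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .aoh import AohMap
from .geo import GridSpec

__all__ = ["KbaThresholds", "KbaResult", "scope_kba", "summarize_kba", "pa_overlap"]

KBA_CELL_SIZE_M = 10_000.0

# KBA Standard population-share thresholds: A1 for CR/EN species 0.5%
# (1% for VU); B1 (restricted range) 10%.
A1_FRACTION_CR_EN = 0.005
A1_FRACTION_VU = 0.01
B1_FRACTION = 0.10


@dataclass(frozen=True)
class KbaThresholds:
    """Minimum fraction of the global population a site must hold."""

    a1_fraction: float = A1_FRACTION_CR_EN
    b1_fraction: float = B1_FRACTION

    def __post_init__(self) -> None:
        if not (0.0 < self.a1_fraction < self.b1_fraction <= 1.0):
            raise ValueError("need 0 < a1_fraction < b1_fraction <= 1")

    @classmethod
    def for_category(cls, category: str) -> "KbaThresholds":
        """A1 sub-threshold chosen by the species' Red List category."""
        if category in ("CR", "EN"):
            return cls(a1_fraction=A1_FRACTION_CR_EN)
        if category == "VU":
            return cls(a1_fraction=A1_FRACTION_VU)
        raise ValueError(f"A1 applies to threatened species only, not {category!r}")


@dataclass
class KbaResult:
    """Scoping-grid outcome.

    ``cell_fractions`` maps scan-grid cells (i, j) to their share of the
    global AOH area (sums to 1 over cells containing habitat);
    ``kba_mask`` is the habitat mask restricted to triggering cells, at
    the AOH resolution.
    """

    grid: GridSpec
    cell_fractions: dict[tuple[int, int], float]
    triggered_cells: dict[str, set[tuple[int, int]]]
    kba_mask: np.ndarray
    total_area_km2: float
    pct_of_aoh: float
    pa_overlap_pct: float | None = None

    @property
    def any_triggered(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for cells in self.triggered_cells.values():
            out |= cells
        return out


def scope_kba(
    aoh: AohMap,
    grid: GridSpec | None = None,
    thresholds: KbaThresholds | None = None,
) -> KbaResult:
    """Scan the AOH with a coarse grid and trigger A1/B1 cells.

    Each AOH cell is assigned to the scan-grid cell containing its
    center (half-open cells).  Cell fraction = habitat area in the cell
    / global AOH area.
    """
    if grid is None:
        grid = GridSpec(cell_size=KBA_CELL_SIZE_M)
    if thresholds is None:
        thresholds = KbaThresholds()
    header = aoh.header
    total_cells = int(aoh.mask.sum())
    if total_cells == 0:
        raise ValueError("AOH is empty; nothing to scope")

    rows, cols = np.nonzero(aoh.mask)
    cx = header.origin_x + (cols + 0.5) * header.cell_size
    cy = header.origin_y + (header.n_rows - 1 - rows + 0.5) * header.cell_size
    gi = np.floor((cx - grid.origin_x) / grid.cell_size).astype(int)
    gj = np.floor((cy - grid.origin_y) / grid.cell_size).astype(int)

    fractions: dict[tuple[int, int], float] = {}
    pairs, counts = np.unique(np.column_stack([gi, gj]), axis=0, return_counts=True)
    for (i, j), c in zip(pairs, counts):
        fractions[(int(i), int(j))] = float(c) / total_cells

    a1 = {c for c, f in fractions.items() if f >= thresholds.a1_fraction}
    b1 = {c for c, f in fractions.items() if f >= thresholds.b1_fraction}
    triggering = a1 | b1

    kba_mask = np.zeros_like(aoh.mask)
    in_trig = np.array([(int(i), int(j)) in triggering for i, j in zip(gi, gj)])
    kba_mask[rows[in_trig], cols[in_trig]] = True

    total_area = float(kba_mask.sum()) * header.cell_area_km2
    pct = 100.0 * float(kba_mask.sum()) / total_cells
    return KbaResult(
        grid=grid,
        cell_fractions=fractions,
        triggered_cells={"A1": a1, "B1": b1},
        kba_mask=kba_mask,
        total_area_km2=total_area,
        pct_of_aoh=pct,
    )


def summarize_kba(result: KbaResult, aoh: AohMap) -> tuple[float, float]:
    """(total potential-KBA area km², percentage of the AOH it covers)."""
    if result.kba_mask.shape != aoh.mask.shape:
        raise ValueError("KBA mask and AOH do not share a header")
    n_aoh = int(aoh.mask.sum())
    n_kba = int(result.kba_mask.sum())
    total = n_kba * aoh.header.cell_area_km2
    pct = 100.0 * n_kba / n_aoh if n_aoh else 0.0
    return float(total), float(pct)


def pa_overlap(result: KbaResult, aoh: AohMap, protected_areas) -> float:
    """Percentage of the potential-KBA area inside protected areas.

    ``protected_areas`` is a shapely geometry or an iterable of them;
    cell membership is by cell center.
    """
    n_kba = int(result.kba_mask.sum())
    if n_kba == 0:
        raise ValueError("empty KBA mask; no overlap to measure")
    if isinstance(protected_areas, BaseGeometry):
        geoms = [protected_areas]
    else:
        geoms = list(protected_areas)
        if not geoms:
            raise ValueError("no protected-area polygons given")
    union = shapely.union_all(geoms)
    shapely.prepare(union)
    header = aoh.header
    rows, cols = np.nonzero(result.kba_mask)
    cx = header.origin_x + (cols + 0.5) * header.cell_size
    cy = header.origin_y + (header.n_rows - 1 - rows + 0.5) * header.cell_size
    inside = shapely.contains_xy(union, cx, cy)
    return 100.0 * float(inside.sum()) / n_kba
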