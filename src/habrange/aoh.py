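"""Area of Habitat: inference, mapping and hypergeometric validation.

The habitat model is deliberately minimal — the set of land-cover
classes observed at the occurrence points plus their elevation band —
mirroring how AOH maps are built from a land-cover proxy and elevation
limits when nothing else is known about a species.  The resulting
boolean mask doubles as the population-size proxy for KBA scoping.

Validation asks whether the occurrences fall inside mapped habitat more
often than cells drawn at random without replacement from the domain:
an upper-tail hypergeometric test on occupied cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.stats import hypergeom
from shapely.geometry.base import BaseGeometry

from .raster import CategoricalRaster, ElevationRaster, RasterHeader

__all__ = [
    "HabitatModel",
    "AohMap",
    "ValidationResult",
    "infer_habitat_model",
    "build_aoh",
    "validate_aoh",
]


@dataclass(frozen=True)
class HabitatModel:
    """Suitable land-cover classes plus an elevation band."""

    suitable_classes: frozenset[int]
    elev_min: float
    elev_max: float

    def __post_init__(self) -> None:
        if not self.suitable_classes:
            raise ValueError("habitat model needs at least one suitable class")
        if self.elev_min > self.elev_max:
            raise ValueError("elev_min exceeds elev_max")

    def with_elevation_buffer(self, buffer_m: float) -> "HabitatModel":
        """Widened elevation band for sensitivity analysis."""
        return HabitatModel(
            self.suitable_classes, self.elev_min - buffer_m, self.elev_max + buffer_m
        )


@dataclass
class AohMap:
    """Boolean habitat mask with area bookkeeping.

    ``domain_mask`` marks the cells the map was built over (land cells,
    optionally clipped to a boundary polygon such as the EOO hull);
    ``mask`` (habitat) is always a subset of it.  ``domain`` is a label:
    ``"eoo-clipped"`` or ``"island-wide"``.
    """

    header: RasterHeader
    mask: np.ndarray
    domain_mask: np.ndarray
    domain: str = "island-wide"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.mask.shape != (self.header.n_rows, self.header.n_cols):
            raise ValueError("mask shape does not match header")
        if np.any(self.mask & ~self.domain_mask):
            raise ValueError("habitat mask extends outside the domain")

    @property
    def area_km2(self) -> float:
        return float(self.mask.sum()) * self.header.cell_area_km2

    @property
    def domain_area_km2(self) -> float:
        return float(self.domain_mask.sum()) * self.header.cell_area_km2


@dataclass
class ValidationResult:
    """Hypergeometric comparison of occurrences against the habitat map.

    N domain cells of which K are habitat; n distinct occupied cells of
    which k fall in habitat.  ``p_value`` is the probability of at least
    k habitat cells among n drawn without replacement.
    """

    N: int
    K: int
    n: int
    k: int
    p_value: float
    better_than_random: bool
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n <= self.N and 0 <= self.K <= self.N):
            raise ValueError("inconsistent hypergeometric counts")


def infer_habitat_model(
    records,
    landcover: CategoricalRaster,
    elevation: ElevationRaster,
    projection,
    elevation_buffer_m: float = 0.0,
) -> HabitatModel:
    """Habitat model from the land-cover classes and elevations at the records.

    The elevation band is the [min, max] of the record elevations; a
    record without a reported elevation is assigned the raster value at
    its cell.  Records falling off the raster (or on sea cells) are
    rejected with an error listing them.
    """
    from .geo import project

    _check_headers(landcover.header, elevation.header)
    lons = np.array([r.lon for r in records], dtype=float)
    lats = np.array([r.lat for r in records], dtype=float)
    if lons.size == 0:
        raise ValueError("no occurrence records")
    x, y = project(lons, lats, projection)
    codes = landcover.sample(x, y)
    off = codes == landcover.header.nodata_code
    if np.all(off):
        bad = ", ".join(r.id for r, o in zip(records, off) if o)
        raise ValueError(f"all records fall off the land-cover raster: {bad}")
    raster_elev = elevation.sample(x, y)
    elevs = np.array(
        [
            r.elevation_m if r.elevation_m is not None else raster_elev[i]
            for i, r in enumerate(records)
        ],
        dtype=float,
    )
    on = ~off & np.isfinite(elevs)
    classes = frozenset(int(c) for c in codes[~off])
    model = HabitatModel(
        suitable_classes=classes,
        elev_min=float(np.min(elevs[on])),
        elev_max=float(np.max(elevs[on])),
    )
    if elevation_buffer_m:
        model = model.with_elevation_buffer(elevation_buffer_m)
    return model


def _check_headers(a: RasterHeader, b: RasterHeader) -> None:
    if a != b:
        raise ValueError(f"raster headers differ: {a} vs {b}")


def build_aoh(
    landcover: CategoricalRaster,
    elevation: ElevationRaster,
    model: HabitatModel,
    boundary: BaseGeometry | None = None,
    domain: str | None = None,
) -> AohMap:
    """Habitat mask: suitable class AND elevation band AND inside boundary.

    Cell membership in the boundary polygon is decided by the cell
    center.  With no boundary the domain is the whole landmass
    ("island-wide").
    """
    _check_headers(landcover.header, elevation.header)
    header = landcover.header
    suitable = np.isin(landcover.values, list(model.suitable_classes))
    in_band = (
        np.isfinite(elevation.values)
        & (elevation.values >= model.elev_min)
        & (elevation.values <= model.elev_max)
    )
    domain_mask = landcover.land_mask & elevation.land_mask
    if boundary is not None:
        cx, cy = header.cell_centers()
        shapely.prepare(boundary)
        inside = shapely.contains_xy(boundary, cx.ravel(), cy.ravel())
        domain_mask = domain_mask & inside.reshape(header.n_rows, header.n_cols)
        label = "eoo-clipped"
    else:
        label = "island-wide"
    mask = suitable & in_band & domain_mask
    return AohMap(header=header, mask=mask, domain_mask=domain_mask, domain=domain or label)


def validate_aoh(
    aoh: AohMap,
    records,
    projection,
    alpha: float = 0.05,
) -> ValidationResult:
    """Upper-tail hypergeometric test of the habitat map.

    Records are de-duplicated to distinct occupied raster cells within
    the domain (pseudo-replication guard): n is the number of those
    cells, k how many are habitat, out of N domain cells with K habitat
    cells.  p = P[X >= k] for X ~ Hypergeom(N, K, n); the map is
    flagged ``better_than_random`` when p <= alpha.  Records off the
    raster or outside the domain are excluded and counted.
    """
    from .geo import project

    lons = np.array([r.lon for r in records], dtype=float)
    lats = np.array([r.lat for r in records], dtype=float)
    if lons.size == 0:
        raise ValueError("no occurrence records")
    header = aoh.header
    x, y = project(lons, lats, projection)
    row, col = header.index_of(x, y)
    inside = header.contains(x, y)
    row_c = np.clip(row, 0, header.n_rows - 1)
    col_c = np.clip(col, 0, header.n_cols - 1)
    in_domain = inside & aoh.domain_mask[row_c, col_c]
    cells = {(int(r), int(c)) for r, c, ok in zip(row, col, in_domain) if ok}
    n_excluded = int((~in_domain).sum())
    if not cells:
        raise ValueError("no record falls inside the map domain")
    N = int(aoh.domain_mask.sum())
    K = int(aoh.mask.sum())
    if K < 1:
        raise ValueError("habitat map is empty; nothing to validate")
    n = len(cells)
    k = sum(1 for r, c in cells if aoh.mask[r, c])
    if n > N:
        raise ValueError("more occupied cells than domain cells")
    # P[X >= k] = sf(k-1); sampling cells without replacement.
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return ValidationResult(
        N=N, K=K, n=n, k=k,
        p_value=p,
        better_than_random=bool(p <= alpha),
        n_excluded=n_excluded,
    )
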