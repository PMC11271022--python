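"""Synthetic island landscapes for end-to-end testing without downloads.

The generator emulates the inputs a real assessment consumes: a smooth
elevation field thresholded at a sea-level quantile (coastline), a
CORINE-like categorical mosaic driven by elevation bands with patchy
noise, habitat-conditioned occurrence points (optionally with historical
outliers outside habitat, mimicking a pre-war record from since-lost
habitat), and a protected-area polygon of prescribed coverage.

All randomness flows from a single integer seed; each component draws
from its own child stream, so adding a generator does not perturb the
output of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from .geo import ProjectionSpec, unproject
from .raster import CategoricalRaster, ElevationRaster, RasterHeader
from .range_metrics import OccurrenceRecord

__all__ = [
    "SyntheticTruth",
    "IslandLandscape",
    "generate_island",
    "sample_occurrences",
    "generate_protected_area",
]

#: Default projection center: a Corsica-like spot in the west Mediterranean.
DEFAULT_PROJECTION = ProjectionSpec(center_lon=9.0, center_lat=42.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth habitat model used to condition occurrence sampling."""

    suitable_classes: frozenset[int]
    elev_min: float
    elev_max: float
    p_in_habitat: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_in_habitat <= 1.0):
            raise ValueError("p_in_habitat must lie in [0, 1]")
        if self.elev_min > self.elev_max:
            raise ValueError("elev_min exceeds elev_max")


@dataclass
class IslandLandscape:
    """A generated island: rasters, coastline and their georeferencing."""

    landcover: CategoricalRaster
    elevation: ElevationRaster
    coastline: shapely.Geometry | None
    projection: ProjectionSpec = DEFAULT_PROJECTION

    @property
    def land_area_km2(self) -> float:
        return float(self.landcover.land_mask.sum()) * self.landcover.header.cell_area_km2

    def habitat_mask(self, truth: SyntheticTruth) -> np.ndarray:
        """Boolean habitat cells implied by a ground-truth model."""
        lc, el = self.landcover.values, self.elevation.values
        return (
            np.isin(lc, list(truth.suitable_classes))
            & np.isfinite(el)
            & (el >= truth.elev_min)
            & (el <= truth.elev_max)
        )


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int, sigma: float) -> np.ndarray:
    field = rng.standard_normal((n_rows, n_cols))
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    return (field - field.mean()) / field.std()


def generate_island(
    seed: int,
    n_rows: int = 500,
    n_cols: int = 500,
    n_classes: int = 8,
    sea_fraction: float = 0.4,
    cell_size: float = 100.0,
    max_elevation_m: float = 2000.0,
    smooth_sigma: float | None = None,
    class_noise: float = 0.8,
    projection: ProjectionSpec = DEFAULT_PROJECTION,
    nodata_code: int = -9999,
) -> IslandLandscape:
    """Generate an island landscape.

    The elevation surface is white noise convolved with an isotropic
    Gaussian kernel; the sea-level is its ``sea_fraction`` quantile, so
    the land fraction of the grid is 1 − sea_fraction by construction.
    Land-cover classes follow equal-width elevation bands perturbed by a
    second, rougher smoothed field, producing a patchy categorical
    mosaic.  The raster is centered on the projection origin.

    Identical seeds give bit-identical outputs.
    """
    if n_classes < 2:
        raise ValueError("need at least two land-cover classes")
    if not (0.0 < sea_fraction < 1.0):
        raise ValueError("sea_fraction must lie strictly in (0, 1)")
    if n_rows * n_cols * (1.0 - sea_fraction) < 9:
        raise ValueError("grid too small to contain land")
    if smooth_sigma is None:
        smooth_sigma = max(3.0, min(n_rows, n_cols) / 12.0)

    ss = np.random.SeedSequence([int(seed), 0])
    elev_stream, class_stream = [np.random.default_rng(s) for s in ss.spawn(2)]

    field = _smooth_field(elev_stream, n_rows, n_cols, smooth_sigma)
    sea_level = float(np.quantile(field, sea_fraction))
    land = field > sea_level
    if not land.any():
        raise ValueError("grid too small to contain land")

    top = float(field.max())
    relief = top - sea_level
    elevation = np.where(land, (field - sea_level) / relief * max_elevation_m, np.nan)

    # Elevation bands -> classes, perturbed by a rougher field so class
    # patches cut across contour lines like a real land-cover mosaic.
    band = np.zeros((n_rows, n_cols))
    band[land] = elevation[land] / max_elevation_m * n_classes
    noise = _smooth_field(class_stream, n_rows, n_cols, max(1.0, smooth_sigma / 4.0))
    band = band + class_noise * noise
    classes = np.clip(np.floor(band), 0, n_classes - 1).astype(int) + 1
    classes[~land] = nodata_code

    header = RasterHeader(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=-n_cols * cell_size / 2.0,
        origin_y=-n_rows * cell_size / 2.0,
        cell_size=cell_size,
        nodata_code=nodata_code,
    )
    landcover = CategoricalRaster(header, classes)
    elev_raster = ElevationRaster(header, elevation)
    coastline = _coastline_polygon(field, sea_level, header)
    return IslandLandscape(landcover, elev_raster, coastline, projection)


def _coastline_polygon(field: np.ndarray, sea_level: float, header: RasterHeader):
    """Sea-level contours of the smoothed field as a (multi)polygon.

    All above-sea-level regions are kept, so multi-island landscapes get
    a multi-part coastline; interior below-sea-level depressions (lakes)
    are filled by the union.
    """
    padded = np.pad(field, 1, constant_values=field.min() - 1.0)
    contours = measure.find_contours(padded, sea_level)
    polys = []
    for cont in contours:
        if len(cont) < 4:
            continue
        rr = cont[:, 0] - 1.0
        cc = cont[:, 1] - 1.0
        x = header.origin_x + (cc + 0.5) * header.cell_size
        y = header.origin_y + (header.n_rows - 1 - rr + 0.5) * header.cell_size
        poly = Polygon(np.column_stack([x, y]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if not poly.is_empty:
            polys.append(poly)
    if not polys:
        raise ValueError("no coastline found")
    return shapely.union_all(polys)


def sample_occurrences(
    truth: SyntheticTruth,
    landscape: IslandLandscape,
    n: int,
    n_outliers: int = 0,
    jitter: bool = True,
) -> list[OccurrenceRecord]:
    """Draw habitat-conditioned occurrence records.

    ``n − n_outliers`` contemporary records are placed uniformly over
    habitat cells with probability ``truth.p_in_habitat`` each (else
    uniformly over any land cell); ``n_outliers`` historical records
    (year < 1950) are forced onto land cells *outside* the habitat.
    Point coordinates are cell centers with optional sub-cell jitter,
    unprojected to lon/lat.
    """
    if n_outliers > n:
        raise ValueError("more outliers than records requested")
    header = landscape.landcover.header
    habitat = landscape.habitat_mask(truth)
    land = landscape.landcover.land_mask
    if not habitat.any():
        raise ValueError("ground-truth habitat is empty on this island")
    non_habitat_land = land & ~habitat
    if n_outliers > 0 and not non_habitat_land.any():
        raise ValueError("no land outside habitat to place outliers on")

    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 1]))
    hab_idx = np.flatnonzero(habitat.ravel())
    land_idx = np.flatnonzero(land.ravel())
    out_idx = np.flatnonzero(non_habitat_land.ravel())

    records: list[OccurrenceRecord] = []
    n_normal = n - n_outliers
    in_habitat = rng.random(n_normal) < truth.p_in_habitat
    for i in range(n_normal):
        pool = hab_idx if in_habitat[i] else land_idx
        flat = int(rng.choice(pool))
        records.append(_make_record(f"occ-{i:04d}", flat, header, landscape, rng, jitter, year=2021))
    for i in range(n_outliers):
        flat = int(rng.choice(out_idx))
        year = int(rng.integers(1900, 1950))
        records.append(
            _make_record(f"hist-{i:04d}", flat, header, landscape, rng, jitter, year=year, note="historical outlier")
        )
    return records


def _make_record(
    rec_id: str,
    flat: int,
    header: RasterHeader,
    landscape: IslandLandscape,
    rng: np.random.Generator,
    jitter: bool,
    year: int,
    note: str = "synthetic",
) -> OccurrenceRecord:
    r, c = divmod(flat, header.n_cols)
    dx, dy = (rng.uniform(-0.49, 0.49, size=2) if jitter else (0.0, 0.0))
    x = header.origin_x + (c + 0.5 + dx) * header.cell_size
    y = header.origin_y + (header.n_rows - 1 - r + 0.5 + dy) * header.cell_size
    lon, lat = unproject(x, y, landscape.projection)
    elev = landscape.elevation.values[r, c]
    return OccurrenceRecord(
        id=rec_id,
        lon=float(lon),
        lat=float(lat),
        year=year,
        elevation_m=float(elev) if np.isfinite(elev) else None,
        georeference_note=note,
    )


def generate_protected_area(
    seed: int,
    coastline: Polygon,
    coverage_fraction: float,
    tol: float = 0.001,
) -> shapely.Geometry:
    """Polygonal protected area covering a prescribed share of the island.

    The area is the part of the island on one side of a straight
    boundary line of random orientation, swept inland until the enclosed
    share of the coastline polygon's area equals ``coverage_fraction``
    (bisection; the enclosed area is continuous and monotone in the
    sweep position, so any interior fraction is attainable).  The result
    is a polygon, or a multi-part polygonal region when the sweep line
    cuts a multi-lobed island into pieces.
    """
    if not (0.0 < coverage_fraction <= 0.95):
        raise ValueError("coverage_fraction must lie in (0, 0.95]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    theta = rng.uniform(0.0, np.pi)
    ux, uy = np.cos(theta), np.sin(theta)
    island_area = coastline.area
    xs, ys = shapely.get_coordinates(coastline).T
    proj = ux * xs + uy * ys
    lo, hi = float(proj.min()), float(proj.max())

    minx, miny, maxx, maxy = coastline.bounds
    diag = float(np.hypot(maxx - minx, maxy - miny)) * 2.0

    def clipped(t: float) -> shapely.Geometry:
        # Half-plane {u . p <= t} as a large rectangle oriented along the line.
        cx_, cy_ = ux * t, uy * t
        px, py = -uy, ux
        corners = [
            (cx_ + px * diag, cy_ + py * diag),
            (cx_ - px * diag, cy_ - py * diag),
            (cx_ - px * diag - ux * diag, cy_ - py * diag - uy * diag),
            (cx_ + px * diag - ux * diag, cy_ + py * diag - uy * diag),
        ]
        return coastline.intersection(Polygon(corners))

    target = coverage_fraction * island_area
    mid = 0.5 * (lo + hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        area = clipped(mid).area
        if abs(area - target) <= tol * island_area:
            break
        if area < target:
            lo = mid
        else:
            hi = mid
    pa = clipped(mid)
    if pa.is_empty:
        raise ValueError("could not carve a protected area of the requested size")
    return pa
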