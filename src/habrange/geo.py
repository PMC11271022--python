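"""Coordinate parsing, equal-area projection and grid indexing.

Everything downstream (convex hulls for extent of occurrence, 2 km
occupancy grids, 100 m rasters, 10 km scoping grids) works in a metric,
equal-area plane.  The plane is a Lambert azimuthal equal-area (LAEA)
projection of the authalic sphere, centered near the data; at the scale
of a Mediterranean island its planar areas agree with ellipsoidal areas
to well under 0.5%.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

__all__ = [
    "AUTHALIC_RADIUS_M",
    "ProjectionSpec",
    "GridSpec",
    "parse_coordinate",
    "project",
    "unproject",
    "haversine_km",
    "convex_hull",
    "polygon_area_km2",
    "cell_index",
]

#: Radius of the sphere with the same surface area as the WGS84 ellipsoid.
AUTHALIC_RADIUS_M = 6_371_007.180918475

# Degrees, minutes and optional (possibly fractional) seconds, with the
# hemisphere letter before or after the digits.  The printed records mix
# quote styles freely (', ’, ‘, ", ”, '') so any of them is accepted.
_DMS_RE = re.compile(
    r"""^\s*
    (?P<pre>[NSEW])?\s*
    (?P<deg>\d{1,3})\s*[°º]\s*
    (?P<min>\d{1,2}(?:\.\d+)?)\s*['’‘′]?\s*
    (?:(?P<sec>\d{1,2}(?:\.\d+)?)\s*(?:[\"”″]|['’‘′]{1,2})?\s*)?
    (?P<post>[NSEW])?\s*$""",
    re.VERBOSE,
)

_DECIMAL_RE = re.compile(
    r"""^\s*(?P<pre>[NSEW])?\s*(?P<sign>[+-])?
    (?P<val>\d{1,3}(?:\.\d+)?)\s*[°º]?\s*
    (?P<post>[NSEW])?\s*$""",
    re.VERBOSE,
)


class CoordinateParseError(ValueError):
    """Raised when a coordinate string cannot be interpreted."""


def parse_coordinate(text: str) -> float:
    """Parse a decimal or DMS coordinate string to signed decimal degrees.

    Accepts plain decimals (``"42.818467"``, ``"9.434145° E"``) and
    degrees-minutes(-seconds) strings with a hemisphere letter before or
    after the digits (``"41°51'04.4''N"``, ``"09°26'E"``).  Southern and
    western hemispheres are returned negative.

    Raises
    ------
    CoordinateParseError
        If the string matches neither form; the message names the
        offending text.
    """
    if not isinstance(text, str):
        raise CoordinateParseError(f"coordinate is not a string: {text!r}")
    m = _DMS_RE.match(text)
    if m:
        deg = float(m.group("deg"))
        minute = float(m.group("min"))
        sec = float(m.group("sec") or 0.0)
        if minute >= 60 or sec >= 60:
            raise CoordinateParseError(
                f"minutes/seconds out of range in {text!r}"
            )
        value = deg + minute / 60.0 + sec / 3600.0
        hemi = m.group("pre") or m.group("post")
        return _apply_hemisphere(value, hemi, text)
    m = _DECIMAL_RE.match(text)
    if m:
        value = float(m.group("val"))
        if m.group("sign") == "-":
            value = -value
        hemi = m.group("pre") or m.group("post")
        if hemi and m.group("sign"):
            raise CoordinateParseError(
                f"both sign and hemisphere letter in {text!r}"
            )
        return _apply_hemisphere(value, hemi, text)
    raise CoordinateParseError(f"unparseable coordinate: {text!r}")


def _apply_hemisphere(value: float, hemi: str | None, text: str) -> float:
    if hemi in ("S", "W"):
        value = -value
    limit = 180.0 if hemi in ("E", "W") else 90.0 if hemi in ("N", "S") else 180.0
    if abs(value) > limit:
        raise CoordinateParseError(f"coordinate out of range: {text!r}")
    return value


@dataclass(frozen=True)
class ProjectionSpec:
    """Equal-area projection of WGS84 lon/lat onto a metric plane.

    Parameters
    ----------
    center_lon, center_lat : float
        Projection center in decimal degrees; should sit near the data
        centroid so that the equal-area plane stays locally faithful.
    kind : str
        Projection family; only ``"laea"`` (Lambert azimuthal
        equal-area on the authalic sphere) is implemented.
    """

    center_lon: float
    center_lat: float
    kind: str = "laea"

    def __post_init__(self) -> None:
        if self.kind != "laea":
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if not (-180.0 <= self.center_lon <= 180.0):
            raise ValueError("center_lon outside [-180, 180]")
        if not (-90.0 <= self.center_lat <= 90.0):
            raise ValueError("center_lat outside [-90, 90]")

    @classmethod
    def for_points(cls, lons: Iterable[float], lats: Iterable[float]) -> "ProjectionSpec":
        """Projection centered on the arithmetic centroid of the points."""
        lons = np.asarray(list(lons), dtype=float)
        lats = np.asarray(list(lats), dtype=float)
        if lons.size == 0:
            raise ValueError("no points to center the projection on")
        return cls(center_lon=float(lons.mean()), center_lat=float(lats.mean()))


def project(lon, lat, spec: ProjectionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Forward LAEA projection: lon/lat degrees -> (x, y) meters.

    The projection center maps to (0, 0).  The point antipodal to the
    center is a singularity and is rejected.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam = np.radians(lon)
    phi = np.radians(lat)
    lam0 = math.radians(spec.center_lon)
    phi0 = math.radians(spec.center_lat)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    if np.any(cosc <= -1.0 + 1e-12):
        raise ValueError("point antipodal to the projection center")
    kprime = np.sqrt(2.0 / (1.0 + cosc))
    x = AUTHALIC_RADIUS_M * kprime * np.cos(phi) * np.sin(lam - lam0)
    y = AUTHALIC_RADIUS_M * kprime * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def unproject(x, y, spec: ProjectionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Inverse LAEA projection: (x, y) meters -> lon/lat degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0 = math.radians(spec.center_lon)
    phi0 = math.radians(spec.center_lat)
    rho = np.hypot(x, y)
    # rho = 0 is the projection center itself; guard the division.
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * AUTHALIC_RADIUS_M), -1.0, 1.0))
        phi = np.where(
            rho == 0.0,
            phi0,
            np.arcsin(
                np.cos(c) * math.sin(phi0)
                + np.where(rho == 0, 0.0, y * np.sin(c) * math.cos(phi0) / np.where(rho == 0, 1.0, rho))
            ),
        )
        lam = np.where(
            rho == 0.0,
            lam0,
            lam0
            + np.arctan2(
                x * np.sin(c),
                rho * math.cos(phi0) * np.cos(c) - y * math.sin(phi0) * np.sin(c),
            ),
        )
    return np.degrees(lam), np.degrees(phi)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance on the authalic sphere, kilometers."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * AUTHALIC_RADIUS_M / 1000.0 * np.arcsin(np.sqrt(a))


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of planar points as a counter-clockwise vertex ring.

    Parameters
    ----------
    points : (n, 2) array
        Projected coordinates in meters.

    Returns
    -------
    (m, 2) array
        Hull vertices in counter-clockwise order, not closed (the first
        vertex is not repeated).  Degenerate inputs (a single point or a
        collinear set) return the extreme points: the ring then has
        fewer than three vertices or zero area.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("convex hull of an empty point set")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type == "Point":
        return np.asarray(hull.coords, dtype=float)
    if hull.geom_type == "LineString":
        return np.asarray(hull.coords, dtype=float)
    hull = orient(hull, sign=1.0)  # counter-clockwise exterior
    return np.asarray(hull.exterior.coords[:-1], dtype=float)


def polygon_area_km2(ring: np.ndarray) -> float:
    """Shoelace area of a simple planar ring, in square kilometers.

    Rings with fewer than three distinct vertices are degenerate and
    return 0.  Vertex order (CW vs CCW) does not matter: the absolute
    area is returned.
    """
    ring = np.atleast_2d(np.asarray(ring, dtype=float))
    distinct = np.unique(ring, axis=0)
    if distinct.shape[0] < 3:
        return 0.0
    x, y = ring[:, 0], ring[:, 1]
    area_m2 = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area_m2 / 1e6)


@dataclass(frozen=True)
class GridSpec:
    """Half-open square grid over the projected plane.

    Cell (i, j) covers ``[origin_x + i*s, origin_x + (i+1)*s) x
    [origin_y + j*s, origin_y + (j+1)*s)``: a point exactly on a shared
    edge belongs to the higher-index cell, so the grid is an exact
    partition of the plane.  Standard cell sizes: 2,000 m for the
    occupancy (AOO) grid, 10,000 m for the KBA scoping grid, 100 m for
    land-cover rasters.
    """

    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size ** 2 / 1e6

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of cell (i, j)."""
        return (
            self.origin_x + i * self.cell_size,
            self.origin_y + j * self.cell_size,
            self.origin_x + (i + 1) * self.cell_size,
            self.origin_y + (j + 1) * self.cell_size,
        )

    def cell_polygon(self, i: int, j: int) -> Polygon:
        xmin, ymin, xmax, ymax = self.cell_bounds(i, j)
        return Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])


def cell_index(x, y, grid: GridSpec) -> np.ndarray:
    """Map projected points to integer (i, j) grid cells.

    Uses ``floor((coord - origin) / cell_size)`` per axis, so negative
    coordinates index negative cells and edge points go to the
    higher-index cell.

    Returns an (n, 2) integer array (or shape (2,) for scalars).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite coordinates cannot be gridded")
    i = np.floor((x - grid.origin_x) / grid.cell_size).astype(int)
    j = np.floor((y - grid.origin_y) / grid.cell_size).astype(int)
    return np.stack([i, j], axis=-1)
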