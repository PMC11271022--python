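"""Reading occurrence tables and writing assessment outputs.

Occurrences come as delimited text with a header row; coordinates may
mix decimal degrees and DMS strings, exactly as printed in collection
labels.  Vector layers go out as GeoJSON, rasters as Esri ASCII grids,
and the assessment report as JSON plus a human-readable summary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .geo import CoordinateParseError, parse_coordinate
from .range_metrics import OccurrenceRecord

__all__ = [
    "read_occurrences",
    "records_to_dataframe",
    "write_geojson",
    "read_geojson",
    "sha256_of",
]

_REQUIRED = ("id", "lat", "lon")
_OPTIONAL = ("year", "elevation_m", "note")


def _parse_coord_cell(value) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    return parse_coordinate(str(value))


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read an occurrence table (CSV with columns id, lat, lon[, year,
    elevation_m, note]); lat/lon cells may be decimal or DMS strings.

    Raises ``ValueError`` naming any missing required column, and a
    parse error carrying the offending row number for bad coordinates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty occurrence file") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no occurrence rows")
    records: list[OccurrenceRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()
        try:
            lat = _parse_coord_cell(row["lat"])
            lon = _parse_coord_cell(row["lon"])
        except CoordinateParseError as exc:
            raise CoordinateParseError(f"{path}, row {pos}: {exc}") from None
        year = row.get("year", "")
        elev = row.get("elevation_m", "")
        records.append(
            OccurrenceRecord(
                id=str(row["id"]),
                lon=lon,
                lat=lat,
                year=int(float(year)) if year not in ("", None) else None,
                elevation_m=float(elev) if elev not in ("", None) else None,
                georeference_note=str(row.get("note", "")),
            )
        )
    return records


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
            "year": [r.year for r in records],
            "elevation_m": [r.elevation_m for r in records],
            "note": [r.georeference_note for r in records],
        }
    )


def write_geojson(geometry, path: str | Path, properties: dict | None = None) -> None:
    """Write a shapely geometry as a single-feature GeoJSON file."""
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": mapping(geometry),
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(doc))


def read_geojson(path: str | Path):
    """Read the geometries of a GeoJSON file; returns a shapely geometry
    (union of all features)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shape(doc["geometry"])]
    else:
        geoms = [shape(doc)]
    return geoms[0] if len(geoms) == 1 else shapely.union_all(geoms)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
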