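"""End-to-end assessment driver.

Chains the whole analysis: occurrence parsing, equal-area projection,
range metrics (EOO / AOO / localities), habitat-model inference, Area of
Habitat mapping (EOO-clipped and island-wide), hypergeometric map
validation, criterion-B classification, KBA scoping and protected-area
overlap — and collects every stage's numbers, with provenance, into one
report object.  Deterministic given config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import Polygon

from . import __version__
from .aoh import AohMap, ValidationResult, build_aoh, infer_habitat_model, validate_aoh
from .geo import GridSpec, ProjectionSpec, project
from .io import read_geojson, read_occurrences, sha256_of, write_geojson
from .kba import KbaResult, KbaThresholds, pa_overlap, scope_kba, summarize_kba
from .range_metrics import (
    RangeSummary,
    RedListAssessment,
    classify_criterion_B,
    summarize_range,
)
from .raster import read_ascii_grid, write_ascii_grid
from .simulate import (
    IslandLandscape,
    SyntheticTruth,
    generate_island,
    generate_protected_area,
    sample_occurrences,
)

__all__ = ["AssessmentConfig", "AssessmentReport", "run_assessment", "write_report", "read_report"]

log = logging.getLogger("habrange")


@dataclass
class AssessmentConfig:
    """Everything one assessment run depends on.

    File-based inputs (occurrence CSV, land-cover and elevation ASCII
    grids, protected-area GeoJSON) and synthetic-landscape parameters
    are mutually exclusive per layer: when ``synthetic`` is true the
    rasters, the protected area and (if no occurrence file is given)
    the occurrence records are generated from ``seed``.
    """

    # file inputs
    occurrences_path: str | None = None
    landcover_path: str | None = None
    elevation_path: str | None = None
    protected_areas_path: str | None = None

    # synthetic landscape
    synthetic: bool = False
    seed: int = 0
    n_rows: int = 500
    n_cols: int = 500
    n_classes: int = 8
    sea_fraction: float = 0.4
    truth_classes: tuple[int, ...] = (3, 4)
    truth_elev_min: float = 100.0
    truth_elev_max: float = 1400.0
    p_in_habitat: float = 1.0
    n_records: int = 30
    n_outliers: int = 1
    pa_coverage: float = 0.4

    # analysis parameters
    linkage_km: float = 10.0
    alpha: float = 0.05
    a1_fraction: float = 0.005
    b1_fraction: float = 0.10
    aoo_grid_origin: tuple[float, float] = (0.0, 0.0)
    kba_grid_origin: tuple[float, float] = (0.0, 0.0)
    decline_observed: bool | None | str = "auto"
    severely_fragmented: bool | None = None
    elevation_buffer_m: float = 0.0
    historical_year_cutoff: int | None = 1950
    run_kba: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssessmentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "truth_classes" in raw:
            raw["truth_classes"] = tuple(raw["truth_classes"])
        for key in ("aoo_grid_origin", "kba_grid_origin"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth_classes"] = list(d["truth_classes"])
        d["aoo_grid_origin"] = list(d["aoo_grid_origin"])
        d["kba_grid_origin"] = list(d["kba_grid_origin"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class AssessmentReport:
    """All stage outputs of one assessment run."""

    range: RangeSummary
    redlist: RedListAssessment
    aoh_areas: dict[str, float] | None
    validation: ValidationResult | None
    kba: dict | None
    provenance: dict
    # heavyweight layers, kept for writing, not serialized to JSON
    eoo_hull_xy: np.ndarray | None = None
    aoh_eoo: AohMap | None = None
    aoh_island: AohMap | None = None
    kba_result: KbaResult | None = None
    landscape: IslandLandscape | None = None
    protected_area: object | None = None

    def to_dict(self) -> dict:
        rng = self.range
        return {
            "range": {
                "eoo_km2": rng.eoo_km2,
                "aoo_km2": rng.aoo_km2,
                "n_localities": rng.n_localities,
                "n_occupied_cells": len(rng.occupied_cells),
                "n_records": rng.n_records,
                "eoo_degenerate": rng.eoo_degenerate,
            },
            "redlist": {
                "category": self.redlist.category,
                "criteria_string": self.redlist.criteria_string,
                "triggered_thresholds": self.redlist.triggered_thresholds,
                "notes": self.redlist.notes,
            },
            "aoh_areas_km2": self.aoh_areas,
            "validation": None
            if self.validation is None
            else {
                "N": self.validation.N,
                "K": self.validation.K,
                "n": self.validation.n,
                "k": self.validation.k,
                "p_value": self.validation.p_value,
                "better_than_random": self.validation.better_than_random,
                "n_excluded": self.validation.n_excluded,
            },
            "kba": self.kba,
            "provenance": self.provenance,
        }


def _load_inputs(config: AssessmentConfig):
    landscape = None
    protected = None
    records = None
    hashes: dict[str, str] = {}

    if config.synthetic:
        landscape = generate_island(
            seed=config.seed,
            n_rows=config.n_rows,
            n_cols=config.n_cols,
            n_classes=config.n_classes,
            sea_fraction=config.sea_fraction,
        )
        truth = SyntheticTruth(
            suitable_classes=frozenset(config.truth_classes),
            elev_min=config.truth_elev_min,
            elev_max=config.truth_elev_max,
            p_in_habitat=config.p_in_habitat,
            seed=config.seed,
        )
        if config.occurrences_path is None:
            records = sample_occurrences(
                truth, landscape, n=config.n_records, n_outliers=config.n_outliers
            )
        if config.protected_areas_path is None and config.pa_coverage:
            protected = generate_protected_area(
                config.seed, landscape.coastline, config.pa_coverage
            )
    elif config.landcover_path and config.elevation_path:
        landcover = read_ascii_grid(config.landcover_path, "categorical")
        elevation = read_ascii_grid(config.elevation_path, "elevation")
        hashes["landcover"] = sha256_of(config.landcover_path)
        hashes["elevation"] = sha256_of(config.elevation_path)
        landscape = IslandLandscape(
            landcover=landcover,
            elevation=elevation,
            coastline=None,  # unknown for file rasters; island-wide domain is the land mask
            projection=ProjectionSpec(center_lon=9.0, center_lat=42.0),
        )

    if config.occurrences_path is not None:
        records = read_occurrences(config.occurrences_path)
        hashes["occurrences"] = sha256_of(config.occurrences_path)
    if config.protected_areas_path is not None:
        protected = read_geojson(config.protected_areas_path)
        hashes["protected_areas"] = sha256_of(config.protected_areas_path)
    if records is None:
        raise ValueError("no occurrence input: give occurrences_path or synthetic=true")
    return records, landscape, protected, hashes


def run_assessment(config: AssessmentConfig) -> AssessmentReport:
    """Execute the full assessment chain described by ``config``."""
    records, landscape, protected, hashes = _load_inputs(config)
    log.info("loaded %d occurrence records", len(records))

    if landscape is not None:
        projection = landscape.projection
    else:
        projection = ProjectionSpec.for_points(
            [r.lon for r in records], [r.lat for r in records]
        )

    ox, oy = config.aoo_grid_origin
    summary, eoo = summarize_range(
        records,
        projection=projection,
        linkage_km=config.linkage_km,
        aoo_grid=GridSpec(cell_size=2000.0, origin_x=ox, origin_y=oy),
    )
    log.info(
        "range: EOO %.1f km2, AOO %.1f km2, %d localities",
        summary.eoo_km2, summary.aoo_km2, summary.n_localities,
    )

    aoh_areas = None
    validation = None
    kba_block = None
    aoh_eoo = aoh_island = None
    kba_result = None
    decline = config.decline_observed

    if landscape is not None:
        # Current habitat is inferred from contemporary records only:
        # land cover at a century-old site reflects today's landscape,
        # not the habitat that held the species then.  Historical
        # records still count for range metrics and validation.
        cutoff = config.historical_year_cutoff
        model_records = [
            r for r in records
            if cutoff is None or r.year is None or r.year >= cutoff
        ] or records
        model = infer_habitat_model(
            model_records,
            landscape.landcover,
            landscape.elevation,
            projection,
            elevation_buffer_m=config.elevation_buffer_m,
        )
        log.info(
            "habitat model: classes %s, elevation %.0f-%.0f m",
            sorted(model.suitable_classes), model.elev_min, model.elev_max,
        )
        hull_poly = (
            Polygon(eoo.hull_xy) if eoo.hull_xy.shape[0] >= 3 else None
        )
        aoh_island = build_aoh(landscape.landcover, landscape.elevation, model)
        aoh_eoo = (
            build_aoh(landscape.landcover, landscape.elevation, model, boundary=hull_poly)
            if hull_poly is not None
            else aoh_island
        )
        aoh_areas = {
            "eoo_clipped": aoh_eoo.area_km2,
            "island_wide": aoh_island.area_km2,
        }
        validation = validate_aoh(aoh_eoo, records, projection, alpha=config.alpha)
        log.info(
            "validation: k=%d of n=%d occupied cells in habitat (p=%.3g)",
            validation.k, validation.n, validation.p_value,
        )
        if decline == "auto":
            # A historical record now outside mapped habitat signals a
            # loss of habitat extent over time (criterion B subcriterion b).
            decline = _historical_record_outside_habitat(records, aoh_island, projection)
            log.info("decline inferred from historical out-of-habitat records: %s", decline)
    elif decline == "auto":
        decline = None

    redlist = classify_criterion_B(
        summary,
        decline_observed=decline,
        severely_fragmented=config.severely_fragmented,
    )
    log.info("red list: %s %s", redlist.category, redlist.criteria_string)

    if landscape is not None and config.run_kba:
        kx, ky = config.kba_grid_origin
        thresholds = KbaThresholds(
            a1_fraction=config.a1_fraction, b1_fraction=config.b1_fraction
        )
        kba_result = scope_kba(
            aoh_eoo,
            grid=GridSpec(cell_size=10_000.0, origin_x=kx, origin_y=ky),
            thresholds=thresholds,
        )
        total, pct = summarize_kba(kba_result, aoh_eoo)
        kba_block = {
            "total_area_km2": total,
            "pct_of_aoh": pct,
            "n_cells_a1": len(kba_result.triggered_cells["A1"]),
            "n_cells_b1": len(kba_result.triggered_cells["B1"]),
            "pa_overlap_pct": None,
        }
        if protected is not None and total > 0:
            kba_block["pa_overlap_pct"] = pa_overlap(kba_result, aoh_eoo, protected)
        log.info("KBA: %.1f km2 (%.1f%% of AOH)", total, pct)

    provenance = {
        "tool": "habrange",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "decline_observed_resolved": decline,
        "config_sha256": config.digest(),
        "input_sha256": hashes,
        "projection": {
            "kind": projection.kind,
            "center_lon": projection.center_lon,
            "center_lat": projection.center_lat,
        },
    }
    return AssessmentReport(
        range=summary,
        redlist=redlist,
        aoh_areas=aoh_areas,
        validation=validation,
        kba=kba_block,
        provenance=provenance,
        eoo_hull_xy=eoo.hull_xy,
        aoh_eoo=aoh_eoo,
        aoh_island=aoh_island,
        kba_result=kba_result,
        landscape=landscape,
        protected_area=protected,
    )


def _historical_record_outside_habitat(records, aoh: AohMap, projection) -> bool:
    lons = np.array([r.lon for r in records], dtype=float)
    lats = np.array([r.lat for r in records], dtype=float)
    x, y = project(lons, lats, projection)
    header = aoh.header
    row, col = header.index_of(x, y)
    inside = header.contains(x, y)
    row = np.clip(row, 0, header.n_rows - 1)
    col = np.clip(col, 0, header.n_cols - 1)
    in_habitat = inside & aoh.mask[row, col]
    for rec, ok in zip(records, in_habitat):
        if not ok and rec.year is not None and rec.year < 1950:
            return True
    return False


def write_report(report: AssessmentReport, out_dir: str | Path, layers: bool = True) -> Path:
    """Write report.json, a plain-text summary and (optionally) the
    geospatial layers into ``out_dir``.  Returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    (out / "summary.txt").write_text(_summary_text(report))
    if layers:
        if report.eoo_hull_xy is not None and report.eoo_hull_xy.shape[0] >= 3:
            write_geojson(Polygon(report.eoo_hull_xy), out / "eoo_hull.geojson",
                          {"layer": "eoo-hull", "crs": "local equal-area plane (m)"})
        if report.landscape is not None:
            write_ascii_grid(report.landscape.landcover, out / "landcover.asc")
            write_ascii_grid(report.landscape.elevation, out / "elevation.asc")
        for name, aoh in (("aoh_eoo", report.aoh_eoo), ("aoh_island", report.aoh_island)):
            if aoh is not None:
                from .raster import CategoricalRaster

                write_ascii_grid(
                    CategoricalRaster(aoh.header, aoh.mask.astype(int)), out / f"{name}.asc"
                )
        if report.kba_result is not None and report.aoh_eoo is not None:
            from .raster import CategoricalRaster

            write_ascii_grid(
                CategoricalRaster(report.aoh_eoo.header, report.kba_result.kba_mask.astype(int)),
                out / "kba_mask.asc",
            )
        if report.protected_area is not None:
            write_geojson(report.protected_area, out / "protected_area.geojson",
                          {"layer": "protected-area"})
    return json_path


def read_report(path: str | Path) -> dict:
    """Read back a report.json written by :func:`write_report`."""
    return json.loads(Path(path).read_text())


def _summary_text(report: AssessmentReport) -> str:
    r = report.range
    lines = [
        "Range metrics",
        f"  EOO: {r.eoo_km2:,.1f} km2" + (" (degenerate hull)" if r.eoo_degenerate else ""),
        f"  AOO: {r.aoo_km2:,.1f} km2 ({len(r.occupied_cells)} occupied 2x2 km cells)",
        f"  Localities (single linkage): {r.n_localities}",
        "",
        f"Red List (criterion B): {report.redlist.category} {report.redlist.criteria_string}".rstrip(),
    ]
    for note in report.redlist.notes:
        lines.append(f"  note: {note}")
    if report.aoh_areas is not None:
        lines += [
            "",
            "Area of Habitat",
            f"  EOO-clipped: {report.aoh_areas['eoo_clipped']:,.1f} km2",
            f"  island-wide: {report.aoh_areas['island_wide']:,.1f} km2",
        ]
    if report.validation is not None:
        v = report.validation
        lines += [
            "",
            "Habitat-map validation (hypergeometric)",
            f"  {v.k} of {v.n} occupied cells in habitat "
            f"(domain {v.N} cells, {v.K} habitat); p = {v.p_value:.3g}; "
            f"better than random: {v.better_than_random}",
        ]
    if report.kba is not None:
        k = report.kba
        lines += [
            "",
            "Potential KBAs",
            f"  total area: {k['total_area_km2']:,.1f} km2 ({k['pct_of_aoh']:.1f}% of AOH)",
            f"  triggering cells: A1 {k['n_cells_a1']}, B1 {k['n_cells_b1']}",
        ]
        if k.get("pa_overlap_pct") is not None:
            lines.append(f"  protected-area overlap: {k['pa_overlap_pct']:.1f}%")
    return "\n".join(lines) + "\n"
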