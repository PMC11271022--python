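"""Habitat-model inference, AOH masking and hypergeometric validation."""

import itertools
import math

import numpy as np
import pytest
from shapely.geometry import Polygon

import habrange as hr
from habrange.aoh import build_aoh, infer_habitat_model, validate_aoh
from habrange.geo import ProjectionSpec, unproject
from habrange.range_metrics import OccurrenceRecord
from habrange.raster import CategoricalRaster, ElevationRaster, RasterHeader

SPEC = ProjectionSpec(center_lon=9.0, center_lat=42.0)


def _tiny_landscape():
    """4x4 raster: classes 1..4 by column, elevation 100*row, sea corner."""
    header = RasterHeader(n_rows=4, n_cols=4, origin_x=0, origin_y=0, cell_size=100.0)
    lc = np.tile(np.arange(1, 5), (4, 1))
    lc[0, 0] = header.nodata_code
    elev = np.repeat(np.arange(4, 0, -1)[:, None] * 100.0, 4, axis=1)
    elev[0, 0] = np.nan
    return CategoricalRaster(header, lc), ElevationRaster(header, elev)


def _record_at_cell(header, row, col, rec_id="r", year=2021, elevation=None):
    x = header.origin_x + (col + 0.5) * header.cell_size
    y = header.origin_y + (header.n_rows - 1 - row + 0.5) * header.cell_size
    lon, lat = unproject(x, y, SPEC)
    return OccurrenceRecord(
        id=rec_id, lon=float(lon), lat=float(lat), year=year, elevation_m=elevation
    )


class TestInferHabitatModel:
    def test_observed_codes_become_suitable_classes(self):
        lc, elev = _tiny_landscape()
        recs = [
            _record_at_cell(lc.header, 1, 2, "a"),  # class 3
            _record_at_cell(lc.header, 2, 0, "b"),  # class 1
        ]
        model = infer_habitat_model(recs, lc, elev, SPEC)
        assert model.suitable_classes == {1, 3}

    def test_elevation_band_from_records_with_raster_fallback(self):
        lc, elev = _tiny_landscape()
        recs = [
            _record_at_cell(lc.header, 1, 2, "a", elevation=250.0),
            _record_at_cell(lc.header, 3, 1, "b"),  # raster: 100 m
        ]
        model = infer_habitat_model(recs, lc, elev, SPEC)
        assert (model.elev_min, model.elev_max) == (100.0, 250.0)

    def test_all_records_off_raster_is_an_error(self):
        lc, elev = _tiny_landscape()
        far = OccurrenceRecord(id="far", lon=12.0, lat=45.0)
        with pytest.raises(ValueError, match="far"):
            infer_habitat_model([far], lc, elev, SPEC)

    def test_corsican_elevation_band(self, corsica_records):
        elevs = [r.elevation_m for r in corsica_records if r.elevation_m is not None]
        assert (min(elevs), max(elevs)) == (25.0, 1244.0)


class TestBuildAoh:
    def test_absent_class_gives_zero_area(self):
        lc, elev = _tiny_landscape()
        model = hr.HabitatModel(frozenset({99}), 0.0, 1000.0)
        assert build_aoh(lc, elev, model).area_km2 == 0.0

    def test_matches_brute_force_cell_scan(self, island, truth):
        model = hr.HabitatModel(truth.suitable_classes, truth.elev_min, truth.elev_max)
        aoh = build_aoh(island.landcover, island.elevation, model)
        # independent full scan over every cell
        count = 0
        lc, el = island.landcover.values, island.elevation.values
        for r in range(lc.shape[0]):
            for c in range(lc.shape[1]):
                if (
                    lc[r, c] in truth.suitable_classes
                    and math.isfinite(el[r, c])
                    and truth.elev_min <= el[r, c] <= truth.elev_max
                ):
                    count += 1
        assert int(aoh.mask.sum()) == count
        assert aoh.area_km2 == pytest.approx(count * island.landcover.header.cell_area_km2)

    def test_header_mismatch_rejected(self):
        lc, _ = _tiny_landscape()
        other = RasterHeader(n_rows=4, n_cols=4, origin_x=50.0, cell_size=100.0)
        elev2 = ElevationRaster(other, np.full((4, 4), 100.0))
        with pytest.raises(ValueError, match="header"):
            build_aoh(lc, elev2, hr.HabitatModel(frozenset({1}), 0, 500))

    def test_boundary_clipping_nests_inside_island_wide(self, island, truth):
        model = hr.HabitatModel(truth.suitable_classes, truth.elev_min, truth.elev_max)
        full = build_aoh(island.landcover, island.elevation, model)
        h = island.landcover.header
        half = Polygon(
            [
                (h.origin_x, h.origin_y),
                (h.origin_x + h.n_cols * h.cell_size, h.origin_y),
                (h.origin_x + h.n_cols * h.cell_size, h.origin_y + h.n_rows * h.cell_size / 2),
                (h.origin_x, h.origin_y + h.n_rows * h.cell_size / 2),
            ]
        )
        clipped = build_aoh(island.landcover, island.elevation, model, boundary=half)
        assert clipped.domain == "eoo-clipped"
        assert not np.any(clipped.mask & ~full.mask)
        assert clipped.area_km2 <= full.area_km2


def _enumeration_p_value(N, K, n, k) -> float:
    """P[X >= k] by full enumeration of all C(N, n) unordered samples."""
    cells = list(range(N))
    habitat = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(cells, n):
        total += 1
        if sum(1 for c in draw if c in habitat) >= k:
            hits += 1
    return hits / total


class TestValidateAoh:
    def _aoh_line(self, N, K):
        """1-row raster with N domain cells, first K habitat."""
        header = RasterHeader(n_rows=1, n_cols=N, cell_size=100.0)
        mask = np.zeros((1, N), bool)
        mask[0, :K] = True
        return hr.AohMap(header=header, mask=mask, domain_mask=np.ones((1, N), bool))

    def test_worked_case_10_45(self):
        aoh = self._aoh_line(10, 5)
        recs = [_record_at_cell(aoh.header, 0, c, f"r{c}") for c in (0, 1)]
        v = validate_aoh(aoh, recs, SPEC)
        assert v.p_value == pytest.approx(10 / 45)
        assert (v.N, v.K, v.n, v.k) == (10, 5, 2, 2)

    def test_all_habitat_gives_p_one(self):
        aoh = self._aoh_line(8, 8)
        recs = [_record_at_cell(aoh.header, 0, c) for c in (1, 3)]
        assert validate_aoh(aoh, recs, SPEC).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "N,K,n",
        [(6, 3, 2), (8, 5, 3), (10, 4, 4), (12, 7, 5), (12, 2, 3), (9, 9, 2)],
    )
    def test_matches_full_enumeration(self, N, K, n):
        aoh = self._aoh_line(N, K)
        # k is bounded below by n - (N - K): only N-K non-habitat cells exist
        for k in range(max(0, n - (N - K)), min(n, K) + 1):
            recs = [
                _record_at_cell(aoh.header, 0, c, f"h{c}") for c in range(k)
            ] + [
                _record_at_cell(aoh.header, 0, K + c, f"o{c}") for c in range(n - k)
            ]
            v = validate_aoh(aoh, recs, SPEC)
            assert (v.n, v.k) == (n, k)
            assert v.p_value == pytest.approx(_enumeration_p_value(N, K, n, k), abs=1e-12)

    def test_p_value_non_increasing_in_k(self):
        N, K, n = 40, 15, 8
        aoh = self._aoh_line(N, K)
        ps = []
        for k in range(n + 1):
            recs = [_record_at_cell(aoh.header, 0, c, f"h{c}") for c in range(k)] + [
                _record_at_cell(aoh.header, 0, K + c, f"o{c}") for c in range(n - k)
            ]
            ps.append(validate_aoh(aoh, recs, SPEC).p_value)
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_duplicate_records_in_one_cell_count_once(self):
        aoh = self._aoh_line(10, 5)
        recs = [_record_at_cell(aoh.header, 0, 2, f"r{i}") for i in range(4)]
        v = validate_aoh(aoh, recs, SPEC)
        assert (v.n, v.k) == (1, 1)

    def test_off_domain_records_excluded_with_count(self):
        aoh = self._aoh_line(10, 5)
        recs = [
            _record_at_cell(aoh.header, 0, 1),
            OccurrenceRecord(id="far", lon=12.0, lat=45.0),
        ]
        v = validate_aoh(aoh, recs, SPEC)
        assert v.n == 1 and v.n_excluded == 1

    def test_one_outlier_gives_k_n_minus_one(self, island, truth):
        """Mirrors a historical record from since-converted habitat."""
        recs = hr.sample_occurrences(truth, island, n=30, n_outliers=1)
        model = hr.HabitatModel(truth.suitable_classes, truth.elev_min, truth.elev_max)
        aoh = build_aoh(island.landcover, island.elevation, model)
        v = validate_aoh(aoh, recs, island.projection)
        # contemporary records sample habitat cells without replacement
        # dedup; the single outlier cell is the one non-habitat cell
        assert v.k == v.n - 1
        assert v.better_than_random
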