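"""EOO, AOO, locality counting and the criterion-B classifier."""

import itertools

import numpy as np
import pytest

import habrange as hr
from habrange.geo import GridSpec, ProjectionSpec, unproject
from habrange.range_metrics import (
    B1_EOO_THRESHOLDS,
    B2_AOO_THRESHOLDS,
    LOCATION_THRESHOLDS,
    OccurrenceRecord,
    RangeSummary,
    classify_criterion_B,
    compute_aoo,
    compute_eoo,
    count_localities,
    summarize_range,
)

SPEC = ProjectionSpec(center_lon=9.0, center_lat=42.0)


def _records_at_xy(xy):
    """Records whose projected positions are the given planar points."""
    out = []
    for i, (x, y) in enumerate(xy):
        lon, lat = unproject(x, y, SPEC)
        out.append(OccurrenceRecord(id=f"r{i}", lon=float(lon), lat=float(lat)))
    return out


class TestEoo:
    def test_right_triangle_300_km2(self):
        recs = _records_at_xy([(0, 0), (20_000, 0), (0, 30_000)])
        result = compute_eoo(recs, SPEC)
        assert result.eoo_km2 == pytest.approx(300.0, rel=1e-6)
        assert not result.degenerate

    def test_duplicated_point_is_degenerate(self):
        recs = _records_at_xy([(500, 500), (500, 500)])
        result = compute_eoo(recs, SPEC)
        assert result.degenerate and result.eoo_km2 == 0.0

    def test_collinear_records_are_degenerate(self):
        recs = _records_at_xy([(0, 0), (1000, 1000), (2000, 2000)])
        result = compute_eoo(recs, SPEC)
        assert result.degenerate and result.eoo_km2 == 0.0

    def test_no_records_is_an_error(self):
        with pytest.raises(ValueError):
            compute_eoo([])

    def test_adding_a_record_never_decreases_eoo(self, rng):
        xy = rng.uniform(-40_000, 40_000, size=(12, 2))
        recs = _records_at_xy(xy)
        areas = [compute_eoo(recs[: k + 1], SPEC).eoo_km2 for k in range(2, 12)]
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))


class TestAoo:
    def test_one_cell_four_km2(self):
        recs = _records_at_xy([(100, 100), (1900, 1900), (900, 1500)])
        cells, aoo = compute_aoo(recs, SPEC, GridSpec(cell_size=2000.0))
        assert (cells, aoo) == ({(0, 0)}, 4.0)

    def test_k_distinct_cells_give_4k(self):
        k = 9
        xy = [(i * 2000.0 + 37.0, i * 2000.0 + 11.0) for i in range(k)]
        cells, aoo = compute_aoo(_records_at_xy(xy), SPEC, GridSpec(cell_size=2000.0))
        assert len(cells) == k and aoo == 4.0 * k

    def test_bounds_and_monotonicity(self, rng):
        xy = rng.uniform(-30_000, 30_000, size=(15, 2))
        recs = _records_at_xy(xy)
        prev = 0.0
        for k in range(1, 16):
            _, aoo = compute_aoo(recs[:k], SPEC, GridSpec(cell_size=2000.0))
            assert 4.0 <= aoo <= 4.0 * k
            assert aoo >= prev
            prev = aoo


class TestLocalities:
    def test_single_record(self):
        assert count_localities(_records_at_xy([(0, 0)]), 10.0) == 1

    @pytest.mark.parametrize("factor,expected", [(1.01, 2), (0.99, 1)])
    def test_pairs_straddling_the_linkage_distance(self, factor, expected):
        d_m = 10_000.0 * factor
        recs = _records_at_xy([(0.0, 0.0), (0.0, d_m)])
        assert count_localities(recs, 10.0) == expected

    def test_chain_is_single_linkage(self):
        # A-B and B-C within linkage, A-C not: all one locality.
        recs = _records_at_xy([(0, 0), (0, 8000), (0, 16_000)])
        assert count_localities(recs, 10.0) == 1

    def test_non_increasing_in_linkage(self, rng):
        xy = rng.uniform(0, 60_000, size=(20, 2))
        recs = _records_at_xy(xy)
        counts = [count_localities(recs, km) for km in (1, 5, 10, 20, 50)]
        assert counts == sorted(counts, reverse=True)


class TestCorsicanRecords:
    """The seven printed collection sites of the Corsican endemic fly."""

    def test_locality_count_is_five(self, corsica_records):
        # Sisco+Chioso merge, the two Zonza seeps merge: 7 records, 5 sites
        assert count_localities(corsica_records, 10.0) == 5

    def test_aoo_is_24_km2(self, corsica_records):
        cells, aoo = compute_aoo(corsica_records)
        assert aoo == 24.0 and len(cells) == 6

    def test_eoo_near_published_extent(self, corsica_records):
        # 3,012 km2 published; tolerance +-300 km2 from the georeference
        # sensitivity of the 1907 type locality (see docs/methods.md)
        result = compute_eoo(corsica_records)
        assert result.eoo_km2 == pytest.approx(3012.0, abs=300.0)

    def test_summary_floors_eoo_at_aoo(self, corsica_records):
        summary, _ = summarize_range(corsica_records)
        assert summary.eoo_km2 >= summary.aoo_km2


def _summary(eoo, aoo, n_loc):
    occupied = {(i, 0) for i in range(int(aoo // 4))}
    return RangeSummary(
        eoo_km2=eoo, aoo_km2=4.0 * len(occupied), n_localities=n_loc,
        occupied_cells=occupied, n_records=max(n_loc, 1),
    )


def _oracle_category(eoo, aoo, n_loc, decline, fragmented):
    """Independent truth table: for each level, range condition plus both
    implemented subcriteria (a: fragmentation or location cap, b: decline)."""
    for cat in ("CR", "EN", "VU"):
        b1 = eoo <= B1_EOO_THRESHOLDS[cat]
        b2 = aoo <= B2_AOO_THRESHOLDS[cat]
        a = fragmented or n_loc <= LOCATION_THRESHOLDS[cat]
        if (b1 or b2) and a and decline:
            return cat
    return "LC"


class TestClassifier:
    def test_corsican_case_is_endangered_b1_b2ab(self):
        s = _summary(3012.0, 24.0, 5)
        out = classify_criterion_B(s, decline_observed=True)
        assert out.category == "EN"
        assert "B1" in out.criteria_string and "B2ab" in out.criteria_string

    def test_wide_eoo_triggers_b2_only(self):
        s = _summary(6000.0, 24.0, 5)
        out = classify_criterion_B(s, decline_observed=True)
        assert out.category == "EN"
        assert out.criteria_string == "B2ab"
        assert out.triggered_thresholds == {"B1": "VU", "B2": "EN"}

    def test_huge_range_gets_no_listing(self):
        s = _summary(1e6, 4e4, 100)
        out = classify_criterion_B(s, decline_observed=False)
        assert out.category == "LC" and out.criteria_string == ""

    def test_missing_flags_treated_as_unmet_and_noted(self):
        s = _summary(3012.0, 24.0, 5)
        out = classify_criterion_B(s)
        assert out.category == "LC"
        assert any("decline" in n for n in out.notes)

    def test_agrees_with_truth_table_oracle(self):
        eoo_bins = [50.0, 3000.0, 10_000.0, 50_000.0]
        aoo_bins = [8.0, 24.0, 1000.0, 5000.0]
        loc_bins = [1, 5, 10, 11]
        for eoo, aoo, n_loc, dec, frag in itertools.product(
            eoo_bins, aoo_bins, loc_bins, (True, False), (True, False)
        ):
            eoo = max(eoo, aoo)  # IUCN floor holds for real summaries
            got = classify_criterion_B(
                _summary(eoo, aoo, n_loc),
                decline_observed=dec,
                severely_fragmented=frag,
            )
            assert got.category == _oracle_category(eoo, aoo, n_loc, dec, frag), (
                eoo, aoo, n_loc, dec, frag
            )


def test_record_validation():
    with pytest.raises(ValueError):
        OccurrenceRecord(id="x", lon=200.0, lat=0.0)
    with pytest.raises(ValueError):
        OccurrenceRecord(id="x", lon=0.0, lat=0.0, year=3000)
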