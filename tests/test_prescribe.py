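"""Grid construction, point counting, density classification (fixed tiers
and exact Fisher-Jenks vs. an exhaustive-search oracle), the tier→rate
rule, and export round trips."""

from itertools import combinations

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon, box

from fieldseg.prescribe import (
    FIXED_TIER_BOUNDS,
    GridCell,
    RateRule,
    assign_rate,
    classify_cells,
    classify_fixed,
    classify_jenks,
    count_points,
    export_map,
    jenks_breaks,
    make_grid,
    read_map_geojson,
)


class TestGrid:
    def test_120m_square_gives_100_cells(self):
        cells = make_grid(box(0, 0, 120, 120), 12)
        assert len(cells) == 100
        assert not any(c.partial for c in cells)

    def test_interior_cells_exactly_144_m2_and_cover_field(self):
        field = box(3, 3, 70, 52)
        cells = make_grid(field, 12)
        area = sum(c.polygon.area for c in cells)
        assert area >= field.area
        for c in cells:
            assert c.polygon.area == pytest.approx(144.0)

    def test_indexing_matches_brute_force_enumeration(self):
        field = box(-5, 7, 40, 44)
        cells = make_grid(field, 12)
        expected = set()
        for r in range(20):
            for c in range(20):
                x0 = (int(np.floor(-5 / 12)) + c) * 12
                y0 = (int(np.floor(7 / 12)) + r) * 12
                if box(x0, y0, x0 + 12, y0 + 12).intersects(field):
                    expected.add((r, c))
        assert {(c.row, c.col) for c in cells} == expected

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            make_grid(Polygon(), 12)


class TestCounting:
    def test_conservation(self, rng):
        cells = make_grid(box(0, 0, 96, 96), 12)
        pts = rng.uniform(0, 96, (1000, 2))
        outside = count_points(cells, pts)
        assert outside == 0
        assert sum(c.weed_count for c in cells) == 1000

    def test_shared_edge_assigned_to_exactly_one_cell(self):
        cells = make_grid(box(0, 0, 48, 48), 12)
        count_points(cells, np.array([[24.0, 24.0], [12.0, 0.0], [0.0, 36.0]]))
        assert sum(c.weed_count for c in cells) == 3

    def test_matches_point_in_polygon_oracle(self, rng):
        cells = make_grid(box(0, 0, 60, 60), 12)
        pts = rng.uniform(0, 60, (1000, 2))
        count_points(cells, pts)
        # oracle: each point must land in a cell whose closed polygon covers
        # it; strictly-interior points determine the cell uniquely
        lookup = {(c.row, c.col): c for c in cells}
        oracle = dict.fromkeys(lookup, 0)
        for x, y in pts:
            covering = [(c.row, c.col) for c in cells
                        if shapely.covers(c.polygon, shapely.Point(x, y))]
            assert covering
            if len(covering) == 1:
                oracle[covering[0]] += 1
        for key, c in lookup.items():
            assert c.weed_count >= oracle[key]
        assert sum(c.weed_count for c in cells) == 1000

    def test_outside_points_reported(self):
        cells = make_grid(box(0, 0, 24, 24), 12)
        outside = count_points(cells, np.array([[100.0, 100.0], [5.0, 5.0]]))
        assert outside == 1


class TestClassification:
    @pytest.mark.parametrize("count,tier", [
        (0, 0), (1, 1), (24, 1), (25, 2), (48, 2), (49, 3),
        (72, 3), (73, 4), (96, 4), (97, 5), (1000, 5),
    ])
    def test_fixed_tier_boundaries(self, count, tier):
        assert classify_fixed(count) == tier

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_fixed(-1)

    @given(st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_monotone_step_function(self, n):
        assert classify_fixed(n + 1) >= classify_fixed(n)

    def test_tier_five_lower_boundary_is_97(self):
        assert FIXED_TIER_BOUNDS[-1] == 97
        assert classify_fixed(96) == 4 and classify_fixed(97) == 5


class TestJenks:
    @staticmethod
    def _sse_of_breaks(vals, breaks):
        classes = {}
        for v in vals:
            t = sum(v >= b for b in breaks)
            classes.setdefault(t, []).append(v)
        return sum(((np.array(c) - np.mean(c)) ** 2).sum() for c in classes.values())

    @staticmethod
    def _brute_cost(vals, k):
        v = sorted(vals)
        n = len(v)
        best = np.inf
        for cuts in combinations(range(1, n), k - 1):
            idx = [0, *cuts, n]
            tot = sum(
                ((np.array(v[a:b]) - np.mean(v[a:b])) ** 2).sum()
                for a, b in zip(idx[:-1], idx[1:])
            )
            best = min(best, tot)
        return best

    def test_k_equals_n_zero_deviance(self):
        vals = [4.0, 9.0, 1.0, 7.0]
        breaks = jenks_breaks(vals, 4)
        assert self._sse_of_breaks(vals, breaks) == 0.0

    def test_separated_clusters(self):
        assert jenks_breaks([1, 2, 3, 100, 101, 102], 2) == [100.0]

    def test_equals_exhaustive_search(self):
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 13))
            k = int(r.integers(2, min(4, n) + 1))
            vals = r.integers(0, 60, n).astype(float).tolist()
            got = self._sse_of_breaks(vals, jenks_breaks(vals, k))
            assert got == pytest.approx(self._brute_cost(vals, k), abs=1e-9)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 2.0], 3)

    def test_deterministic(self):
        vals = [3.0, 3.0, 7.0, 7.0, 20.0, 21.0]
        assert jenks_breaks(vals, 3) == jenks_breaks(vals, 3)

    def test_classify_jenks_tiers_monotone_in_count(self):
        counts = [0, 2, 5, 30, 31, 60, 90, 120, 150]
        tiers = classify_jenks(counts, 5)
        nonzero = [(c, t) for c, t in zip(counts, tiers) if c > 0]
        for (c1, t1), (c2, t2) in zip(nonzero, nonzero[1:]):
            assert t2 >= t1


class TestRates:
    def test_paper_rate_ladder(self):
        rule = RateRule()
        assert [assign_rate(t, rule) for t in (5, 4, 3, 2, 1)] == [120, 114, 108, 102, 96]

    def test_no_spray_tier(self):
        assert assign_rate(0) == 0.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            assign_rate(6)
        with pytest.raises(ValueError):
            assign_rate(-1)

    def test_rate_monotone_in_tier(self):
        rates = [assign_rate(t) for t in range(6)]
        assert rates == sorted(rates)


class TestExport:
    def _cells(self, rng):
        cells = make_grid(box(0, 0, 48, 36), 12)
        count_points(cells, rng.uniform(0, 48, (400, 2)) * [1, 0.75])
        classify_cells(cells, "fixed")
        return cells

    def test_geojson_round_trip_exact(self, tmp_path, rng):
        cells = self._cells(rng)
        p = export_map(cells, tmp_path / "m.geojson", "geojson")
        props = read_map_geojson(p)
        assert [q["weed_count"] for q in props] == [c.weed_count for c in cells]
        assert [q["tier"] for q in props] == [c.tier for c in cells]
        assert [q["rate_l_per_hm2"] for q in props] == [c.rate for c in cells]

    def test_raster_matches_vector_rates(self, tmp_path, rng):
        cells = self._cells(rng)
        p = export_map(cells, tmp_path / "m.asc", "asc")
        lines = p.read_text().splitlines()
        hdr = dict(l.split() for l in lines[:6])
        grid = np.loadtxt(lines[6:])
        grid = np.atleast_2d(grid)
        rows = int(hdr["nrows"])
        for c in cells:
            assert grid[rows - 1 - c.row, c.col] == pytest.approx(c.rate)

    def test_geotiff_written_with_georeferencing_tags(self, tmp_path, rng):
        import tifffile

        cells = self._cells(rng)
        p = export_map(cells, tmp_path / "m.tif", "geotiff")
        with tifffile.TiffFile(p) as tf:
            page = tf.pages[0]
            assert 33550 in page.tags and 33922 in page.tags
            data = page.asarray()
        for c in cells:
            assert data[data.shape[0] - 1 - c.row, c.col] == pytest.approx(c.rate)

    def test_empty_field_valid_file_with_zero_features(self, tmp_path):
        p = export_map([], tmp_path / "empty.geojson", "geojson")
        import json

        doc = json.loads(p.read_text())
        assert doc["features"] == []

    def test_unsupported_format_raises(self, tmp_path, rng):
        with pytest.raises(ValueError):
            export_map(self._cells(rng), tmp_path / "m.xyz", "shapefile")

    def test_classify_cells_consistency_invariant(self, rng):
        cells = self._cells(rng)
        rule = RateRule()
        for c in cells:
            assert c.tier == classify_fixed(c.weed_count)
            assert c.rate == rule.rate(c.tier)
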