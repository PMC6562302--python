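"""Geometry of MCP and a-LoCoH estimators against hand calculations and
brute-force re-implementations."""
import numpy as np
import pytest
from shapely.geometry import Polygon, box

import movescape as ms
from movescape.homerange import (
    count_components,
    dedup_homeranges,
    overlap_fraction,
    to_geojson,
    HomeRangeEstimate,
)
from _oracles import brute_force_max_distance, brute_force_mcp_points

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)


class TestMCP:
    def test_unit_square_with_center_has_exact_area(self):
        pts = np.vstack([UNIT_SQUARE, [0.5, 0.5]])
        est = ms.mcp(pts, 100.0)
        assert est.geometry.area == pytest.approx(1.0)
        assert est.area_km2 == pytest.approx(1e-6)  # 1 m^2 in km^2, exactly 1e-6
        assert est.level_achieved == 1.0

    def test_full_percent_is_hull_of_all_points(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, (50, 2))
        est = ms.mcp(pts, 100.0)
        from shapely.geometry import MultiPoint

        assert est.geometry.equals(MultiPoint(pts).convex_hull)

    def test_95_percent_peels_centroid_farthest_points(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1000, (100, 2))
        est = ms.mcp(pts, 95.0)
        keep = brute_force_mcp_points(pts, 95.0)
        assert keep.size == 95
        from shapely.geometry import MultiPoint

        assert est.geometry.equals(MultiPoint(pts[keep]).convex_hull)

    def test_area_monotone_in_percent(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 500, (200, 2))
        areas = [ms.mcp(pts, p).geometry.area for p in (50, 70, 90, 100)]
        assert np.all(np.diff(areas) >= 0)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        with pytest.raises(ValueError):
            ms.mcp(pts, 100.0)


class TestMaxPairwiseDistance:
    def test_unit_square_diagonal(self):
        assert ms.max_pairwise_distance(UNIT_SQUARE) == pytest.approx(np.sqrt(2))

    def test_collinear_points(self):
        pts = np.array([[0, 0], [3, 0], [7, 0]], float)
        assert ms.max_pairwise_distance(pts) == 7.0

    def test_matches_brute_force_on_1000_points(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1000, (1000, 2))
        assert ms.max_pairwise_distance(pts) == pytest.approx(
            brute_force_max_distance(pts), rel=1e-12
        )


class TestALoCoH:
    def test_equilateral_triangle_with_tight_a_is_degenerate(self):
        # side 1: each root's cumulative neighbor distance hits a=1 after one
        # neighbor, so every local hull is a segment and the union has no area
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        with pytest.raises(ValueError, match="degenerate"):
            ms.alocoh(pts, a=1.0, isopleth_targets=(1.0,))

    def test_full_isopleth_never_exceeds_full_mcp(self):
        xx, yy = np.meshgrid(np.arange(20.0), np.arange(20.0))
        pts = np.column_stack([xx.ravel() * 50, yy.ravel() * 50])
        a = ms.max_pairwise_distance(pts)
        est = ms.alocoh(pts, a=a, isopleth_targets=(1.0,))[1.0]
        assert est.geometry.area <= ms.mcp(pts, 100.0).geometry.area + 1e-9

    def test_duplicated_points_are_handled(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, (30, 2))
        pts = np.vstack([pts, pts[:5]])  # exact duplicates
        est = ms.alocoh(pts, a=50.0, isopleth_targets=(0.95,))[0.95]
        assert est.geometry.area > 0

    def test_achieved_fraction_nearest_target(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 300, (80, 2))
        ests = ms.alocoh(pts, isopleth_targets=(0.5, 0.95))
        for target, est in ests.items():
            assert abs(est.level_achieved - target) <= 0.5  # sane
            assert est.level_requested == target
            assert 0 < est.level_achieved <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_area_below_full_mcp_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 500, (60, 2))
        mcp_area = ms.mcp(pts, 100.0).geometry.area
        for est in ms.alocoh(pts, isopleth_targets=(0.5, 0.95)).values():
            assert est.geometry.area <= mcp_area + 1e-9


class TestComplexityIndex:
    def test_identical_areas_give_zero(self):
        assert ms.complexity_index(3.0, 3.0) == 0.0

    def test_half_area_gives_half(self):
        assert ms.complexity_index(2.0, 1.0) == 0.5

    def test_natural_fragment_scale_arithmetic(self):
        assert ms.complexity_index(4.05, 3.24) == pytest.approx(0.2)

    def test_larger_locoh_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert ms.complexity_index(1.0, 1.2) == 0.0

    def test_nonpositive_mcp_rejected(self):
        with pytest.raises(ValueError):
            ms.complexity_index(0.0, 1.0)


class TestComponents:
    def test_single_polygon(self):
        assert count_components(box(0, 0, 1, 1)) == 1

    def test_two_disjoint_squares(self):
        assert count_components([box(0, 0, 1, 1), box(5, 5, 6, 6)]) == 2

    def test_overlapping_squares_merge(self):
        assert count_components([box(0, 0, 2, 2), box(1, 1, 3, 3)]) == 1

    def test_touching_at_a_point_counts_connected(self):
        assert count_components([box(0, 0, 1, 1), box(1, 1, 2, 2)]) == 1


def _estimate(geom, animal_id="a", coverage=100.0, level=0.95):
    return HomeRangeEstimate(animal_id, "aLoCoH", level, level, geom, 100, coverage)


class TestOverlapAndDedup:
    def test_identical_polygons_full_overlap_drops_shorter(self):
        a = _estimate(box(0, 0, 10, 10), "long", coverage=200.0)
        b = _estimate(box(0, 0, 10, 10), "short", coverage=120.0)
        assert overlap_fraction(a, b) == 1.0
        kept = dedup_homeranges([a, b])
        assert [e.animal_id for e in kept] == ["long"]

    def test_disjoint_polygons_both_kept(self):
        a = _estimate(box(0, 0, 1, 1))
        b = _estimate(box(5, 0, 6, 1))
        assert overlap_fraction(a, b) == 0.0
        assert len(dedup_homeranges([a, b])) == 2

    def test_half_shifted_square_fraction_half(self):
        a = _estimate(box(0, 0, 1, 1))
        b = _estimate(box(0.5, 0, 1.5, 1))
        assert overlap_fraction(a, b) == pytest.approx(0.5)
        assert len(dedup_homeranges([a, b])) == 2

    def test_denominator_is_smaller_range(self):
        small = _estimate(box(0, 0, 1, 1))
        big = _estimate(box(0, 0, 10, 10))
        assert overlap_fraction(small, big) == 1.0

    def test_never_drops_both_members(self):
        ests = [
            _estimate(box(0, 0, 10, 10), "a", 100.0),
            _estimate(box(0, 0, 10, 10), "b", 150.0),
            _estimate(box(0.1, 0, 10.1, 10), "c", 120.0),
        ]
        kept = dedup_homeranges(ests)
        assert len(kept) >= 1
        assert "b" in {e.animal_id for e in kept}

    def test_mismatched_levels_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(_estimate(box(0, 0, 1, 1), level=0.5),
                             _estimate(box(0, 0, 1, 1), level=0.95))


class TestLandscapeClassification:
    @pytest.mark.parametrize(
        "level,expected",
        [(10.0, "natural_fragment"), (35.0, "suburban"), (60.0, "highly_urbanized"),
         (20.0, "suburban"), (50.0, "suburban")],
    )
    def test_uniform_raster_thresholds(self, level, expected):
        raster = ms.make_imperviousness_raster((0, 0, 900, 900), 30, "uniform", level)
        cls = ms.classify_landscape(box(100, 100, 800, 800), raster)
        assert cls.label == expected
        assert cls.mean_imperviousness == pytest.approx(level)

    def test_gradient_mean_is_average_over_cells_inside(self):
        raster = ms.make_imperviousness_raster((0, 0, 3000, 300), 30, "gradient", 100.0)
        cls = ms.classify_landscape(box(0, 0, 3000, 300), raster)
        assert cls.mean_imperviousness == pytest.approx(50.0)

    def test_polygon_outside_raster_rejected(self):
        raster = ms.make_imperviousness_raster((0, 0, 300, 300), 30, "uniform", 10.0)
        with pytest.raises(ValueError):
            ms.classify_landscape(box(1000, 1000, 1100, 1100), raster)


def test_geojson_export_roundtrip(tmp_path):
    import json

    ests = [_estimate(box(0, 0, 100, 100), "a"), _estimate(box(200, 0, 300, 100), "b")]
    fc = to_geojson(ests, tmp_path / "hr.geojson")
    back = json.loads((tmp_path / "hr.geojson").read_text())
    assert back == json.loads(json.dumps(fc))  # tuples vs lists aside
    assert back["features"][0]["properties"]["area_km2"] == pytest.approx(1e-2)
    geom = Polygon(back["features"][0]["geometry"]["coordinates"][0])
    assert geom.equals(ests[0].geometry)
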