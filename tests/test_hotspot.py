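from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressmap import (
    GridSpec,
    HotspotGrid,
    InsufficientCellsError,
    SpatialWeights,
    UndefinedChangeError,
    classify,
    classify_z,
    compare_campaigns,
    difference_map,
    gi_star,
    gi_star_z,
    rasterize,
)
from stressmap.utm import UtmCrs
from helpers import gi_star_oracle

CRS = UtmCrs(zone=33)


def grid_spec(nx=4, ny=4, cell=25.0):
    return GridSpec(crs=CRS, cell_size_m=cell, x0=353_000.0, y0=5_295_000.0,
                    nx=nx, ny=ny)


def manual_grid(n_meas, n_mos, min_support=10, spec=None):
    """Build a HotspotGrid from explicit count arrays (indexed [ix, iy])."""
    n_meas = np.asarray(n_meas, dtype=np.int64)
    spec = spec or grid_spec(*n_meas.shape)
    zeros = np.zeros_like(n_meas)
    return HotspotGrid(spec=spec, n_meas=n_meas, n_mos=np.asarray(n_mos, np.int64),
                       n_diary_neg=zeros.copy(), n_diary_pos=zeros.copy(),
                       min_support=min_support)


class TestRasterize:
    def test_rate_is_events_per_measurement(self):
        spec = grid_spec(1, 1)
        inside = lambda k: np.full((k, 2), [353_010.0, 5_295_010.0])
        grid = rasterize(spec, inside(100), inside(2))
        assert grid.rate("mos")[0, 0] == pytest.approx(0.02)

    def test_empty_input_all_zero(self):
        grid = rasterize(grid_spec(), None)
        assert grid.n_meas.sum() == 0 and grid.n_mos.sum() == 0

    def test_half_open_edge_goes_right_top(self):
        spec = grid_spec(2, 2)
        # exactly on the shared edge between columns 0 and 1
        pt = np.array([[spec.x0 + spec.cell_size_m, spec.y0 + 5.0]])
        grid = rasterize(spec, pt, min_support=1)
        assert grid.n_meas[1, 0] == 1 and grid.n_meas[0, 0] == 0

    def test_outside_point_counted_in_overflow(self):
        spec = grid_spec(2, 2)
        pts = np.array([[spec.x0 + 10, spec.y0 + 10], [spec.x0 - 100, spec.y0]])
        grid = rasterize(spec, pts)
        assert grid.n_meas.sum() == 1 and grid.overflow["meas"] == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 300))
    def test_count_conservation(self, seed, n_pts):
        rng = np.random.default_rng(seed)
        spec = grid_spec(5, 5)
        pts = np.column_stack([
            spec.x0 + rng.uniform(-50, 200, n_pts),
            spec.y0 + rng.uniform(-50, 200, n_pts),
        ])
        grid = rasterize(spec, pts, pts[: n_pts // 2])
        assert grid.n_meas.sum() + grid.overflow["meas"] == n_pts
        assert grid.n_mos.sum() + grid.overflow["mos"] == n_pts // 2

    def test_min_support_excludes_sparse_cells(self):
        grid = manual_grid([[100, 3]], [[2, 1]], min_support=10)
        assert grid.included.tolist() == [[True, False]]
        assert np.isnan(grid.rate("mos")[0, 1])


class TestGiStar:
    def test_uniform_field_all_zero(self):
        x = np.full(9, 0.7)
        w = SpatialWeights.distance_band(
            np.array([[i, j] for i in range(3) for j in range(3)], float), 1.0).w
        assert np.all(gi_star_z(x, w) == 0.0)

    def test_single_hot_cell_sign_pattern(self):
        """3x3 field, centre 9, rook+self neighbourhood: centre hot, corners cold."""
        coords = np.array([[i, j] for i in range(3) for j in range(3)], float)
        x = np.zeros(9)
        x[4] = 9.0
        w = SpatialWeights.distance_band(coords, 1.0).w  # rook + self
        z = gi_star_z(x, w)
        oracle = gi_star_oracle(list(x), w.tolist())
        np.testing.assert_allclose(z, oracle, atol=1e-9)
        assert z[4] > 0
        for corner in (0, 2, 6, 8):
            assert z[corner] < 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = np.array([[i, j] for i in range(8) for j in range(8)], float)
        x = rng.uniform(0, 1, 64)
        band = rng.uniform(1.0, 4.0)
        w = SpatialWeights.distance_band(coords, band).w
        z = gi_star_z(x, w)
        oracle = np.array(gi_star_oracle(list(x), w.tolist()))
        assert np.max(np.abs(z - oracle)) < 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 100, (12, 2))
        x = rng.uniform(0, 1, 12)
        w = SpatialWeights.distance_band(coords, 40.0).w
        z = gi_star_z(x, w)
        perm = rng.permutation(12)
        z_perm = gi_star_z(x[perm], w[np.ix_(perm, perm)])
        np.testing.assert_allclose(z_perm, z[perm], atol=1e-12)

    def test_insufficient_cells_rejected(self):
        with pytest.raises(InsufficientCellsError):
            gi_star_z(np.array([1.0]), np.array([[1.0]]))
        grid = manual_grid([[100, 3]], [[2, 1]])
        with pytest.raises(InsufficientCellsError):
            gi_star(grid)

    def test_grid_level_wrapper(self):
        rng = np.random.default_rng(7)
        n_meas = rng.integers(20, 100, (5, 5))
        n_mos = rng.binomial(n_meas, 0.05)
        grid = manual_grid(n_meas, n_mos)
        result = gi_star(grid)
        assert result.n == 25
        assert len(result.z) == 25
        # self-inclusive band of 2 cells: interior cells have 13 neighbours
        w = SpatialWeights.from_grid(grid).w
        assert w[12].sum() == 13


class TestClassification:
    @pytest.mark.parametrize("z,expected", [
        (3.0, "hot99"), (2.0, "hot95"), (1.7, "hot90"), (0.0, "neutral"),
        (-1.7, "cold90"), (-2.0, "cold95"), (-3.0, "cold99"),
        (1.645, "hot90"), (-2.576, "cold99"),
    ])
    def test_thresholds(self, z, expected):
        assert classify_z(z) == expected

    def test_geojson_layer_roundtrips(self):
        rng = np.random.default_rng(11)
        n_meas = rng.integers(20, 100, (4, 4))
        grid = manual_grid(n_meas, rng.binomial(n_meas, 0.05))
        layers = classify(gi_star(grid))
        fc = layers["geojson"]
        assert fc["type"] == "FeatureCollection"
        assert len(fc["features"]) == 16
        props = fc["features"][0]["properties"]
        assert {"ix", "iy", "z", "rate", "class"} <= set(props)
        ring = fc["features"][0]["geometry"]["coordinates"][0]
        assert len(ring) == 5 and ring[0] == ring[-1]
        assert len(layers["table"]) == 16


class TestDifferenceMap:
    def test_identical_grids_zero(self):
        n_meas = np.full((2, 2), 100)
        grid = manual_grid(n_meas, [[2, 4], [1, 3]])
        diff = difference_map(grid, grid, diary_value="mos")
        np.testing.assert_allclose(diff["difference"], 0.0, atol=1e-15)

    def test_two_cell_minmax_example(self):
        """Sensor rates {0.02, 0.04} vs diary {0.04, 0.02} -> {-1, +1}."""
        n_meas = np.array([[100, 100]])
        sensor = manual_grid(n_meas, [[2, 4]])
        diary = manual_grid(n_meas, [[4, 2]])
        diff = difference_map(sensor, diary, diary_value="mos")
        np.testing.assert_allclose(diff["difference"], [-1.0, 1.0])

    def test_sensor_only_cell_positive(self):
        spec = grid_spec(1, 2)
        n_meas = np.array([[100, 100]])
        sensor = manual_grid(n_meas, [[0, 5]], spec=spec)
        diary = manual_grid(np.array([[100, 3]]), [[0, 0]], spec=spec)
        diff = difference_map(sensor, diary, diary_value="diary_neg")
        d = dict(zip(diff["cells"], diff["difference"]))
        assert d[(0, 1)] > 0


class TestCompareCampaigns:
    def test_headline_20_percent(self):
        change = compare_campaigns({"overall": (100, 1.0)}, {"overall": (80, 1.0)})
        assert change.overall_pct == pytest.approx(-20.0)

    def test_per_zone_percentages(self):
        pre = {"city": (103, 1.0), "out_of_town": (58, 1.0)}
        post = {"city": (90, 1.0), "out_of_town": (43, 1.0)}
        change = compare_campaigns(pre, post)
        assert round(change.zones["city"], 1) == -12.6
        assert round(change.zones["out_of_town"], 1) == -25.9

    def test_exposure_rate_mode(self):
        # equal counts, doubled exposure -> rate halves
        change = compare_campaigns({"overall": (50, 100.0)},
                                   {"overall": (50, 200.0)},
                                   mode="exposure_rate")
        assert change.overall_pct == pytest.approx(-50.0)

    def test_zero_baseline_undefined(self):
        with pytest.raises(UndefinedChangeError):
            compare_campaigns({"overall": (0, 1.0)}, {"overall": (5, 1.0)})

    def test_grid_input_with_zones(self):
        from shapely.geometry import box

        spec = grid_spec(2, 1, cell=25.0)
        pre = manual_grid([[100], [100]], [[10], [10]], spec=spec)
        post = manual_grid([[100], [100]], [[8], [5]], spec=spec)
        zones = {
            "west": box(spec.x0, spec.y0, spec.x0 + 25, spec.y0 + 25),
            "east": box(spec.x0 + 25, spec.y0, spec.x0 + 50, spec.y0 + 25),
        }
        change = compare_campaigns(pre, post, zones=zones)
        assert change.zones["west"] == pytest.approx(-20.0)
        assert change.zones["east"] == pytest.approx(-50.0)
        assert change.overall_pct == pytest.approx(-35.0)


def test_plot_hotspots_smoke(tmp_path):
    from stressmap.viz import plot_hotspots

    rng = np.random.default_rng(13)
    n_meas = rng.integers(20, 100, (4, 4))
    grid = manual_grid(n_meas, rng.binomial(n_meas, 0.05))
    out = tmp_path / "hotspots.png"
    plot_hotspots(gi_star(grid), out)
    assert out.exists() and out.stat().st_size > 0
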