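import numpy as np
import pandas as pd
import pytest
import shapely.geometry as sgeom

from heatscape import (
    RasterGrid,
    SceneSpec,
    ZoneLayer,
    make_lake_scene,
    polygon_to_raster,
    run_raster_pipeline,
    run_vector_pipeline,
    simulate_scene,
    single_cell_zones,
    zonal_mean,
)


def _layer(zones_geoms, attrs=None):
    ids = [zid for zid, _ in zones_geoms]
    table = attrs if attrs is not None else pd.DataFrame(
        index=pd.Index(ids, name="zone_id")
    )
    return ZoneLayer(zones_geoms, table)


class TestPolygonToRaster:
    def test_single_polygon_constant_fill(self):
        template = RasterGrid(np.zeros((3, 3)), 10.0, (0.0, 30.0))
        layer = _layer(
            [("a", sgeom.box(0, 0, 30, 30))],
            pd.DataFrame({"v": [7.0]}, index=pd.Index(["a"], name="zone_id")),
        )
        out, diag = polygon_to_raster(layer, "v", template)
        np.testing.assert_allclose(out.values, 7.0)
        assert diag["n_unassigned"] == 0

    def test_left_right_split_assigns_by_center(self):
        # 4x4 template split into two rectangles: all 16 centers checked
        # by hand against the half-open cell convention
        template = RasterGrid(np.zeros((4, 4)), 10.0, (0.0, 40.0))
        layer = _layer(
            [("L", sgeom.box(0, 0, 20, 40)), ("R", sgeom.box(20, 0, 40, 40))],
            pd.DataFrame({"v": [1.0, 2.0]}, index=pd.Index(["L", "R"], name="zone_id")),
        )
        out, _ = polygon_to_raster(layer, "v", template)
        assert (out.values == 1.0).sum() == 8
        assert (out.values == 2.0).sum() == 8
        np.testing.assert_allclose(out.values[:, :2], 1.0)

    def test_hole_center_becomes_nodata(self):
        template = RasterGrid(np.zeros((3, 3)), 10.0, (0.0, 30.0))
        ring = sgeom.Polygon(
            [(0, 0), (30, 0), (30, 30), (0, 30)],
            holes=[[(12, 12), (18, 12), (18, 18), (12, 18)]],
        )
        layer = _layer(
            [("a", ring)],
            pd.DataFrame({"v": [3.0]}, index=pd.Index(["a"], name="zone_id")),
        )
        out, diag = polygon_to_raster(layer, "v", template)
        assert out.nodata_mask[1, 1]
        assert diag["n_unassigned"] == 1

    def test_boundary_tie_deterministic_and_counted(self):
        # zone boundary passes exactly through the middle column of centers
        template = RasterGrid(np.zeros((2, 3)), 10.0, (0.0, 20.0))
        layer = _layer(
            [("b", sgeom.box(0, 0, 15, 20)), ("a", sgeom.box(15, 0, 30, 20))],
            pd.DataFrame({"v": [1.0, 2.0]}, index=pd.Index(["b", "a"], name="zone_id")),
        )
        out, diag = polygon_to_raster(layer, "v", template)
        assert diag["boundary_ties"] == 2
        # id 'a' sorts before 'b' so ties go to zone 'a'
        np.testing.assert_allclose(out.values[:, 1], 2.0)


class TestZonalMean:
    def test_constant_raster(self):
        raster = RasterGrid(np.full((4, 4), 3.25), 10.0, (0.0, 40.0))
        layer = _layer([("a", sgeom.box(0, 0, 40, 40))])
        means, _ = zonal_mean(raster, layer)
        assert means["a"] == pytest.approx(3.25)

    def test_mean_of_all_cells(self):
        raster = RasterGrid(np.array([[1.0, 2.0], [3.0, 4.0]]), 10.0, (0.0, 20.0))
        layer = _layer([("a", sgeom.box(0, 0, 20, 20))])
        means, _ = zonal_mean(raster, layer)
        assert means["a"] == pytest.approx(2.5)

    def test_tiny_zone_without_center_warns(self):
        raster = RasterGrid(np.ones((2, 2)), 10.0, (0.0, 20.0))
        layer = _layer(
            [("big", sgeom.box(0, 0, 20, 18)), ("sliver", sgeom.box(0, 18, 20, 20))]
        )
        with pytest.warns(UserWarning, match="sliver"):
            means, diag = zonal_mean(raster, layer)
        assert np.isnan(means["sliver"])
        assert diag["empty_zones"] == ["sliver"]

    def test_nodata_outside_polygon_irrelevant(self):
        vals = np.array([[1.0, 99.0], [3.0, 99.0]])
        mask = np.array([[False, True], [False, True]])
        raster = RasterGrid(vals, 10.0, (0.0, 20.0), mask)
        layer = _layer([("a", sgeom.box(0, 0, 10, 20))])
        means, _ = zonal_mean(raster, layer)
        assert means["a"] == pytest.approx(2.0)

    def test_conservation_roundtrip(self, rng):
        """zonal_mean(polygon_to_raster(col)) returns col exactly."""
        template = RasterGrid(np.zeros((10, 10)), 10.0, (0.0, 100.0))
        widths = np.array([30, 20, 50])
        x0 = 0.0
        zones = []
        for i, w in enumerate(widths):
            zones.append((f"z{i}", sgeom.box(x0, 0, x0 + w, 100)))
            x0 += w
        col = pd.DataFrame(
            {"v": rng.random(3) * 100},
            index=pd.Index([f"z{i}" for i in range(3)], name="zone_id"),
        )
        layer = _layer(zones, col)
        grid, _ = polygon_to_raster(layer, "v", template)
        back, _ = zonal_mean(grid, layer)
        np.testing.assert_array_equal(back.to_numpy(), col["v"].to_numpy())


class TestPipelines:
    def test_single_cell_zones_make_frames_coincide(self):
        scene = simulate_scene(SceneSpec(shape=(7, 7), n_zones=1, seed=5))
        zones = single_cell_zones(scene["true_T"])
        from heatscape.synthetic_scenes import simulate_vulnerability

        table = simulate_vulnerability(scene["spec"], zones, scene["true_T"])
        res_r = run_raster_pipeline(scene["thermal"], zones, table)
        res_v = run_vector_pipeline(scene["thermal"], zones, table)
        raster_by_zone, _ = zonal_mean(
            res_r.risk.carrier.like(res_r.risk.carrier.values.astype(float)), zones
        )
        np.testing.assert_array_equal(
            raster_by_zone.to_numpy(), pd.Series(res_v.risk.carrier).to_numpy()
        )

    def test_constant_scene_single_class(self):
        spec = SceneSpec(
            shape=(6, 6), n_zones=4, noise_sd_K=0.0, heat_islands=(),
            temp_coupling=0.0, shared_factor_sd=0.0, seed=2,
            mean_density={k: 0.0 for k in
                          ["seniors", "infants", "old_housing_households",
                           "high_risk_homes", "low_income", "low_education",
                           "living_alone"]},
        )
        scene = simulate_scene(spec)
        table = scene["table"].copy()
        table["unemployment_rate"] = 5.0  # all-equal vulnerability
        with pytest.warns(UserWarning):
            res = run_raster_pipeline(scene["thermal"], scene["zones"], table)
        vals = res.risk.carrier.valid_values()
        assert np.unique(vals).size == 1

    def test_lake_scene_vector_washes_out_hot_cells(self):
        scene = make_lake_scene()
        res_r = run_raster_pipeline(scene["thermal"], scene["zones"], scene["table"])
        res_v = run_vector_pipeline(scene["thermal"], scene["zones"], scene["table"])
        lake_zone = scene["lake_zone"]
        vec_class = int(res_v.exposure_idx.carrier[lake_zone])
        # raster exposure classes of the cells inside that zone
        from heatscape.spatial_join import assign_cells_to_zones

        assignment, _ = assign_cells_to_zones(res_r.lst, scene["zones"])
        zpos = scene["zones"].zone_ids.index(lake_zone)
        cell_classes = res_r.exposure_idx.carrier.values[assignment == zpos]
        assert vec_class < cell_classes.max()
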