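import json

import numpy as np
import pandas as pd
import pytest
import shapely.geometry as sgeom

from heatscape import (
    GeoValidationError,
    RasterGrid,
    ZoneLayer,
    read_raster,
    read_zones,
    write_raster,
    write_zones,
)


class TestRasterRoundTrip:
    def test_values_metadata_bitexact(self, tmp_path):
        g = RasterGrid(np.arange(1.0, 10.0).reshape(3, 3), 60.0, (120.5, 980.25))
        path = tmp_path / "g.tif"
        write_raster(g, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.cell_size == g.cell_size
        assert back.origin == g.origin
        assert not back.nodata_mask.any()

    def test_mask_preserved(self, tmp_path):
        g = RasterGrid(np.arange(9.0).reshape(3, 3), 30.0)
        g.nodata_mask[0, 1] = True
        g.nodata_mask[2, 2] = True
        path = tmp_path / "m.tif"
        write_raster(g, path)
        back = read_raster(path)
        np.testing.assert_array_equal(back.nodata_mask, g.nodata_mask)
        np.testing.assert_array_equal(
            back.values[~back.nodata_mask], g.values[~g.nodata_mask]
        )

    def test_integer_dtype_roundtrip(self, tmp_path):
        g = RasterGrid(np.arange(9, dtype=np.int16).reshape(3, 3), 10.0)
        write_raster(g, tmp_path / "i.tif")
        back = read_raster(tmp_path / "i.tif")
        assert back.values.dtype == np.int16
        np.testing.assert_array_equal(back.values, g.values)

    def test_rectangular_cells_rejected(self, tmp_path):
        import tifffile

        meta = {"heatscape_meta": {"cell_size": [30.0, 60.0], "origin": [0, 0]}}
        tifffile.imwrite(
            tmp_path / "rect.tif", np.zeros((2, 2)), description=json.dumps(meta)
        )
        with pytest.raises(GeoValidationError, match="square"):
            read_raster(tmp_path / "rect.tif")

    def test_geographic_units_rejected(self, tmp_path):
        import tifffile

        meta = {"heatscape_meta": {"cell_size": 0.001, "units": "degree"}}
        tifffile.imwrite(
            tmp_path / "deg.tif", np.zeros((2, 2)), description=json.dumps(meta)
        )
        with pytest.raises(GeoValidationError, match="planar"):
            read_raster(tmp_path / "deg.tif")

    def test_missing_file(self, tmp_path):
        with pytest.raises((FileNotFoundError, OSError, ValueError)):
            read_raster(tmp_path / "nope.tif")


class TestRasterGridInvariants:
    def test_cell_size_positive(self):
        with pytest.raises(GeoValidationError):
            RasterGrid(np.zeros((2, 2)), 0.0)

    def test_mask_shape_must_match(self):
        with pytest.raises(GeoValidationError):
            RasterGrid(np.zeros((2, 2)), 1.0, nodata_mask=np.zeros((3, 3), bool))

    def test_cell_centers_halfopen_convention(self):
        g = RasterGrid(np.zeros((2, 3)), 10.0, (100.0, 50.0))
        xs, ys = g.cell_centers()
        assert xs[0, 0] == 105.0 and ys[0, 0] == 45.0
        assert xs[1, 2] == 125.0 and ys[1, 2] == 35.0


class TestZoneLayer:
    def _square(self, x0, y0, s=1000.0):
        return sgeom.box(x0, y0, x0 + s, y0 + s)

    def test_area_km2_exact(self):
        layer = ZoneLayer(
            [("a", self._square(0, 0))],
            pd.DataFrame(index=pd.Index(["a"], name="zone_id")),
        )
        assert abs(layer.area_km2["a"] - 1.0) < 1e-9

    def test_duplicate_ids_rejected(self):
        zs = [("a", self._square(0, 0)), ("a", self._square(2000, 0))]
        with pytest.raises(GeoValidationError, match="duplicate"):
            ZoneLayer(zs, pd.DataFrame(index=pd.Index(["a"], name="zone_id")))

    def test_overlapping_interiors_rejected(self):
        zs = [("a", self._square(0, 0)), ("b", self._square(500, 0))]
        with pytest.raises(GeoValidationError, match="tessellation"):
            ZoneLayer(zs, pd.DataFrame(index=pd.Index(["a", "b"], name="zone_id")))

    def test_touching_zones_allowed(self):
        zs = [("a", self._square(0, 0)), ("b", self._square(1000, 0))]
        layer = ZoneLayer(zs, pd.DataFrame(index=pd.Index(["a", "b"], name="zone_id")))
        assert len(layer) == 2


class TestZoneIO:
    def _write_geojson(self, path, ids):
        feats = []
        for i, zid in enumerate(ids):
            geom = sgeom.box(i * 1000, 0, (i + 1) * 1000, 1000)
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"zone_id": zid},
                    "geometry": sgeom.mapping(geom),
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    def test_join_four_zones(self, tmp_path):
        gj = tmp_path / "z.geojson"
        self._write_geojson(gj, ["a", "b", "c", "d"])
        csv = tmp_path / "t.csv"
        pd.DataFrame({"zone_id": list("abcd"), "x": [1, 2, 3, 4]}).to_csv(
            csv, index=False
        )
        layer = read_zones(gj, csv)
        assert len(layer) == 4
        assert layer.attributes.loc["c", "x"] == 3

    def test_duplicate_table_id_errors(self, tmp_path):
        gj = tmp_path / "z.geojson"
        self._write_geojson(gj, ["a", "b"])
        csv = tmp_path / "t.csv"
        pd.DataFrame({"zone_id": ["a", "a"], "x": [1, 2]}).to_csv(csv, index=False)
        with pytest.raises(GeoValidationError, match="'a'"):
            read_zones(gj, csv)

    def test_orphan_id_warns_and_drops(self, tmp_path):
        gj = tmp_path / "z.geojson"
        self._write_geojson(gj, ["a", "b", "c", "d"])
        csv = tmp_path / "t.csv"
        pd.DataFrame({"zone_id": ["a", "b", "c"], "x": [1, 2, 3]}).to_csv(
            csv, index=False
        )
        with pytest.warns(UserWarning, match="d"):
            layer = read_zones(gj, csv)
        assert len(layer) == 3

    def test_write_read_roundtrip(self, tmp_path):
        gj = tmp_path / "z.geojson"
        self._write_geojson(gj, ["a", "b"])
        csv = tmp_path / "t.csv"
        pd.DataFrame({"zone_id": ["a", "b"], "x": [1.5, 2.5]}).to_csv(csv, index=False)
        layer = read_zones(gj, csv)
        out = tmp_path / "out.geojson"
        write_zones(layer, out)
        back = read_zones(out)
        assert back.zone_ids == layer.zone_ids
        for (_, g1), (_, g2) in zip(layer.zones, back.zones):
            assert g1.equals(g2)
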