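"""Shared raster/vector data model and file I/O.

The package works on a planar metric frame: raster cell sizes, polygon
coordinates and all distances are metres. Rasters are north-up, row-major,
with cell (0, 0) in the north-west corner; ``origin`` is the outer (x, y)
corner of that cell, so cell (r, c) covers the half-open square
``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` and its centre is at
``(x0 + (c + 0.5)*s, y0 - (r + 0.5)*s)``.

Nodata is a boolean mask in memory; on disk it is a sentinel value recorded
in metadata. Rasters round-trip bit-exactly through :func:`write_raster` /
:func:`read_raster`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
import tifffile

__all__ = [
    "RasterGrid",
    "ZoneLayer",
    "IndexLayer",
    "read_raster",
    "write_raster",
    "read_zones",
    "write_zones",
    "GeoValidationError",
]

# Description-tag key under which raster georeferencing is stored in TIFFs.
_META_KEY = "heatscape_meta"
_DEFAULT_NODATA = -9999.0

_GEOGRAPHIC_UNIT_NAMES = {"degree", "degrees", "deg"}
_GEOGRAPHIC_CRS_NAMES = ("4326", "crs84", "wgs 84", "wgs84")


class GeoValidationError(ValueError):
    """Raised when a raster or zone layer violates a structural invariant."""


@dataclass
class RasterGrid:
    """Rectangular field of values on a square-celled, north-up grid.

    Parameters
    ----------
    values
        2-D array of cell values (row 0 at the north edge).
    cell_size
        Edge length of the (square) cells in metres.
    origin
        ``(x, y)`` of the outer north-west corner of cell (0, 0).
    nodata_mask
        Boolean array, same shape as ``values``; True marks nodata cells,
        which are excluded from every statistic.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GeoValidationError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise GeoValidationError(f"cell_size must be > 0, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise GeoValidationError(
                "nodata_mask shape "
                f"{self.nodata_mask.shape} != values shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.cell_size, self.origin, self.nodata_mask.copy()
        )

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid on the same frame carrying ``values``."""
        if mask is None:
            mask = self.nodata_mask.copy()
        return RasterGrid(values, self.cell_size, self.origin, mask)

    def valid_values(self) -> np.ndarray:
        """1-D array of the non-nodata values."""
        return self.values[~self.nodata_mask]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(xs, ys)`` of cell-centre coordinates, shaped like values."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        s = self.cell_size
        xs = x0 + (np.arange(ncol) + 0.5) * s
        ys = y0 - (np.arange(nrow) + 0.5) * s
        return np.meshgrid(xs, ys)

    def same_frame(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


@dataclass
class ZoneLayer:
    """Polygon tessellation with identifiers and an attribute table.

    Zones are the census-like analysis units (for urban heat work,
    dissemination areas of roughly 400-700 persons). Polygons must be
    individually valid and pairwise interior-disjoint; ``area_km2`` is the
    planar polygon area in square kilometres.
    """

    zones: list[tuple[object, sgeom.base.BaseGeometry]]
    attributes: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [zid for zid, _ in self.zones]
        if len(set(ids)) != len(ids):
            seen, dups = set(), []
            for z in ids:
                if z in seen:
                    dups.append(z)
                seen.add(z)
            raise GeoValidationError(f"duplicate zone_id(s): {dups}")
        for zid, geom in self.zones:
            if not geom.is_valid:
                raise GeoValidationError(f"invalid geometry for zone {zid!r}")
            if geom.area <= 0:
                raise GeoValidationError(f"zone {zid!r} has non-positive area")
        self._check_tessellation()
        if not self.attributes.index.is_unique:
            dups = self.attributes.index[self.attributes.index.duplicated()].tolist()
            raise GeoValidationError(f"duplicate zone_id(s) in attribute table: {dups}")

    def _check_tessellation(self, rel_tol: float = 1e-9) -> None:
        geoms = [g for _, g in self.zones]
        tree = shapely.STRtree(geoms)
        pairs = tree.query(geoms, predicate="intersects")
        for i, j in zip(*pairs):
            if i >= j:
                continue
            inter = geoms[i].intersection(geoms[j])
            if inter.area > rel_tol * min(geoms[i].area, geoms[j].area):
                raise GeoValidationError(
                    f"zones {self.zones[i][0]!r} and {self.zones[j][0]!r} "
                    "have overlapping interiors (not a tessellation)"
                )

    @property
    def zone_ids(self) -> list:
        return [zid for zid, _ in self.zones]

    @property
    def geometries(self) -> list[sgeom.base.BaseGeometry]:
        return [g for _, g in self.zones]

    @property
    def area_km2(self) -> pd.Series:
        return pd.Series(
            [g.area / 1e6 for _, g in self.zones], index=self.zone_ids, name="area_km2"
        )

    def __len__(self) -> int:
        return len(self.zones)


@dataclass
class IndexLayer:
    """Integer 1..k classification, on either a raster or a per-zone carrier.

    ``breaks`` are the k-1 strictly increasing upper class boundaries used
    to produce the labels (empty for a degenerate single-class layer).
    """

    carrier: "RasterGrid | pd.Series"
    k: int
    breaks: np.ndarray

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        if self.breaks.size and not np.all(np.diff(self.breaks) > 0):
            raise GeoValidationError("breaks must be strictly increasing")
        vals = self.labels()
        vals = vals[np.isfinite(vals)]
        if vals.size and (vals.min() < 1 or vals.max() > self.k):
            raise GeoValidationError(
                f"index values must lie in 1..{self.k}, "
                f"found range [{vals.min()}, {vals.max()}]"
            )

    @property
    def is_raster(self) -> bool:
        return isinstance(self.carrier, RasterGrid)

    def labels(self) -> np.ndarray:
        """Non-nodata label values as a flat float array (NaN dropped)."""
        if self.is_raster:
            return self.carrier.valid_values().astype(float)
        arr = np.asarray(self.carrier, dtype=float)
        return arr[~np.isnan(arr)]


# ---------------------------------------------------------------------------
# Raster I/O (single-band TIFF, georeferencing in the ImageDescription tag)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path, nodata: float = _DEFAULT_NODATA) -> None:
    """Write ``grid`` as a single-band TIFF.

    Cell size, origin and the nodata sentinel go into the ImageDescription
    tag as JSON, so the file round-trips bit-exactly through
    :func:`read_raster` (values keep their dtype; masked cells hold the
    sentinel on disk and come back as mask bits).
    """
    values = grid.values.copy()
    if grid.nodata_mask.any():
        if np.issubdtype(values.dtype, np.integer):
            nodata = int(nodata)
        values[grid.nodata_mask] = nodata
    meta = {
        _META_KEY: {
            "cell_size": grid.cell_size,
            "origin": list(grid.origin),
            "nodata": nodata,
            "units": "metre",
        }
    }
    tifffile.imwrite(str(path), values, description=json.dumps(meta))


def read_raster(path) -> RasterGrid:
    """Read a single-band TIFF written by :func:`write_raster`.

    Files with rectangular (non-square) cells or geographic (degree) units
    are rejected. Cells equal to the recorded nodata sentinel become mask
    bits.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value).get(_META_KEY, {})
            except (json.JSONDecodeError, AttributeError):
                meta = {}
    if values.ndim != 2:
        raise GeoValidationError(f"{path}: expected a single-band 2-D raster")
    units = str(meta.get("units", "metre")).lower()
    if units in _GEOGRAPHIC_UNIT_NAMES:
        raise GeoValidationError(
            f"{path}: raster declares geographic (degree) units; "
            "coordinates must be planar metres"
        )
    cell_size = meta.get("cell_size", 1.0)
    if isinstance(cell_size, (list, tuple)):
        sx, sy = float(cell_size[0]), float(cell_size[1])
        if sx != sy:
            raise GeoValidationError(
                f"{path}: rectangular cells ({sx} x {sy} m) are not supported; "
                "cells must be square"
            )
        cell_size = sx
    origin = tuple(meta.get("origin", (0.0, 0.0)))
    nodata = meta.get("nodata")
    mask = None
    if nodata is not None:
        mask = values == nodata
    return RasterGrid(values, float(cell_size), origin, mask)


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON + CSV attribute table)
# ---------------------------------------------------------------------------

def _check_geojson_crs(obj: dict, path) -> None:
    crs = obj.get("crs")
    if crs is None:
        return  # GeoJSON default is geographic, but coordinates here are
        # declared planar by the package contract; only an explicit
        # geographic CRS is rejected.
    name = str(crs.get("properties", {}).get("name", "")).lower()
    if any(tag in name for tag in _GEOGRAPHIC_CRS_NAMES):
        raise GeoValidationError(
            f"{path}: geographic CRS {name!r}; coordinates must be planar metres"
        )


def read_zones(path, attribute_table_path=None, id_key: str = "zone_id") -> ZoneLayer:
    """Read a GeoJSON polygon layer, optionally inner-joined to a CSV table.

    The join key is ``id_key`` (a feature property and a CSV column).
    Zones missing from the table are dropped with a warning naming the
    orphan ids; a duplicated id in the table is an error.
    """
    with open(path) as fh:
        obj = json.load(fh)
    _check_geojson_crs(obj, path)
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else [obj]
    zones = []
    props_rows = []
    for feat in feats:
        props = feat.get("properties") or {}
        if id_key not in props:
            raise GeoValidationError(f"{path}: feature missing {id_key!r} property")
        geom = sgeom.shape(feat["geometry"])
        zones.append((props[id_key], geom))
        props_rows.append(props)
    if attribute_table_path is not None:
        table = pd.read_csv(attribute_table_path)
        if id_key not in table.columns:
            raise GeoValidationError(
                f"{attribute_table_path}: missing {id_key!r} column"
            )
        dup = table[id_key][table[id_key].duplicated()].tolist()
        if dup:
            raise GeoValidationError(
                f"{attribute_table_path}: duplicate zone_id(s): {dup}"
            )
        table = table.set_index(id_key)
    else:
        table = pd.DataFrame(props_rows).set_index(id_key)
    zone_ids = [zid for zid, _ in zones]
    matched = [zid for zid in zone_ids if zid in table.index]
    orphans_geom = sorted(set(zone_ids) - set(table.index), key=str)
    orphans_table = sorted(set(table.index) - set(zone_ids), key=str)
    if orphans_geom or orphans_table:
        warnings.warn(
            "zone/attribute join dropped unmatched ids: "
            f"geometry-only={orphans_geom}, table-only={orphans_table}",
            stacklevel=2,
        )
    zones = [(zid, g) for zid, g in zones if zid in table.index]
    table = table.loc[matched]
    return ZoneLayer(zones, table)


def write_zones(layer: ZoneLayer, path, properties: pd.DataFrame | None = None) -> None:
    """Write a ZoneLayer as a GeoJSON FeatureCollection.

    Attribute columns (or ``properties`` if given) are embedded as feature
    properties next to ``zone_id``.
    """
    table = layer.attributes if properties is None else properties
    feats = []
    for zid, geom in layer.zones:
        props = {"zone_id": zid}
        if zid in table.index:
            row = table.loc[zid]
            props.update({k: _jsonable(v) for k, v in row.items()})
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": sgeom.mapping(geom),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
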