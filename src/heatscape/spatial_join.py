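"""Raster-based and vector-based aggregation frames.

The mismatch between a 60 m temperature grid and census polygons can be
bridged in two directions, and the choice changes the map (the modifiable
areal unit problem). The raster frame resamples zone attributes onto the
grid by taking, for each cell, the value of the zone containing its
centre; the vector frame aggregates the grid into zones by the mean of the
cells whose centres fall inside each polygon. Cell-centre containment is
used for both directions so that they are exact duals: when every zone is
a single cell the two pipelines coincide bit-for-bit.

Cell centres that land exactly on a shared boundary are assigned to the
zone whose id sorts first, deterministically, and the count of such ties
is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .breaks import classify_attribute, classify_grid
from .core_geo import GeoValidationError, IndexLayer, RasterGrid, ZoneLayer
from .lst import ThermalInputs, retrieve_lst
from .mca import WeightScheme, build_risk_index
from .vulnerability import build_vulnerability_composite, density_normalize

__all__ = [
    "assign_cells_to_zones",
    "polygon_to_raster",
    "zonal_mean",
    "PipelineResult",
    "run_raster_pipeline",
    "run_vector_pipeline",
]


def assign_cells_to_zones(
    template: RasterGrid, zones: ZoneLayer
) -> tuple[np.ndarray, int]:
    """Zone index (into ``zones.zones``) per cell; -1 where no zone contains
    the cell centre. Second return is the boundary-tie count."""
    xs, ys = template.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    tree = shapely.STRtree(zones.geometries)
    p_idx, z_idx = tree.query(pts, predicate="intersects")
    # tie rule: zone whose zone_id sorts first wins
    order = np.argsort(np.argsort([str(z) for z in zones.zone_ids], kind="stable"))
    rank = order[z_idx]
    n_cells = pts.size
    best_rank = np.full(n_cells, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(best_rank, p_idx, rank)
    assignment = np.full(n_cells, -1, dtype=np.int64)
    hit_counts = np.zeros(n_cells, dtype=np.int64)
    np.add.at(hit_counts, p_idx, 1)
    # map winning rank back to zone position
    rank_to_pos = np.empty(len(zones), dtype=np.int64)
    rank_to_pos[order] = np.arange(len(zones))
    has_hit = hit_counts > 0
    assignment[has_hit] = rank_to_pos[best_rank[has_hit]]
    n_ties = int((hit_counts > 1).sum())
    return assignment.reshape(template.shape), n_ties


def polygon_to_raster(
    zones: ZoneLayer, column: str, template: RasterGrid
) -> tuple[RasterGrid, dict]:
    """Resample a zone attribute onto the template grid (cell-centre rule).

    Cells whose centre lies in no zone become nodata. Returns the grid and
    a diagnostics dict with ``boundary_ties`` and ``n_unassigned``.
    """
    assignment, n_ties = assign_cells_to_zones(template, zones)
    col = zones.attributes[column].to_numpy(dtype=float)
    out = np.full(template.shape, np.nan)
    hit = assignment >= 0
    out[hit] = col[assignment[hit]]
    mask = ~hit
    return template.like(out, mask), {
        "boundary_ties": n_ties,
        "n_unassigned": int(mask.sum()),
    }


def zonal_mean(raster: RasterGrid, zones: ZoneLayer) -> tuple[pd.Series, dict]:
    """Per-zone arithmetic mean of the non-nodata cells whose centres fall
    inside each polygon. Zones containing no cell centre get NaN with a
    warning."""
    assignment, n_ties = assign_cells_to_zones(raster, zones)
    flat_assign = assignment.ravel()
    flat_vals = raster.values.ravel().astype(float)
    ok = (flat_assign >= 0) & ~raster.nodata_mask.ravel()
    nz = len(zones)
    sums = np.zeros(nz)
    counts = np.zeros(nz)
    np.add.at(sums, flat_assign[ok], flat_vals[ok])
    np.add.at(counts, flat_assign[ok], 1)
    # constant zones take the constant itself, so the mean is exact (the
    # round trip with polygon_to_raster conserves attributes bit-for-bit)
    lo = np.full(nz, np.inf)
    hi = np.full(nz, -np.inf)
    np.minimum.at(lo, flat_assign[ok], flat_vals[ok])
    np.maximum.at(hi, flat_assign[ok], flat_vals[ok])
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        means = np.where((counts > 0) & (lo == hi), lo, means)
    empty = [zid for zid, c in zip(zones.zone_ids, counts) if c == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} zone(s) contain no cell centre: {empty[:10]}",
            stacklevel=2,
        )
    return (
        pd.Series(means, index=zones.zone_ids, name="zonal_mean"),
        {"boundary_ties": n_ties, "empty_zones": empty},
    )


@dataclass
class PipelineResult:
    """Risk index plus the intermediate layers the analysis produced."""

    risk: IndexLayer
    exposure_idx: IndexLayer
    vulnerability_idx: IndexLayer
    lst: RasterGrid | pd.Series
    meta: dict = field(default_factory=dict)


def _resolve_lst(thermal) -> tuple[RasterGrid, dict]:
    if isinstance(thermal, ThermalInputs):
        return retrieve_lst(thermal)
    if isinstance(thermal, RasterGrid):
        return thermal, {}
    raise TypeError("thermal must be ThermalInputs or an LST RasterGrid")


def run_raster_pipeline(
    thermal,
    zones: ZoneLayer,
    table: pd.DataFrame,
    k: int = 9,
    scheme: WeightScheme | None = None,
    method: str = "jenks",
    breaks_domain: str = "zones",
) -> PipelineResult:
    """Risk analysis on the raster frame (grid cells are the units).

    LST is classified 1..k cell-by-cell; the zone-level vulnerability
    composite is resampled onto cells by the cell-centre rule; the two are
    combined 50/50 (by default) and re-classified on the cell domain.
    Cells outside every zone are masked throughout.
    """
    scheme = scheme or WeightScheme(k=k)
    lst_grid, lst_diag = _resolve_lst(thermal)
    assignment, n_ties = assign_cells_to_zones(lst_grid, zones)
    covered = assignment >= 0
    lst_masked = lst_grid.like(lst_grid.values, lst_grid.nodata_mask | ~covered)
    exposure_idx = classify_grid(lst_masked, k=k, method=method)
    densities = density_normalize(table, zones)
    _, vuln_raster, vmeta = build_vulnerability_composite(
        densities,
        zones,
        grid_template=lst_masked,
        k=k,
        weights=scheme.vulnerability_weights,
        breaks_domain=breaks_domain,
        method=method,
    )
    risk = build_risk_index(vuln_raster, exposure_idx, scheme, method=method)
    return PipelineResult(
        risk=risk,
        exposure_idx=exposure_idx,
        vulnerability_idx=vuln_raster,
        lst=lst_masked,
        meta={
            "frame": "raster",
            "boundary_ties": n_ties,
            "vulnerability": vmeta,
            "lst_diagnostics": lst_diag,
        },
    )


def run_vector_pipeline(
    thermal,
    zones: ZoneLayer,
    table: pd.DataFrame,
    k: int = 9,
    scheme: WeightScheme | None = None,
    method: str = "jenks",
) -> PipelineResult:
    """Risk analysis on the vector frame (zones are the units).

    LST is averaged into zones (cell-centre membership), classified 1..k
    across zones, and combined with the zone-level vulnerability composite.
    """
    scheme = scheme or WeightScheme(k=k)
    lst_grid, lst_diag = _resolve_lst(thermal)
    zone_lst, zdiag = zonal_mean(lst_grid, zones)
    densities = density_normalize(table, zones)
    zlayer = ZoneLayer(zones.zones, zone_lst.to_frame())
    exposure_idx = classify_attribute(zlayer, "zonal_mean", k=k, method=method)
    vuln_zone, _, vmeta = build_vulnerability_composite(
        densities,
        zones,
        grid_template=None,
        k=k,
        weights=scheme.vulnerability_weights,
        breaks_domain="zones",
        method=method,
    )
    risk = build_risk_index(vuln_zone, exposure_idx, scheme, method=method)
    return PipelineResult(
        risk=risk,
        exposure_idx=exposure_idx,
        vulnerability_idx=vuln_zone,
        lst=zone_lst,
        meta={
            "frame": "vector",
            "zonal": zdiag,
            "vulnerability": vmeta,
            "lst_diagnostics": lst_diag,
        },
    )
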