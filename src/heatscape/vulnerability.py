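"""Social heat-vulnerability surfaces from census-style zone attributes.

Eight variables quantify population vulnerability to extreme heat: counts
of seniors, infants, households in pre-1970 housing, households in
multi-storey/mobile ("high heat risk") homes, low-income population,
low-education population, single-person households, plus the unemployment
rate. The seven count variables are normalised to densities (per km^2 of
zone area) so that large and small zones are comparable; the unemployment
rate is already intensive and passes through unchanged.

Each density surface is classified into k ordinal classes (1 = lowest
vulnerability, k = highest) by natural breaks, the classified layers are
combined as an equally-weighted average (weights configurable; equal
weights are the default because no calibration data exist to justify
others), and the composite is re-classified to stretch it back onto 1..k.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .breaks import classify_attribute, classify_values, jenks_breaks, assign_labels
from .core_geo import IndexLayer, RasterGrid, ZoneLayer

__all__ = [
    "COUNT_VARIABLES",
    "RATE_VARIABLES",
    "VULNERABILITY_VARIABLES",
    "validate_table",
    "density_normalize",
    "build_vulnerability_composite",
]

COUNT_VARIABLES = (
    "seniors",
    "infants",
    "old_housing_households",
    "high_risk_homes",
    "low_income",
    "low_education",
    "living_alone",
)
RATE_VARIABLES = ("unemployment_rate",)
VULNERABILITY_VARIABLES = COUNT_VARIABLES + RATE_VARIABLES


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the eight-variable table: counts >= 0, rate in [0, 100]."""
    missing = [c for c in VULNERABILITY_VARIABLES if c not in table.columns]
    if missing:
        raise ValueError(f"vulnerability table missing column(s): {missing}")
    if not table.index.is_unique:
        raise ValueError("vulnerability table has duplicated zone ids")
    for c in COUNT_VARIABLES:
        if (table[c] < 0).any():
            bad = table.index[table[c] < 0].tolist()
            raise ValueError(f"negative count in {c!r} for zone(s) {bad}")
    r = table["unemployment_rate"]
    if ((r < 0) | (r > 100)).any():
        raise ValueError("unemployment_rate must lie in [0, 100]")
    return table


def density_normalize(table: pd.DataFrame, zones: ZoneLayer) -> pd.DataFrame:
    """Counts -> counts per km^2 of zone area; rates pass through.

    Any zone with non-positive area is an error naming the zone (a zero
    area would silently blow a density up to infinity).
    """
    validate_table(table)
    area = zones.area_km2.reindex(table.index)
    if area.isna().any():
        raise ValueError(
            f"zones missing for table ids {table.index[area.isna()].tolist()}"
        )
    if (area <= 0).any():
        raad = table.index[area <= 0].tolist()
        raise ValueError(f"zone(s) with non-positive area: {raad}")
    out = table.copy()
    for c in COUNT_VARIABLES:
        out[c] = table[c] / area
    return out


def _check_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(
        list(weights.values()) if isinstance(weights, dict) else weights, dtype=float
    )
    if w.size != n:
        raise ValueError(f"expected {n} weights, got {w.size}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return w


def build_vulnerability_composite(
    densities: pd.DataFrame,
    zones: ZoneLayer,
    grid_template: RasterGrid | None = None,
    k: int = 9,
    weights=None,
    breaks_domain: str = "zones",
    method: str = "jenks",
):
    """Composite heat-vulnerability index from the eight density surfaces.

    Each variable is classified 1..k by natural breaks, the class layers
    are averaged with ``weights`` (default: eight equal weights of 1/8),
    and the weighted average is re-classified into 1..k.

    ``breaks_domain`` decides where per-variable breaks are computed:
    "zones" (default) uses one value per zone; "cells" rasterises the
    densities first so values are duplicated in proportion to zone size,
    which shifts break positions. The choice is recorded in the returned
    metadata.

    Returns ``(zone_index, raster_index, meta)``; ``raster_index`` is None
    when no ``grid_template`` is given. The zone composite is always
    computed; the raster variant resamples by the cell-centre rule.
    """
    from .spatial_join import polygon_to_raster  # local: avoid import cycle

    if weights is None:
        weights = np.full(len(VULNERABILITY_VARIABLES), 1.0 / 8)
    w = _check_weights(weights, len(VULNERABILITY_VARIABLES))
    if breaks_domain not in ("zones", "cells"):
        raise ValueError(f"breaks_domain must be 'zones' or 'cells', got {breaks_domain!r}")

    meta: dict = {"breaks_domain": breaks_domain, "weights": w.tolist(), "k": k}

    if breaks_domain == "cells" and grid_template is None:
        raise ValueError("breaks_domain='cells' requires a grid_template")

    # --- per-variable 1..k index layers -----------------------------------
    zone_index_layers: list[pd.Series] = []
    per_var_breaks: dict[str, list[float]] = {}
    if breaks_domain == "zones":
        for var in VULNERABILITY_VARIABLES:
            idx = classify_attribute(
                ZoneLayer(zones.zones, densities), var, k=k, method=method
            )
            zone_index_layers.append(pd.Series(idx.carrier, name=var))
            per_var_breaks[var] = np.asarray(idx.breaks).tolist()
        score = sum(wi * s for wi, s in zip(w, zone_index_layers))
        labels, res = classify_values(score.to_numpy(dtype=float), k, method)
        zone_idx = IndexLayer(
            carrier=pd.Series(labels, index=score.index, name="vulnerability_idx"),
            k=res.k,
            breaks=res.breaks,
        )
        raster_idx = None
        if grid_template is not None:
            # the raster frame resamples the finished zone composite by the
            # cell-centre rule: classes stay as classified on zones, so the
            # raster variant is the exact dual of the vector one
            comp = pd.Series(zone_idx.carrier, name="vulnerability_idx")
            g, _ = polygon_to_raster(
                ZoneLayer(zones.zones, comp.to_frame()), comp.name, grid_template
            )
            raster_idx = IndexLayer(
                carrier=g.like(g.values.astype(np.int16), g.nodata_mask),
                k=zone_idx.k,
                breaks=zone_idx.breaks,
            )
    else:  # cells domain: rasterise densities first, classify cell-by-cell
        cell_layers = []
        cell_mask = None
        for var in VULNERABILITY_VARIABLES:
            g, _ = polygon_to_raster(ZoneLayer(zones.zones, densities), var, grid_template)
            cell_layers.append(g)
            cell_mask = g.nodata_mask if cell_mask is None else (cell_mask | g.nodata_mask)
        valid = ~cell_mask
        idx_stack = []
        for var, g in zip(VULNERABILITY_VARIABLES, cell_layers):
            lab, res_v = classify_values(g.values[valid], k, method)
            per_var_breaks[var] = np.asarray(res_v.breaks).tolist()
            idx_stack.append(lab.astype(float))
        cell_score = sum(wi * v for wi, v in zip(w, idx_stack))
        lab, res_c = classify_values(cell_score, k, method)
        out = np.zeros(grid_template.shape, dtype=np.int16)
        out[valid] = lab
        raster_idx = IndexLayer(
            carrier=grid_template.like(out, cell_mask), k=res_c.k, breaks=res_c.breaks
        )
        # zone composite from zone-level classification is still reported
        zone_idx, _, _ = build_vulnerability_composite(
            densities, zones, None, k=k, weights=w, breaks_domain="zones", method=method
        )
    meta["per_variable_breaks"] = per_var_breaks
    return zone_idx, raster_idx, meta
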