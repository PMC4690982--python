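"""Multi-criteria combination of exposure and vulnerability into risk.

Risk is framed as the Crichton risk-triangle product of two ordered index
layers — heat exposure (from land-surface temperature) and social
vulnerability (the eight-variable composite) — combined as a weighted
average of their 1..k class values and re-classified into 1..k. The
weighted average treats the ordinal class values as if cardinal; that
ordinal-as-interval step is exactly what weighted-overlay MCA does and is
documented as an assumption, not hidden.

Equal weights (50/50 for risk, 1/8 each for the vulnerability layers) are
the defaults: no mortality-calibration data exist to justify others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breaks import classify_values
from .core_geo import IndexLayer, RasterGrid

__all__ = ["WeightScheme", "combine_weighted", "build_risk_index"]


@dataclass
class WeightScheme:
    """Weights for the two-stage MCA.

    vulnerability_weights : eight non-negative reals summing to 1
    risk_weights : (w_vulnerability, w_exposure), non-negative, summing to 1
    k : number of index classes (>= 2)
    """

    vulnerability_weights: tuple = tuple([1.0 / 8] * 8)
    risk_weights: tuple[float, float] = (0.5, 0.5)
    k: int = 9

    def __post_init__(self) -> None:
        vw = np.asarray(self.vulnerability_weights, dtype=float)
        rw = np.asarray(self.risk_weights, dtype=float)
        if vw.size != 8 or abs(vw.sum() - 1) > 1e-9 or np.any(vw < 0):
            raise ValueError("vulnerability_weights must be 8 non-negative reals summing to 1")
        if rw.size != 2 or abs(rw.sum() - 1) > 1e-9 or np.any(rw < 0):
            raise ValueError("risk_weights must be 2 non-negative reals summing to 1")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


def _carriers(layers: list[IndexLayer]):
    kinds = {layer.is_raster for layer in layers}
    if len(kinds) != 1:
        raise ValueError("cannot combine raster and per-zone index layers")
    return kinds.pop()


def combine_weighted(index_layers: list[IndexLayer], weights):
    """Per-cell / per-zone weighted mean of index values.

    All layers must share a frame (raster grid or zone index). A location
    is nodata in the output if any contributing layer is nodata there.
    Returns a RasterGrid (raster input) or pandas Series (zone input) of
    real-valued scores.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != len(index_layers):
        raise ValueError(f"{len(index_layers)} layers but {w.size} weights")
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must be non-negative and sum to 1")
    is_raster = _carriers(index_layers)
    if is_raster:
        grids: list[RasterGrid] = [l.carrier for l in index_layers]
        base = grids[0]
        for g in grids[1:]:
            if not base.same_frame(g):
                raise ValueError("index layers do not share a raster frame")
        mask = np.zeros(base.shape, dtype=bool)
        for g in grids:
            mask |= g.nodata_mask
        score = np.zeros(base.shape, dtype=float)
        for wi, g in zip(w, grids):
            score += wi * g.values.astype(float)
        score[mask] = np.nan
        return base.like(score, mask)
    series: list[pd.Series] = [pd.Series(l.carrier) for l in index_layers]
    idx = series[0].index
    for s in series[1:]:
        if not s.index.equals(idx):
            raise ValueError("index layers do not share a zone frame")
    out = sum(wi * s.astype(float) for wi, s in zip(w, series))
    return out


def build_risk_index(
    vulnerability_idx: IndexLayer,
    exposure_idx: IndexLayer,
    scheme: WeightScheme | None = None,
    method: str = "jenks",
) -> IndexLayer:
    """Combine vulnerability and exposure indices into the k-class risk index.

    The 50/50 (by default) weighted average of the two 1..k layers is
    re-classified by natural breaks into 1..k: class 1 is jointly low
    vulnerability and exposure, class k jointly high. A constant score
    surface (both inputs constant) collapses to a single class with a
    degenerate-input warning.
    """
    scheme = scheme or WeightScheme()
    score = combine_weighted(
        [vulnerability_idx, exposure_idx], scheme.risk_weights
    )
    if isinstance(score, RasterGrid):
        valid = ~score.nodata_mask
        labels, res = classify_values(score.values[valid], scheme.k, method)
        out = np.zeros(score.shape, dtype=np.int16)
        out[valid] = labels
        return IndexLayer(carrier=score.like(out), k=res.k, breaks=res.breaks)
    labels, res = classify_values(score.to_numpy(dtype=float), scheme.k, method)
    return IndexLayer(
        carrier=pd.Series(labels, index=score.index, name="risk_idx"),
        k=res.k,
        breaks=res.breaks,
    )
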