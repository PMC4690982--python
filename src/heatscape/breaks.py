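"""Jenks natural-breaks optimal 1-D classification.

All index layers in the risk pipeline (the eight vulnerability surfaces,
the exposure layer, the composite and the final risk layer) are discretised
into k ordered classes by minimising the total within-class sum of squared
deviations (SSD) over contiguous partitions of the sorted values. The exact
Fisher dynamic programme is used (O(k m^2) on the m distinct values), not
the iterative heuristic, so the optimum is global and deterministic.

Class intervals are half-open on the left, ``(b_{i-1}, b_i]``, with the
first interval closed below: a value equal to a break belongs to the lower
class. Values outside the training range clamp to class 1 or k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_geo import IndexLayer, RasterGrid, ZoneLayer

__all__ = ["BreaksResult", "jenks_breaks", "quantile_breaks", "assign_classes",
           "classify_grid", "classify_attribute", "classify_values"]


@dataclass
class BreaksResult:
    """Result of a 1-D optimal classification.

    breaks : the k-1 strictly increasing upper class boundaries (values
        from the input; the maximum of each class but the last)
    within_class_ssd : total within-class sum of squared deviations from
        the class means at the optimum
    k : number of classes actually used (may be reduced for degenerate
        inputs with fewer distinct values than requested)
    """

    breaks: np.ndarray
    within_class_ssd: float
    k: int


def _dedupe(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted distinct values and their multiplicities."""
    return np.unique(values, return_counts=True)


def _fisher_jenks(v: np.ndarray, w: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact weighted Fisher DP over m distinct values.

    Returns the end index (inclusive, into ``v``) of each of the k classes
    and the optimal total within-class SSD. Ties in the argmin break toward
    the smallest start index, making the partition deterministic.
    """
    m = v.size
    W = np.concatenate(([0.0], np.cumsum(w)))
    Sx = np.concatenate(([0.0], np.cumsum(w * v)))
    Sxx = np.concatenate(([0.0], np.cumsum(w * v * v)))

    def ssd_span(i: np.ndarray, j: int) -> np.ndarray:
        # SSD of values i..j (inclusive); i may be an array
        wt = W[j + 1] - W[i]
        sx = Sx[j + 1] - Sx[i]
        sxx = Sxx[j + 1] - Sxx[i]
        return sxx - sx * sx / wt

    # dp[j] = optimal SSD of v[0..j] with c classes; start with c = 1
    zero = np.array([0])
    dp = np.array([ssd_span(zero, j)[0] for j in range(m)])
    back = np.zeros((k, m), dtype=int)
    for c in range(1, k):
        dp_new = np.full(m, np.inf)
        for j in range(c, m):
            starts = np.arange(c, j + 1)
            cost = dp[starts - 1] + ssd_span(starts, j)
            best = int(np.argmin(cost))
            dp_new[j] = cost[best]
            back[c, j] = starts[best]
        dp = dp_new
    # recover class end indices
    ends = np.empty(k, dtype=int)
    j = m - 1
    for c in range(k - 1, -1, -1):
        ends[c] = j
        j = back[c, j] - 1
    return ends, float(dp[m - 1])


def jenks_breaks(values, k: int) -> BreaksResult:
    """Optimal k-class natural breaks of a multiset of reals.

    If the input has fewer distinct values than k, one class per distinct
    value is returned (k reduced) with a warning. Empty input is an error.
    The result is invariant to input order.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("jenks_breaks: empty input")
    if k < 1:
        raise ValueError(f"jenks_breaks: k must be >= 1, got {k}")
    v, w = _dedupe(values)
    m = v.size
    if m < k:
        warnings.warn(
            f"only {m} distinct value(s) for k={k}; reducing to k={m}",
            stacklevel=2,
        )
        k = m
    ends, ssd = _fisher_jenks(v, w.astype(float), k)
    breaks = v[ends[:-1]] if k > 1 else np.array([])
    return BreaksResult(breaks=np.asarray(breaks, float), within_class_ssd=ssd, k=k)


def quantile_breaks(values, k: int) -> BreaksResult:
    """Quantile classification (sensitivity-analysis alternative to Jenks)."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("quantile_breaks: empty input")
    qs = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
    breaks = np.unique(qs)
    k_eff = breaks.size + 1
    if k_eff < k:
        warnings.warn(f"quantile breaks degenerate; k reduced to {k_eff}", stacklevel=2)
    labels = assign_labels(values, breaks)
    ssd = 0.0
    for c in range(1, k_eff + 1):
        grp = values[labels == c]
        if grp.size:
            ssd += float(((grp - grp.mean()) ** 2).sum())
    return BreaksResult(breaks=breaks, within_class_ssd=ssd, k=k_eff)


def assign_labels(values, breaks: np.ndarray) -> np.ndarray:
    """Labels 1..k from upper class boundaries; break values go low."""
    values = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(breaks, float), values, side="left") + 1


def assign_classes(values, result: BreaksResult) -> np.ndarray:
    """Apply a BreaksResult: integer labels 1..k, NaN passed through as 0."""
    values = np.asarray(values, dtype=float)
    labels = assign_labels(values, result.breaks)
    labels = np.where(np.isnan(values), 0, labels)
    return labels.astype(int)


def classify_values(values, k: int, method: str = "jenks") -> tuple[np.ndarray, BreaksResult]:
    """Break computation + assignment in one step on a value array."""
    fn = {"jenks": jenks_breaks, "quantile": quantile_breaks}[method]
    res = fn(values, k)
    if res.k < k:
        warnings.warn(
            f"degenerate input: {res.k} class(es) used where {k} requested",
            stacklevel=2,
        )
    vals = np.asarray(values, dtype=float)
    labels = assign_labels(vals, res.breaks).astype(float)
    labels[np.isnan(vals)] = np.nan  # missing stays missing
    return labels, res


def classify_grid(grid: RasterGrid, k: int = 9, method: str = "jenks") -> IndexLayer:
    """Classify all non-nodata cells of a raster into 1..k.

    Breaks are computed once on the full grid's non-nodata distribution
    (study-area-wide, not per tile).
    """
    valid = grid.valid_values()
    labels_flat, res = classify_values(valid, k, method)
    out = np.zeros(grid.shape, dtype=np.int16)
    out[~grid.nodata_mask] = labels_flat
    carrier = grid.like(out)
    return IndexLayer(carrier=carrier, k=res.k, breaks=res.breaks)


def classify_attribute(
    layer: ZoneLayer, column: str, k: int = 9, method: str = "jenks"
) -> IndexLayer:
    """Classify one attribute column across zones into 1..k."""
    import pandas as pd

    vals = layer.attributes[column].to_numpy(dtype=float)
    labels, res = classify_values(vals, k, method)
    series = pd.Series(labels, index=layer.zone_ids, name=f"{column}_idx")
    return IndexLayer(carrier=series, k=res.k, breaks=res.breaks)
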