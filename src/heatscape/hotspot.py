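"""Getis-Ord G_i hotspot statistic on raster surfaces, swept over lags.

For cell i and a binary distance-band weight matrix w_ij(d) (ones for all
cells j != i whose centre lies within d cells of i, zero otherwise,
including the diagonal), the G_i ratio is

    G_i(d) = sum_j w_ij(d) x_j / sum_{j != i} x_j .

The printed ratio is tiny for large grids, so hotspot maps use the
standardised form: under the randomisation hypothesis (values permuted
over cells, conditioning on x_i) the neighbourhood sum has mean
W_i * xbar_(i) and the z-score is

    z_i = (sum_j w_ij x_j - W_i xbar_(i))
          / ( s_(i) * sqrt( W_i (n - 1 - W_i) / (n - 2) ) )

with xbar_(i), s_(i) the mean and standard deviation of all values except
x_i, and W_i the number of in-bounds, valid neighbours (edge cells simply
have fewer). High z marks a hot spot, low z a cold spot; sweeping the lag
distance d from one to several cells moves the map from local detail to
smoothed regional pattern.

Self-excluded G_i is the default, matching the ratio above; the
self-inclusive G_i* variant is available via ``star=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_geo import IndexLayer, RasterGrid

__all__ = ["GiWeights", "GiField", "build_weights", "gi_ratio", "gi_zscore",
           "hotspot_sweep", "local_roughness"]


@dataclass
class GiWeights:
    """Distance-band neighbourhood on the cell lattice.

    offsets : (m, 2) integer array of (dr, dc) with Euclidean length <= d,
        excluding (0, 0); closed under negation.
    d : lag distance in cells
    cell_size : metres per cell (for radius_m = d * cell_size)
    metric : "euclidean" (default; rook neighbours at d=1) or "chebyshev"
    """

    offsets: np.ndarray
    d: int
    cell_size: float
    metric: str = "euclidean"

    @property
    def radius_m(self) -> float:
        return self.d * self.cell_size

    def kernel(self) -> np.ndarray:
        """(2d+1)^2 binary footprint with the centre zero."""
        k = np.zeros((2 * self.d + 1, 2 * self.d + 1))
        k[self.offsets[:, 0] + self.d, self.offsets[:, 1] + self.d] = 1.0
        return k


def build_weights(
    template: RasterGrid, d: int, metric: str = "euclidean", star: bool = False
) -> GiWeights:
    """Enumerate the lattice offsets within lag distance d (cells).

    Euclidean metric: all integer (dr, dc) with dr^2 + dc^2 <= d^2, origin
    excluded (d=1 gives the 4 rook neighbours; d=4 gives 48 offsets).
    ``star=True`` keeps the origin (the self-inclusive variant).
    """
    if d < 1:
        raise ValueError(f"lag distance d must be >= 1, got {d}")
    rng = np.arange(-d, d + 1)
    dr, dc = np.meshgrid(rng, rng, indexing="ij")
    if metric == "euclidean":
        inside = dr * dr + dc * dc <= d * d
    elif metric == "chebyshev":
        inside = np.maximum(np.abs(dr), np.abs(dc)) <= d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if not star:
        inside &= ~((dr == 0) & (dc == 0))
    offsets = np.stack([dr[inside], dc[inside]], axis=1)
    return GiWeights(offsets=offsets, d=int(d), cell_size=template.cell_size,
                     metric=metric)


def _neighbour_sums(values: RasterGrid, weights: GiWeights):
    """Per-cell sum of valid neighbour values and valid-neighbour counts."""
    kernel = weights.kernel()
    x = np.where(values.nodata_mask, 0.0, values.values.astype(float))
    valid = (~values.nodata_mask).astype(float)
    num = ndimage.convolve(x, kernel, mode="constant", cval=0.0)
    cnt = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    return num, np.rint(cnt).astype(int)


def gi_ratio(values: RasterGrid, weights: GiWeights) -> RasterGrid:
    """The G_i ratio: neighbourhood sum over the global sum excluding i.

    Cells where the denominator is zero are set nodata with a warning.
    With all x >= 0 the ratio lies in [0, 1].
    """
    num, _ = _neighbour_sums(values, weights)
    x = np.where(values.nodata_mask, 0.0, values.values.astype(float))
    total = x.sum()
    denom = total - x
    zero = ~values.nodata_mask & (denom == 0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero G_i denominator set to nodata",
            stacklevel=2,
        )
    mask = values.nodata_mask | zero
    with np.errstate(divide="ignore", invalid="ignore"):
        g = num / denom
    g = np.where(mask, np.nan, g)
    return values.like(g, mask)


def gi_zscore(
    values: RasterGrid, weights: GiWeights
) -> tuple[RasterGrid, dict]:
    """Standardised G_i under the randomisation (permutation) hypothesis.

    Cells whose leave-one-out standard deviation is zero, or whose
    neighbourhood is empty or exhausts the data, get z = 0 and are counted
    in the ``n_degenerate`` diagnostic. Requires at least 3 valid cells.
    """
    valid = ~values.nodata_mask
    n = int(valid.sum())
    if n < 3:
        raise ValueError(f"gi_zscore needs >= 3 valid cells, got {n}")
    num, cnt = _neighbour_sums(values, weights)
    x = np.where(valid, values.values.astype(float), 0.0)
    S = x.sum()
    S2 = (x * x).sum()
    mean_i = (S - x) / (n - 1)  # leave-one-out mean
    var_i = (S2 - x * x) / (n - 1) - mean_i**2
    var_i = np.maximum(var_i, 0.0)
    s_i = np.sqrt(var_i)
    W = cnt.astype(float)
    scale2 = W * (n - 1 - W) / (n - 2)
    degen = valid & ((s_i == 0) | (scale2 <= 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (num - W * mean_i) / (s_i * np.sqrt(scale2))
    z = np.where(degen, 0.0, z)
    z = np.where(~valid, np.nan, z)
    n_degen = int(degen.sum())
    return values.like(z, values.nodata_mask.copy()), {
        "n_degenerate": n_degen,
        "n": n,
    }


def local_roughness(grid: RasterGrid) -> float:
    """Scale-free local variability of a surface.

    Mean squared difference between rook-adjacent valid cells, divided by
    twice the field variance (the variogram at lag one over the sill; one
    minus the neighbour correlation). Near 0 for a smooth surface, near 1
    for spatial noise. This is the quantity that shrinks as the G_i lag
    distance grows: widening the distance band smooths the z map locally
    even though the marginal variance of z rises with the evidence
    accumulated over bigger neighbourhoods.
    """
    z = np.where(grid.nodata_mask, np.nan, grid.values.astype(float))
    var = np.nanvar(z)
    if not var > 0:
        return 0.0
    diffs = np.concatenate(
        [np.diff(z, axis=0).ravel() ** 2, np.diff(z, axis=1).ravel() ** 2]
    )
    return float(np.nanmean(diffs) / (2.0 * var))


@dataclass
class GiField:
    """G_i ratio and z-score surfaces at one lag distance."""

    gi: RasterGrid
    z: RasterGrid
    d: int
    radius_m: float
    neighbour_counts: np.ndarray
    n_degenerate: int


def hotspot_sweep(
    risk: "IndexLayer | RasterGrid", lags, metric: str = "euclidean",
    star: bool = False,
) -> list[GiField]:
    """One GiField per lag distance, from local to regional scale.

    ``risk`` may be a raster IndexLayer (classes are the analysed values)
    or any RasterGrid. An empty lag list is an error.
    """
    lags = list(lags)
    if not lags:
        raise ValueError("hotspot_sweep: empty lag list")
    if isinstance(risk, IndexLayer):
        if not risk.is_raster:
            raise ValueError("hotspot_sweep needs a raster index layer")
        grid = risk.carrier
        grid = grid.like(grid.values.astype(float), grid.nodata_mask)
    else:
        grid = risk
    fields = []
    for d in lags:
        w = build_weights(grid, d, metric=metric, star=star)
        g = gi_ratio(grid, w)
        z, diag = gi_zscore(grid, w)
        _, cnt = _neighbour_sums(grid, w)
        fields.append(
            GiField(
                gi=g,
                z=z,
                d=int(d),
                radius_m=w.radius_m,
                neighbour_counts=cnt,
                n_degenerate=diag["n_degenerate"],
            )
        )
    return fields
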