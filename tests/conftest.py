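import itertools

import numpy as np
import pytest

from heatscape import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def small_grid():
    vals = np.arange(1.0, 10.0).reshape(3, 3)
    return RasterGrid(vals, 60.0, (0.0, 180.0))


# ---------------------------------------------------------------------------
# Independent oracles (brute force / enumeration; never share code with the
# implementations they check)
# ---------------------------------------------------------------------------

def exhaustive_jenks_ssd(values, k):
    """Minimum within-class SSD over ALL contiguous partitions of the sorted
    values into k classes, by direct enumeration of cut positions."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def ssd(seg):
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    best_parts = None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(ssd(v[bounds[i]: bounds[i + 1]]) for i in range(k))
        if total < best - 1e-12:
            best = total
            best_parts = [v[bounds[i]: bounds[i + 1]] for i in range(k)]
    return best, best_parts


def brute_force_gi_ratio(values, mask, d, cell_size=1.0):
    """Literal double-loop evaluation of the G_i ratio with a Euclidean
    distance-band weight matrix (ones within d cells, zero diagonal)."""
    nrow, ncol = values.shape
    out = np.full((nrow, ncol), np.nan)
    cells = [(r, c) for r in range(nrow) for c in range(ncol) if not mask[r, c]]
    total = sum(values[r, c] for r, c in cells)
    for r, c in cells:
        num = 0.0
        for r2, c2 in cells:
            if (r2, c2) == (r, c):
                continue
            if (r - r2) ** 2 + (c - c2) ** 2 <= d * d:
                num += values[r2, c2]
        denom = total - values[r, c]
        out[r, c] = num / denom if denom != 0 else np.nan
    return out


def permutation_gi_z(values, d, n_perm, seed):
    """Conditional-permutation z-score for every cell of a full 2-D grid.

    For each cell i the neighbourhood sum under the randomisation
    hypothesis is the sum of W_i values drawn without replacement from the
    other n-1 values; the z is (observed - perm mean) / perm sd.
    """
    rng_ = np.random.default_rng(seed)
    nrow, ncol = values.shape
    flat = values.ravel()
    n = flat.size
    z = np.empty((nrow, ncol))
    for r in range(nrow):
        for c in range(ncol):
            i = r * ncol + c
            others = np.delete(flat, i)
            # count in-bounds neighbours within d
            W = 0
            obs = 0.0
            for r2 in range(nrow):
                for c2 in range(ncol):
                    if (r2, c2) == (r, c):
                        continue
                    if (r - r2) ** 2 + (c - c2) ** 2 <= d * d:
                        W += 1
                        obs += values[r2, c2]
            draws = np.empty(n_perm)
            tiled = np.tile(others, (n_perm, 1))
            perm = rng_.permuted(tiled, axis=1)[:, :W]
            draws = perm.sum(axis=1)
            z[r, c] = (obs - draws.mean()) / draws.std(ddof=0)
    return z
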