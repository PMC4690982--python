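# Methods

## Spatial frame

All coordinates are planar metres; files declaring geographic (degree)
units are rejected rather than silently misread. Rasters are north-up with
square cells; cell (r, c) covers the half-open square
[x₀+c·s, x₀+(c+1)·s) × (y₀−(r+1)·s, y₀−r·s], so every point belongs to
exactly one cell and point-in-cell assignment is unambiguous. Nodata is a
boolean mask in memory and a sentinel recorded in file metadata on disk;
masked cells are excluded from every statistic. Zones are valid, pairwise
interior-disjoint polygons with unique identifiers; areas are planar, in
km². These zones model census dissemination areas (~400–700 persons),
typically spanning tens of 60 m cells — the resolution mismatch that
motivates the frame comparison below.

## LST retrieval

At-sensor spectral radiance is corrected to surface blackbody radiance
with scene-level upwelling/downwelling path radiances L↑, L↓ and
transmittance τ (scalars, as delivered by an atmospheric-correction
service for a single acquisition; per-cell rasters would be a
straightforward extension) and a per-cell emissivity ε:

    B = (L_sen − L↑)/(ε·τ) − ((1−ε)/ε)·L↓ ,

then inverted through Planck's law for the sensor band,
LST = K₂ / ln(K₁/B + 1) (kelvin). K₁, K₂ are band calibration constants;
the defaults (607.76 W m⁻² sr⁻¹ µm⁻¹, 1260.56 K) are the Landsat 5 TM
band 6 handbook values and are configuration, not assertions — the physics
tests hold for arbitrary positive constants. Cells whose corrected
radiance is non-positive (radiance at or below the path contribution) are
masked and counted in a diagnostic rather than aborting the scene;
ε = 0 or τ = 0 is rejected up front. The package also provides the exact
forward model (T → radiance), so retrieval is verified as an inverse:
round trips recover temperature fields to < 10⁻⁶ K for any
ε ∈ (0.5, 1], τ ∈ (0.3, 1].

## Classification

Every index layer uses Jenks natural breaks: the partition of the sorted
values into k contiguous classes minimising total within-class sum of
squared deviations. The implementation is the exact Fisher dynamic
programme on the distinct values with multiplicity weights — O(k·m²) for m
distinct values — not the common iterative heuristic, so the optimum is
global, deterministic, and testable against exhaustive enumeration.
Argmin ties break toward the smaller start index. Class intervals are
half-open, (b_{i−1}, b_i] with the first closed below: a value equal to a
break belongs to the lower class. Values outside the training range clamp
to class 1 or k. Degenerate inputs (fewer distinct values than k) reduce k
with a warning, one class per distinct value. Breaks are always computed
on the full study-area distribution of non-nodata values, never per tile;
k defaults to 9. A quantile classifier is available for sensitivity
analysis only.

## Vulnerability and risk indices

The eight vulnerability variables are seven counts (seniors, infants,
pre-1970 housing households, multi-storey/mobile-home households, low
income, low education, living alone) and one rate (unemployment, %).
Counts are normalised to densities per km² of zone area; the rate passes
through. The density unit is cosmetic — Jenks classes are invariant under
positive rescaling — but is documented for reproducibility. Each density
surface is classified 1..9, the classes are averaged with equal weights
(1/8 each), and the composite is re-classified 1..9. Equal weights are
the default at both stages because no calibration data (e.g. geocoded
heat mortality) exist to justify others; both weight vectors live in the
YAML config. Per-variable breaks are computed on the zone domain by
default (one value per zone); a `breaks_domain="cells"` option computes
them after rasterisation, where values are duplicated in proportion to
zone size and break positions shift — the choice is recorded in output
metadata. Risk combines the exposure and vulnerability class layers 50/50
and re-classifies by Jenks (quantile behind a flag). The weighted average
treats ordinal classes as interval data; that ordinal-as-interval step is
standard weighted-overlay MCA and is an explicit assumption here.

## Raster and vector frames

Zone→cell resampling takes, for each cell, the attribute of the zone
containing the cell centre; cell→zone aggregation takes the mean of the
non-nodata cells whose centres fall inside the polygon. Cell-centre
containment is used in both directions (not area-weighted overlap) so the
operations are exact duals: when zones coincide with single cells the two
pipelines produce bit-for-bit identical risk maps, which is tested.
Area-weighted zonal means are deliberately out of the default path; the
equivalence property would otherwise hold only approximately. Cell
centres landing exactly on a shared boundary are assigned to the zone
whose id sorts first, deterministically, and counted. Zonal means use a
constant-zone shortcut (when a zone's cells all carry one value, the mean
is that value) so that aggregating a freshly rasterised attribute returns
it exactly, with no summation rounding. Cells outside every zone are
masked; zones containing no cell centre get a missing value and a
warning. In the raster pipeline the finished zone composite is resampled
to cells and the final risk re-classification runs on the cell domain; in
the vector pipeline LST is averaged into zones and everything runs on the
zone domain.

## Getis-Ord G_i

Neighbourhoods are binary distance bands on the cell lattice: all offsets
with Euclidean length ≤ d cells, origin excluded (4 rook neighbours at
d = 1, 48 offsets at d = 4; Chebyshev available behind a flag). The G_i
ratio is the printed statistic, Σ_j w_ij x_j / Σ_{j≠i} x_j, evaluated by
convolution and verified against a literal double loop. Hotspot maps use
the standardised form under the randomisation hypothesis: conditioning on
x_i, the neighbourhood sum is a sum of W_i draws without replacement from
the remaining n−1 values, giving

    z_i = (Σ_j w_ij x_j − W_i·x̄₍ᵢ₎) / (s₍ᵢ₎·√(W_i(n−1−W_i)/(n−2))),

with x̄₍ᵢ₎, s₍ᵢ₎ the leave-one-out mean and standard deviation. Edges are
handled by truncation (W_i is the in-bounds, non-nodata neighbour count;
no wrap-around); the global sums run over all valid cells. Cells with
zero leave-one-out variance or empty/exhaustive neighbourhoods get z = 0
and are counted as degenerate; fewer than three valid cells is an error.
The analytic z agrees with a 20,000-draw conditional permutation test to
within Monte-Carlo error, and on iid Gaussian fields the upper 1.96 tail
holds 2.5 % within sampling error. The self-inclusive G_i* neighbourhood
is available as an option for the ratio; its moments are not adjusted, so
standardised output should use the default self-excluded form.

### Multi-scale smoothing

Sweeping d from 1 to 4 cells (radii d × cell size; 60–240 m at 60 m
cells) moves the z map from local to regional structure. Smoothing is
quantified as local roughness: the mean squared difference between
rook-adjacent z values over twice the field variance (the lag-one
variogram over the sill). Roughness decreases monotonically in d on every
tested surface — the maps get locally smoother — while the *marginal*
variance of z grows with d, since a wider band accumulates more evidence
for large coherent clusters and pushes their z further from zero. Both
facts are measured; "smoother at larger lags" here means the roughness
statement, which is asserted across the synthetic suite (an empirical
regularity, not a theorem).

## Synthetic scenes

The generator emulates the structure of a thermal-satellite heat study:
T(x) = background + Σ islands a·exp(−|x−c|²/2r²) + N(0, σ²) with
forward-modelled at-sensor radiance (so retrieval is exercised end to
end); zones as Voronoi cells of uniform random points clipped to the
extent (mirror-point construction, exact tessellation); vulnerability
counts as negative binomial draws with zone rate
λ_z = density·area_z·exp(β·T̄_z^std + γ·u_z), where u is a shared
zone-level Gaussian factor with exponential spatial correlation over zone
centroids, and the unemployment rate as a scaled Beta. Defaults: 80×80
cells of 60 m, 295 K background, two islands (+8 K / +6 K, 500–700 m
radii), 0.4 K noise, 150 zones (median zone ≈ 40 cells), dispersion 5
(overdispersion comparable to census tallies; Poisson is the r → ∞
limit), β = 0.6, γ = 0.4, correlation range 1 km, unemployment mean ≈ 6 %.
Everything is deterministic under the scene seed.

What the generator does *not* emulate: street-scale urban morphology,
spatially varying emissivity classes, census suppression artefacts,
irregular non-convex administrative boundaries, or water masks. Passing
tests therefore demonstrate correctness of the algorithms and the
frame-comparison logic, not fidelity of any particular city's risk map.

A constructed "lake scene" (16 square zones on a 12×12 grid; one zone
two-thirds cold lake at 288 K, one-third hot dwellings at 313 K) makes
the zoning effect concrete: the vector frame averages the zone to ~296 K
and assigns a low exposure class, while the raster frame keeps the
dwelling cells in the top class. The strict inequality between the two is
a regression test.

## Numerical and design choices

- Jenks DP runs on distinct values with multiplicity weights, which also
  guarantees strictly increasing break values.
- Raster I/O stores georeferencing (cell size, origin, nodata sentinel,
  units) as JSON in the TIFF ImageDescription tag; arrays round-trip in
  their native dtype bit-exactly. Vector I/O is GeoJSON plus a CSV
  attribute table joined on `zone_id` (inner join; orphans warned).
- Tessellation validation tolerates shared boundaries but rejects
  interior overlaps above a 10⁻⁹ relative-area tolerance.
- The z-score denominator guard (degenerate → z = 0, flagged) keeps
  constant fields and isolated cells from producing infinities.
- Problem sizes in the test suite and acceptance script (8×8 oracle
  grids, 200 null fields of 40×40, 20 six-cell-square equivalence scenes)
  are chosen so each independent oracle — exhaustive enumeration,
  double-loop evaluation, 20,000-draw permutation — runs in seconds while
  still covering every code path end to end.

## Known limitations

- No CRS handling or reprojection: inputs must already share a projected
  metric frame.
- ESRI Shapefile is not read; use GeoJSON.
- The vector pipeline inherits any census-zone artefacts wholesale; no
  dasymetric refinement is attempted.
- G_i p-values are per-cell; no multiple-testing correction across cells
  is applied, so hotspot maps are exploratory, not inferential.
- Weights are global; spatially varying vulnerability weights would need
  calibration data the method deliberately does not assume.
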