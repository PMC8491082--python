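# Methods

This note records the models, parameter choices, and numerical decisions
behind `canopylidar`, and what its synthetic-field tests do and do not show
about real LiDAR data.

## Coordinate and unit conventions

Point clouds carry metric metres with z up; no geographic projection is
used, because every stage needs only relative geometry.  After height
normalization, ground points carry z = 0 exactly and above-ground points
carry height in centimetres (the cloud's `z_unit` records which convention
it is in, which also makes normalization idempotent).  Rasters use
row 0 = northern edge, 0-based pixels, pixel centres at half-integer geo
offsets; the geo→pixel map is affine and exact to the 0.5-pixel
quantization.  LAS classification codes follow the LAS convention:
2 ground, 5 above-ground vegetation, 7 outlier.

## Statistical outlier removal

A point is an outlier when the mean distance to its `n_neighbors` nearest
neighbours exceeds avg + k·std, where avg/std are taken over all per-point
means.  Defaults are 50 neighbours and k = 1, the convention of the
classical filter.  Two properties matter in practice:

* With k = 1 the rule always trims the sparsest ~10–15% tail of a
  homogeneous cloud; that is intended behaviour, not a defect.
* The neighbour count is a proxy for a physical neighbourhood radius,
  r ≈ sqrt(n/(π·density)).  Fifty neighbours at a field-scan density of
  ~15,000 points/m² is a ~3 cm neighbourhood; at a sparser cloud the same
  count inflates the radius and with it the band of plot-edge points whose
  neighbourhoods are half-empty and hence get flagged, visibly eroding plot
  edges.  `DenoiseParams.for_density` scales the count to keep the radius
  fixed; analyses of down-sampled or synthetic clouds should use it.

## Ground classification and terrain flattening

The filter seeds the terrain with the lowest point of each `radius`-sized
grid cell (default 2 m), discards seeds rising faster than `max_slope_deg`
above their cell neighbourhood, interpolates a provisional ground surface
from seed-cell centroids (linear TIN inside the centroid hull, a
least-squares plane beyond it, so a uniformly sloped field extrapolates
correctly at its margins), takes points within `height_threshold`
(default 10 cm) of the surface as ground, and re-estimates once.  The
contract is label accuracy against synthetic truth (≥99% on bare and
canopied test terrains, ≤2 cm RMSE on recovered plot heights), not
bit-equality with any published filter.  `height_threshold` must stay below
the shortest canopy of interest; 10 cm is safe for cereals past stem
elongation.

## TIN interpolation and the canopy height model

Rasters are piecewise-linear interpolations over the Delaunay triangulation
of the points, sampled at cell centres; cells outside the hull are no-data.
Progressive densification — iteratively inserting points that take their
interpolated value — cannot change any cell, by linearity, so a single
triangulation already satisfies a 0.5 cm convergence rule and is what the
implementation computes.  A `max_edge` mask (default 0.2 m) removes cells
whose containing triangle has a long edge; without it the TIN would bridge
the 30 cm inter-plot gaps and erase them from the CHM.  The CHM default
resolution is 1 cm/pixel, and grayscale encoding is linear with 0 cm black
and 160 cm white, round-half-up, clamped (canopies above 160 cm saturate
rather than error).  No-data encodes as 0; a validity mask is carried on
the raster object.

## Plot segmentation

The canopy mask combines a global Otsu threshold OR a local Sauvola
threshold; the local arm is gated on local contrast (window std > 2
intensity levels) because on a constant region Sauvola's threshold sits
just below the region's own level and would admit flat background
wholesale.  Holes smaller than one gap-width square (900 px² at 1 cm/px)
and specks below 64 px are cleaned: both are smaller than any real plot or
gap feature, and their edges would otherwise pollute line detection.

Lines are found per orientation with Sobel edges and a Hough transform
restricted to ±2° of the axis (the CHM is aligned first).  Two robustness
measures: the mask is smoothed *along* the candidate line direction before
edge detection, so a boundary that wiggles a few pixels still concentrates
its votes; and each Hough peak is canonicalized to its crossing of the
image centre line, since a slightly tilted peak's ρ is offset by up to
centre·sin θ.  Peaks must collect `min_line_votes` (default 0.3) of the
spanned dimension.  Lines within `merge_distance` (default 35 px: the 30 px
gap plus the ~2 px Sobel response on each side) merge at their vote-weighted
mean.  Where no line is detected near the mask content extent, a
field-boundary line is inserted there, because a plot flush with the raster
border has no gap edge to detect.

Plot rectangles are cells of the merged-line lattice, with two refinements:
lattice slabs whose best cell holds under 40% canopy are classified as gap
slivers and dropped (so the plot count does not depend on perfect
pair-merging of gap edges), and each surviving cell snaps to the occupancy
profile of the mask inside it (threshold 0.5 along each axis), recovering
the plot edge rather than the gap centre.  On clean synthetic trial blocks
this recovers all 162 plots with every boundary within 3 px of truth.  A
supplied row × column layout replaces a deficient orientation with evenly
spaced baselines and guarantees the plot count.  Sampling windows shrink
each plot by 10% per side and re-centre at the entropy-weighted centroid
(window 9 px), falling back to the geometric centre for uniform or empty
plots.

## Traits

* **Height** H₁₀: mean of the highest ceil(0.10·n) point heights; ties at
  the cutoff resolve deterministically by sort order.
* **Coverage**: the highest 50% of points project onto a 5 cm occupancy
  grid over the plot footprint; isolated empty cells are closed
  (morphological closing plus removal of holes ≤ 8 cells) and coverage is
  the occupied fraction.  Occupancy-based, hence invariant to uniform
  density changes once cells saturate.
* **3D surface area**: points are voxelized (5 cm), down-sampled, and the
  *corner* points of occupied voxels are meshed with an alpha shape
  (α = 2 × voxel size).  Corners rather than centres give a flat canopy its
  physical one-voxel thickness: the centre set of a smooth canopy is
  coplanar, on which a 3D alpha shape is degenerate, while the corner slab
  closes to top + bottom + rim.  The alpha complex keeps Delaunay
  tetrahedra with circumradius ≤ α; zero-volume slivers (abundant in
  gridded point sets) use the half-longest-edge bound of their minimum
  enclosing ball instead of the unbounded circumsphere, so interior slivers
  do not punch spurious boundary faces.  The mesh is the set of faces
  belonging to exactly one kept tetrahedron.  The normalized surface index
  divides by the per-run maximum across plots (the only self-contained
  cohort; configurable).
* **3DVI / 3DPI**: occupied-voxel fraction of the plot bounding volume,
  and the sum over 5 cm height bins of per-bin occupied-cell fractions.
  These are declared occupancy definitions, not reconstructions of any
  prior instrument-specific variant.

## Spectral canopy-structure index

The plot CHM image is transformed with a forward 2D DFT; log(1 + |F|) with
the DC component shifted to the centre is the spectrogram.  Amplitudes are
sampled along the main diagonal through the centre at integer steps on
[−100, 100] (201 samples; a plot too small to host the span is linearly
resampled onto it, keeping the integration domain fixed across plot
sizes).  Sampling uses the log-magnitude *before* its 0–255 display
rescale: the rescale maps each plot's own extremes to the full range and
therefore erases exactly the cross-plot amplitude differences the index
accumulates — with rescaled amplitudes the index *decreases* as canopy
height variance grows, the opposite of its meaning.  A Gaussian
A·exp(−(x−μ)²/2σ²) is least-squares fitted (initialized at the peak,
σ₀ = span/8, bounds keeping σ > 0); degenerate or failed fits are flagged
and the raw curve retained.  The area under the fitted curve is the
trapezoidal sum over the span (exact for constant and linear integrands,
within 1e-3 of the Gaussian's error-function closed form at σ = 20).
Curvature uses the parametric formula |x′y″ − x″y′|/(x′²+y′²)^{3/2} with
single-step central differences (the one-step Laplacian keeps the apex
second derivative second-order accurate), reported at the curve apex,
where it equals A/σ² analytically.  Cohort normalization stretches the
band to 0.593·min and 1.294·max, so every value is strictly inside (0, 1);
it is invariant to positive scaling of the cohort.  The default cohort is
all plots of one run; studies comparing a variety across treatments should
normalize within that variety's plots.

## N-response classification and performance matrix

With d = (3DCI at low, medium, high N) and tolerance τ (default 0.02):
Class 1 if all pairwise gaps exceed τ and d decreases; Class 2 if low and
medium agree within τ and high drops below medium − τ; Class 3 if medium
and high agree within τ and medium drops below low − τ; Class 4 if medium
is the minimum and high rises above medium + τ; otherwise unclassified.
τ is a free parameter because the class definitions are qualitative.

The performance matrix computes each trait's percentage deviation from the
trimmed mean (10% per tail by default), banded lower-inclusive /
upper-exclusive: ≥15% → 5, [7.5, 15) → 4, [−7.5, 7.5) → 3, [−15, −7.5) → 2,
else 1.  Height is penalized symmetrically (|dev| ≤ 7.5 → 3, ≤ 15 → 2,
else 1): both very short and very tall are undesirable.  Ranks combine with
weights GN 0.25, SN 0.25, 3DCI 0.2, surface 0.2, height 0.1 (yield
components weighted most; the mapping is configurable since only the
weight vector, not its order, is canonical).

## The synthetic fields

`synthfield` emulates a drilled plot trial: plots (default 2 × 3 m, 30 cm
gaps) on a terrain with linear slopes and Gaussian roughness; canopy points
are a mixture of drill-row scatter (6 rows at 15 cm, giving the CHM the
stripe periodicity the spectral stage detects; row tops sit 8 cm above the
inter-row canopy) and a uniform canopy-closure component over the full
rectangle (the closed canopy of a heading-stage crop — without it the plot
boundary would be undetectable, since the drill rows alone span only
0.75 m of a 2 m plot).  Spike-scale texture is per-point Gaussian height
jitter (`height_sd`), the single dial the index-monotonicity tests turn.
Ground returns cover the whole field.  Ground truth (mean height, H₁₀,
occupancy coverage, plot corners) is recomputed from the generated points.

Default densities are 1,500 canopy points/m² and 800 ground points/m² —
an order below a real field scan (~90,000 points per 6 m² plot), chosen so
the whole trial block runs in seconds while every occupancy-based trait
still saturates; the trait definitions themselves are density-invariant.
Not emulated: intensity/radiometry, multi-return physics, wind motion,
occlusion, lodging geometry, and the scanner's distance-dependent density
falloff.  Consequently, passing tests demonstrate the correctness of the
algorithms and their contracts, and the recoverability of known structure;
they do not calibrate accuracy against real vegetation.

## Problem sizes

The test suite and the acceptance script run trial blocks of 162 plots
(9 × 18) at the densities above (~2.5 million points per block); a block
takes well under two minutes on one CPU through segmentation.  Single-plot
analyses (spectral index, traits) use 9,000-point plots.
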