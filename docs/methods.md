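# Methods

## The model

A closed planar contour is represented as a simple closed polyline of N
vertices; vertex i sits at parameter t = i/N on the circle R/Z, evaluation
between vertices is piecewise linear, and the y-axis points up.  Two contours
describe the same *oriented shape* when one is a translation, rotation,
scaling, cyclic roll, or orientation-preserving reparameterization of the
other.  The package turns each orbit under this symmetry group into a single
canonical representative, in two stages.

**Finite-dimensional normalization.**  Five steps applied in a fixed order:

1. *direction* — make the signed (shoelace) area positive, i.e. travel
   counterclockwise; clockwise inputs are reversed keeping vertex 0.
2. *start* — roll the vertex list so vertex 0 is the distinguished start
   point (the leaf tip).
3. *scale* — rescale to unit perimeter (default) or unit enclosed area.
   Unit perimeter separates leaf varieties better; unit area is insensitive
   to peduncles, which add length but almost no area.
4. *position* — translate a designated center to the origin: the start
   vertex, the arc-length-weighted boundary centroid, or (default) the
   centroid of the enclosed region.
5. *rotation* — either align the principal axes of the arc-length-weighted
   boundary covariance (minor axis horizontal), or (default) rotate about the
   area centroid so the segment from the centroid to the start vertex points
   along +y.

A subtlety arises when the start rule "vertex with largest vertical
component" is combined with the tip-vertical rotation: the max-y vertex of an
arbitrarily rotated input is arbitrary, so a literal single pass is neither
idempotent nor rotation-invariant, and iterating it converges to
rotation-dependent local fixed points.  The composition has exactly one
stable, rotation-invariant fixed point: the start vertex farthest from the
area centroid (once it points up, every other height is bounded by its
centroid distance, so it is also the max-y vertex and the max-vertical
postcondition holds).  `normalize` therefore selects that vertex directly
when both defaults are enabled, and iterates the step composition to its
fixed point in all configurations.  Consequence: shapes whose two
farthest-from-centroid candidates are nearly tied (near-symmetric outlines)
have an unstable canonical pose; this is a property of the normalization
family, not of the implementation.

**Canonical reparameterization.**  The remaining infinite-dimensional factor
(reparameterizations fixing the start point) is removed by the 2-parameter
family of curvature-weighted clock parameterizations s_{λ,n}:

* The sampling density along the curve is proportional to
  `λ·Length + |κ|`, where κ is the discrete signed curvature (exterior
  turning angle at a vertex divided by the mean of the two adjacent edge
  lengths — this makes the total discrete turning exactly 2π).  λ = ∞ (an
  explicit symbolic value) is the constant-speed parameterization; λ = 0
  keeps only the curvature term, giving a weakly monotone map whose plateaus
  cover flat pieces exactly (they receive no samples; plateaus are inverted
  to their left edge); λ multiplies the total length so the map is invariant
  under uniform scaling.
* With n ≥ 2 clock subdivisions, the contour is cut at the n parameters
  where the unwrapped winding angle about an interior reference point first
  crosses the multiples of 2π/n; each angular sector receives ⌊N/n⌋ samples
  (the first N mod n sectors one extra, keypoints included as sector
  leaders), distributed within the sector by the curvature-weighted rule.
  The winding angle is accumulated continuously (first *upward* crossing of
  the unwrapped angle), which extends the construction to contours whose raw
  angle function is locally non-monotone.

The reference point is the area centroid when it is strictly interior;
otherwise a deterministic fallback is used — by default the interior Voronoi
vertex of the contour vertices nearest the centroid, alternatively the
nearest interior centroid of triangles anchored at the boundary point closest
to the centroid.  Both are hyperparameter-free; step-size-based alternatives
were deliberately not implemented.

`project = normalize ∘ canonical_resample` is idempotent and depends only on
the oriented shape, up to discretization error (measured: ≤ 1e-2 relative L2
at N = 1000 under random similarity transforms, flips, rolls and
reparameterizations for the default section).

## Distance and validity indices

On canonical representatives with a common N the shape distance is the
discrete L2(S¹) norm `d(a,b) = sqrt(mean_j ||a_j − b_j||²)`.  The uniform
1/N quadrature weight reflects that canonical representatives are uniform in
the section's parameter, and makes the distance between concentric
uniformly-sampled circles exactly |r1 − r2|; any other fixed positive weight
would rescale all distances uniformly and leave both validity indices
unchanged.  The distance is a true metric (symmetric, non-degenerate,
triangle inequality) because it is a norm restricted to the section's range.

Cluster validity uses the centroid convention: the inter-class distance is
the distance between vertex-wise mean shapes, the intra-class diameter the
maximum pairwise distance within a class.  The Dunn index is (min inter) /
(max diameter), higher is better; Davies–Bouldin averages over classes the
worst ratio (spread_k + spread_k′) / centroid distance, where a spread is the
mean member-to-centroid distance, lower is better.  All-singleton classes
raise an error for Dunn (rather than returning ∞, which would poison grid
search); coincident centroids raise for Davies–Bouldin.  Extreme-pair
diagnostics (the most distant same-class pair, the closest cross-class pair)
break ties lexicographically.

## Metric learning

`grid_search` evaluates the index over a grid of (n, λ) cells — defaults
λ ∈ {0.5, 1, 2, 5, 10, 100, 1000, 2000, ∞} and n ∈ {0, 2, 3, 4, 5, 7, 9, 10,
20} — averaging over repeated seeded stratified training subsamples (default
fraction 2/3, matching a 50-train / 25-test per-class protocol).  Disjoint
k-fold partitioning would cap the usable fold count at the class size, so
repeated subsampling was chosen; the subsamples are drawn once and shared
across cells, making the whole grid a pure function of (dataset, grids,
folds, seed, config).  Cells whose index is undefined on some fold are NaN
and excluded from the best-cell selection.

`knn_evaluate` implements the distance-matrix k-nearest-neighbors rule
(majority vote; ties by smaller mean distance, then smaller label), which
exercises the section distance directly.  Feature-based classifiers (SVM and
the like on flattened canonical coordinates) are intentionally out of scope.

`orientation_bias_report` summarizes, per class, the circular distribution of
the tip direction (centroid → vertex 0, measured from vertical): a resultant
length near 1 across many classes indicates a dataset-level alignment bias
that would let a classifier cheat on orientation; applying random rotations
(`nuisance_transform`) removes it.

## Synthetic study conditions

The generator produces radial-Fourier outlines r(θ) = 1 + Σ a_k cos(kθ + φ_k)
(star-shaped about the origin, hence simple whenever r > 0), evaluated on a
dense grid and resampled to roughly constant speed so that thin features are
adequately represented.  A peduncle is a narrow Gaussian radial bump (default
widths ≈ 0.035 rad): it adds substantial boundary length and curvature while
contributing < 2% of the enclosed area, reproducing the length-vs-area
normalization trade-off seen in real leaves.  The five default classes (two
with peduncles, one with a pointed drip tip) use per-sample amplitude jitter
of 0.02 and 10 samples per class by default.  Each class was designed with a
single dominant tip: a first harmonic alone is nearly a *translated* circle
(limaçon), which leaves the farthest-from-centroid vertex nearly tied across
bumps and the canonical pose unstable, so classes use genuinely elongating
harmonics or an explicit tip bump.

Nuisance transforms draw from named, independent seeded streams: rotation
uniform on [0, 2π), translation uniform in [−2, 2]², scale log-uniform in
[1/2, 2], a fair-coin orientation flip, a uniform cyclic roll, and a random
monotone reparameterization (normalized cumulative softplus of 64 Gaussian
increments).  A dedicated crescent builder (thin annular arc) provides the
exterior-centroid case for the reference-point fallback.

What the generator does *not* emulate: pixelation and segmentation noise of
real image boundaries, within-class structural variation beyond harmonic
jitter (e.g. presence/absence of a peduncle inside one class), texture and
vein features.  Passing tests therefore demonstrate the correctness and
invariance of the pipeline, not classification performance on any real
dataset.

## Numerical choices

* All integrals (length, centroids, cumulative densities) use exact per-edge
  formulas or the composite trapezoid rule on the polyline; no splines.
* Parameter maps are inverted by monotone piecewise-linear interpolation with
  left-most preimages on plateaus; evaluation snaps parameters within 1e-9 of
  a vertex so that identity maps reproduce inputs bit-exactly.
* Clock resampling works on a constant-speed copy at max(4N, 2048) samples;
  keypoint crossings are linearly interpolated on that grid.
* The approximating ellipse uses boundary (not region) moments: the
  arc-length-weighted covariance of edge midpoints; its half-turn ambiguity
  is fixed by the farthest boundary point (non-negative y, then x).  Equal
  principal moments raise an error.
* Mask boundaries are traced by marching squares at level 0.5 after a 1-pixel
  Gaussian pre-filter; on binary data the raw iso-contour overestimates a
  disk's perimeter by ≈ 7% (staircase bias), ≈ 0.4% after smoothing.
* Problem sizes: invariance checks run 50 shapes at N = 1000; grid-search and
  kNN checks use N = 300 with 5 classes.

## Known limitations

* Clock sections (n ≥ 2) are ill-conditioned on shapes with long radial
  spikes: the winding angle is nearly flat along a spike, so a keypoint that
  lands there moves freely along the spike under tiny perturbations of the
  contour (observed ≈ 5e-2 relative L2 under nuisance transforms on peduncle
  classes, independent of grid resolution).  The default constant-speed
  section does not suffer from this.
* λ = 0 with clock subdivisions can collapse a sector that is entirely flat
  (all its samples coincide); this raises an invalid-contour error rather
  than silently degenerating.
* Near-symmetric contours have unstable canonical poses (tie-breaking in the
  tip rule), an intrinsic property of any deterministic section of this kind.
* The normalization assumes a nonzero enclosed area and (for clock sections)
  an interior reference point reachable by the fallbacks; pathological
  space-filling outlines are out of scope.
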