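# Methods

This note documents the statistical model behind murimorph, the defaults
and why they were chosen, the synthetic study conditions, and the numerical
decisions a maintainer would want on record.

## Superimposition

Configurations are centered, scaled to unit centroid size, and rotated
(proper rotations only, determinant +1; antimeres must be mirrored
explicitly upstream with `apply_reflection`) onto an evolving consensus.
The consensus is the normalized mean of the aligned set; iteration stops
when the change in summed squared residuals falls below `tol = 1e-10`
(`max_iter = 100`; non-convergence is flagged on the result, not raised).
The first alignment target is the first specimen; the final consensus is
rotated so its longitudinal-axis chord (landmarks 8→16) points along +x,
which fixes the sign/orientation indeterminacy of all downstream axes.
Aligned pre-shapes z are orthogonally projected to the tangent plane at the
consensus μ, v = z − (z·μ)μ. Because μ is the normalized mean of the final
aligned set, tangent rows sum to zero exactly (to the convergence
tolerance), and Euclidean distances among rows agree with pairwise full
Procrustes distances to first order — to better than 1e-6 in the near-mean
noise regime the test suite pins.

## Sliding semilandmarks

The tangent direction at each semilandmark is the chord through its two
outline neighbors; the outline itself is the piecewise-linear polygon
through all 16 points (the digitized curve is never available, so a more
elaborate curve model would be invented structure). Per specimen, slide
amounts minimize the quadratic form of the consensus bending-energy matrix
applied to the x- and y-displacement fields (minimum bending energy); a
closed-form generalized-least-squares solve gives the slides, with a ridge
applied only if the slide system is near-singular (collinear tangent
directions). Setting the energy matrix to the identity reproduces the
minimum-Procrustes-distance criterion exactly, which is how that criterion
is implemented. Slides are clamped to half the distance to the nearer
neighbor per pass to prevent point crossing, and slid points are
re-projected onto the two outline segments adjacent to their original
position. The slide → re-GPA → new-tangents loop runs at most 5 times or
until the consensus moves less than 1e-8; whether the original protocol
iterated or slid once is not determinable, so both are supported
(iterated by default, `max_outer_iterations=1` for a single pass).

## Shape variables

The thin-plate-spline bending-energy matrix is the upper-left k×k block of
the inverted augmented system built from U(r) = r² log r²; it is symmetric
PSD with exactly three zero eigenvalues (the 2D affine kernel), checked at
rank k−3 = 13 for the 16-point scheme. Eigenvalues below 1e-10 of the
largest are treated as affine. Partial-warp scores are projections of the
tangent residuals on each nonzero eigenvector (an x- and a y-score per
warp), weighted by λ^(−α/2) with α = 0 throughout; the uniform component is
the orthonormal basis of the affine complement of the non-uniform subspace
within the tangent space. Because the TPS reference is the GPA consensus,
the non-uniform basis lies inside the tangent space, so at α = 0 the full
28-column score matrix is an exact isometry of tangent space — the
relative-warps equivalence (identical PCA eigenvalues from scores and from
tangent coordinates) is the module's master invariant, and it makes every
downstream distance statistic independent of the uniform-component variant
chosen. Eigenvector signs follow the largest-magnitude-component-positive
convention for run-to-run reproducibility.

## Morphospace statistics

PCA is an eigendecomposition of the covariance matrix (not correlations:
the scaling of the shape variables is meaningful). Distances between
species means and from the basal species use the smallest set of leading
PCs whose cumulative variance exceeds 95% (override: fix `n_pcs`).
Percent shape change anchors the basal group at 0% and the most derived
(or a configured reference) group at 100%.

Confidence intervals are bias-corrected and accelerated bootstrap
intervals: the resampling unit is the specimen, stratified within groups;
z₀ comes from the bootstrap fraction below the observed statistic,
acceleration from leave-one-out jackknife skewness within strata, and a
degenerate bootstrap distribution yields a zero-width interval with a
warning. The implementation is vectorized for axis-aware statistics and is
cross-checked against scipy's BCa in the tests; its measured coverage for
a normal mean at n = 30 is ≈94%, indistinguishable from the reference
implementation (small-sample undercoverage is a property of BCa, not of
this code). For distance statistics near zero the bias correction can push
both percentiles past the (chi-like, upward-biased) observed value, so the
reported divergence tables widen the interval minimally to bracket the
point estimate. Two CIs are compared by the rule of eye: significant at
p ≤ 0.05 when they overlap by less than half the mean of their
half-widths.

Concentration ellipses at level 0.55 scale the covariance eigenvectors by
√q with q = χ²₂(0.55) = −2 ln 0.45 ≈ 1.59702. Overlap between coexisting
species is intersection-over-union of the ellipses on PC1/PC2, computed on
720-vertex polygons (area error < 0.01%, versus image-based area
measurement this is exactly defined); for three species it is the area
covered by more than one ellipse over the union of all three.

## Association and allometry

Two-block PLS takes the SVD of the between-block correlation matrix
(the documented protocol; covariance mode is available because shape-block
conventions differ between programs — with a univariate second block the
two modes give the same single axis and the same r). Permutation tests
shuffle rows of the second block and report p = (1 + exceedances)/(1 +
n_perm), never zero. The allometric regression fits each shape variable on
ln CS; percent variance predicted is 100·tr(SSCP_pred)/tr(SSCP_total), and
Wilks' Λ = det(E)/det(E+H) with the exact single-predictor F transform,
computed on the leading min(n−2, p) shape PCs when the shape block is rank
deficient (flagged on the result). Λ and its p-value are cross-checked
against statsmodels MANOVA; PLS axes against scikit-learn's PLSSVD.

## Synthetic study conditions

The generator is the package's ground truth, not a fixture. The template
is a hand-specified stylized convex molar outline (no published
coordinates exist to trace): 16 points on a 1.0 × 0.65 ellipse with fixed
radial modulation, a dense anterior arc carrying the nine semilandmarks,
axis landmarks 8 and 16 spanning the labial side, unit centroid size. All
tests are written to be template-independent.

The default two-clade scenario uses seven assemblage ages (13.8, 11.2,
10.5, 9.2, 8.2, 7.4, 6.5 Ma) with 25 specimens each plus a 25-specimen
basal population — sample sizes of the order of real assemblage pooling.
Each lineage drifts along its own unit tangent-space direction (the two
directions orthogonal) by a piecewise-linear distance schedule:

- leading clade: 0 → 0.009 → 0.021 → 0.081 → 0.095 → 0.105 → 0.120,
- lagging clade: 0 → 0.004 → 0.006 → 0.016 → 0.020 → 0.110 → 0.126.

Landmark noise is isotropic Gaussian at 1.5% of centroid size per
coordinate (within-assemblage scatter comparable to the planted effects).
These numbers were fixed by design arithmetic: early separations of
~0.7–1.5 within-group sd give broadly overlapping 55% ellipses; from
9.2 Ma the separation exceeds 5 sd so ellipse overlap is robustly zero;
the distance-from-basal gap inside the lag window (9.2–8.2 Ma) exceeds
2 sd of landmark noise so the rule of eye resolves it at n = 25, and the
lagging clade overshoots slightly after catch-up so "no longer below" is
unambiguous. A shared allometric direction (coefficient 0.03 shape units
per ln CS, ln CS sd 0.08, stronger size trend 0.06/Myr in the leading
clade) and a VD-like index coupled to the leading clade's direction at
ρ = 0.7 complete the structure. Specimens are emitted with random
rotation (±45°, keeping the axis-orientation convention well defined),
translation, and scale, so superimposition is genuinely exercised.

Two auxiliary scenarios plant single effects for recovery tests: an
allometry-only population whose coefficient is chosen analytically so the
allometric component is a stated fraction of expected tangent variance
(c = √(f/(1−f) · (2k−4)s²/Var(lnCS))), and a coupling-only population for
the PLS recovery band.

What the generator does **not** emulate: correlated landmark noise, wear-
stage dependence of the posterior outline, measurement error structure of
real digitization, phylogenetic covariance beyond the two-lineage mean
structure, and unequal sampling through time. Passing tests therefore
establish the correctness and calibration of the machinery and its power
to recover planted effects of realistic magnitude — not the fossil
results themselves, whose landmark data were never published.

## Problem sizes and runtime choices

The test suite and acceptance script scale resampling to the precision the
assertions need: bootstrap depth 999 and permutation depth 499–999 where
the quantity of interest is a coverage, a floor, or a stable pattern
(the 9999 default remains for real analyses); the coverage calibration
uses 10,000 Monte Carlo replications so its ~0.24-point standard error is
small against the ±2-point acceptance band. The grid-search sliding
oracle uses a 3-semilandmark toy scheme (41³ grid evaluations,
vectorized).

## Known limitations

- 2D curves only; no surface semilandmarks, no 3D.
- The outline for sliding re-projection is piecewise linear; with only 16
  points the re-projected position can differ slightly from a smooth-curve
  protocol.
- Wilks' Λ on rank-deficient shape blocks tests the retained-PC subspace,
  not the full block.
- BCa intervals inherit the method's small-sample undercoverage (~94% at
  n = 30 for a nominal 95%).
- The three-ellipse overlap definition (shared area over total area)
  matches the two-species intersection-over-union only in the
  one-overlapping-pair case it was designed for.
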