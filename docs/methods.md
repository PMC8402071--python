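# Methods

This note records the conventions, estimators and design choices behind
`berrymorph`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
establish.

## Coordinate and orientation conventions

Outline polygons live in a millimetre frame with y pointing up and are
counter-clockwise; rasterization flips y so image row 0 is the top of the
frame, and contour tracing flips it back. A berry is represented by two
views: the *horizontal* silhouette carries length L along image columns
and width W along rows; the *vertical* silhouette carries W along columns
and thickness T along rows. T is therefore recovered as the vertical
view's row extent — the extent perpendicular to the shared W axis. This
pairing is a convention of the package (two-view rigs rarely document it)
and is applied consistently by the generator and the measurement code.

## Synthetic silhouettes

Three outline families cover the shape vocabulary of table grapes:

- **ellipse** — x = (L/2)·cos t, y = (W/2)·sin t;
- **circle/sphere** — the degenerate case L = W (sphere-like varieties are
  generated as ellipses with nearly equal drawn L and W);
- **drop** — the ellipse half-width is modulated by 1 + asym·sin(t/2),
  asym ∈ [0, 0.6], which widens one end and tapers the other while the
  outline stays smooth and symmetric about the length axis. After
  modulation the polygon is rescaled so its bounding box is exactly
  (L, W) and recentred on its area centroid. asym = 0 reproduces the
  ellipse vertex-for-vertex. No published quantitative drop
  parameterization exists for grapes; this taper is the package's own
  choice, and 0.3 is used for the one drop-like variety of the built-in
  panel (a visible but moderate taper).

The vertical view is elliptical for *every* family, because the drop's
taper acts along the length axis and the W×T cross-section is orthogonal
to it.

Per-variety dimensions (L, W, T) are drawn from independent normals
truncated at ±3 SD (published per-variety min–max ranges are finite),
redrawn when nonpositive or when W > L. The built-in ten-variety panel
uses published dimension means/SDs of Anatolian table grapes with 40
berries per variety — 800 silhouettes — and family labels (4 sphere-like,
5 ellipse-like, 1 drop-like) assigned from the published shape
descriptions. The default raster scale is 0.05 mm/px (a 30 mm berry spans
~600 px, comparable to a DSLR frame at ~56 cm), with an 8 px background
margin so the foreground never touches the border. Rasterization fills
every pixel whose centre lies inside the polygon (even-odd scanline
rule).

What the generator does *not* emulate: boundary roughness, pedicel scars,
lighting/thresholding artifacts, partial occlusion, and within-berry
deviations from the ideal family geometry. Synthetic berries of one
variety differ only in (L, W, T); consequently shape-PCA variance shares
on synthetic panels are more extreme than on real berries (PC1 ≈ 99.6%
versus the mid-90s typical of real outline sets), and passing tests
establish correctness of the algorithms, not measurement performance on
real imagery.

## Trait measurement

PA is the foreground pixel count times scale²; ED = √(4·PA/π);
C = 4π·PA/P². The perimeter uses the Crofton-formula estimator
(`skimage.measure.perimeter_crofton`, 4 directions), which is close to
unbiased for smooth convex outlines: on a digitized disk of radius 200 px
it errs by −0.2%, whereas counting boundary steps with √2 diagonal
weights overestimates by ~5% and would cap circularity near 0.9 for a
perfect disk. (The chain-code length is still available via
`efd.chain_length`, with Kulpa's corrected weights 0.948/1.340 by
default.) L and W are the extents along/perpendicular to the silhouette's
principal axis, with one pixel of width added to each extent; on
generated panels the recovered (L, W, T) agree with the drawn truth
within 2 raster scales. Circularity of a digitized disk can slightly
exceed 1 (discretization); values up to 1.02 are considered valid.

Grayscale input images are binarized at a fixed threshold (128 of 255 by
default) when loaded from disk.

## Elliptic Fourier analysis

Contours are traced with Moore border following from the
topmost-leftmost foreground pixel, yielding a closed 8-connected Freeman
chain; the cycle terminates when the first directed edge repeats, and
the chain is reversed if the traversal came out clockwise in the
mm frame. Coefficients follow the Kuhl–Giardina closed-form integrals
over the piecewise-linear arc-length parametrization, with the DC term
as the exact curve centroid. The implementation is validated against an
independent brute-force Fourier quadrature (trapezoid rule on 10⁵
arc-length samples) to 1e-6.

Normalization uses the first-harmonic ellipse (the common default in
outline-morphometrics software): the parameter origin moves to the
semi-major axis (θ = ½·atan2(2(a₁b₁+c₁d₁), a₁²+c₁²−b₁²−d₁²)), the
ellipse is rotated onto the x-axis, and all coefficients are divided by
the semi-major amplitude, leaving a₁ = 1, b₁ = c₁ = 0 and d₁ the (signed)
first-harmonic aspect ratio — positive for counter-clockwise contours.
The residual 180° ambiguity (either end of the major axis is a valid
parameter origin; the two solutions differ exactly by negating every
even harmonic) is pinned by requiring the largest-magnitude
even-harmonic coefficient to be positive. This makes normalized
descriptors invariant under rotation, scaling, translation and cyclic
start-point shifts to machine precision, and the map idempotent. The
rule is unstable only for outlines whose even harmonics all vanish
(perfect ellipses), where the two branches coincide numerically anyway.
Mirror images are deliberately *not* identified — berries carry no
handedness convention.

Shape PCA is an eigendecomposition of the *covariance* matrix of the
flattened coefficient vectors with the constant columns (a₁, b₁, c₁)
excluded; components retained: min(n−1, 4N−3); eigenvector signs pinned
by forcing the largest-magnitude loading positive, making scores
bit-for-bit reproducible. Reconstruction at mean ± k·SD along a
component (k = ±2 in the panels) visualizes what the component encodes.

At 20 harmonics the chain → coefficients → reconstruction round trip
preserves the area of berry-like masks within 1% at scales ≤ 0.1 mm/px;
reconstruction error is nonincreasing in the harmonic count.

## Multivariate statistics

The canonical discriminant solver takes the min(p, g−1) leading roots of
the generalized eigenproblem B·v = λ·W·v (between- and within-group
scatter). Coefficients are scaled to unit pooled within-group variance
of the scores, canonical correlations are √(λ/(1+λ)), and the structure
matrix holds pooled within-group correlations of each variable with each
function; function signs are pinned by the largest structure
correlation. The within matrix is checked for singularity first, and the
error names the collinear or constant columns. Classification is
resubstitution (training-set) assignment to the nearest group centroid
by Mahalanobis distance on the all-group pooled covariance with equal
priors — the panel is balanced by design.

MANOVA statistics derive from the same eigenvalues: Wilks'
Λ = Π 1/(1+λᵢ) with Rao's F approximation, Pillai's V = Σ λᵢ/(1+λᵢ) with
its standard F approximation; hypothesis df is p(g−1) for both. The
identities Λ·Π(1+λᵢ) = 1 and V = Σ rᵢ² hold to 1e-12 and are tested.
Pairwise comparisons are Hotelling T² tests on the *two-group* pooled
covariance (the convention of common paleontological/ecological
packages), reported with squared Mahalanobis distances D² and Bonferroni
correction by g(g−1)/2; classification instead uses the all-group pooled
covariance (the convention of mainstream discriminant routines). Both
matrices are exposed. D² is affine-invariant and the reported values are
squared distances.

Duncan's multiple range test uses studentized-range critical points at
protection level 1−(1−α)^(k−1) for a span of k means and the harmonic
mean group size; letters come from the standard sweep over sorted means
with the containment rule. Exact tabulations in legacy statistical
packages may differ in the fourth decimal of the critical points. With
zero within-group variance the F statistic is reported infinite and
distinct means get distinct letters.

Variety centroids are clustered by UPGMA (between-group average linkage)
on Euclidean distances; merge heights are monotone, and the tree is
exported as Newick with branch lengths from the merge heights.

## Pipeline choices

- The discriminant step on traits uses the ten variables
  φ, Eh, P_h, PA_h, L, P_v, T, W, C_h, C_v. The remaining traits (ED, Dg,
  V, SA, Ev, PA_v) are deterministic functions of these and would make
  the pooled covariance singular, so they are excluded from the
  discriminant block (they remain in the trait tables).
- The elliptic Fourier step takes one orientation (default: horizontal,
  i.e. 400 of the 800 outlines); the orientation is a config field. The
  shape discriminant step uses the first 2 PCs by default.
- The dendrogram concatenates the trait-CDA and shape-CDA centroid
  coordinates unweighted. Discriminant scores have unit within-group
  variance per function, which gives the blocks comparable scales, but
  any weighting is legitimate — `cluster_centroids` accepts an arbitrary
  feature table. On the built-in panel the concatenated tree groups one
  large ellipse-like variety with the large sphere-like ones (size
  information dominates), while clustering the shape-CDA centroids alone
  separates the planted sphere/ellipse/drop families cleanly at a
  four-cluster cut; the family-recovery test therefore clusters shape
  features.
- Defaults follow standard practice for this analysis: 20 harmonics,
  α = 0.05, equal priors, resubstitution (not cross-validated)
  classification.
- All interchange is CSV; figures are PNG; a JSON manifest records the
  config, seed, library versions, record counts and stage timings. Runs
  are deterministic given the seed.

## Problem sizes

The validation suite runs its structural tests on small coarse panels
(three varieties × 8–12 berries at 0.2 mm/px) and one full-scale run of
the built-in panel (10 varieties × 40 berries × 2 orientations at
0.05 mm/px, ~35 s on one CPU), the size at which the acceptance metrics
(resubstitution accuracy, PC1 share, family recovery) are measured.

## Known limitations

- The Crofton perimeter is near-unbiased for smooth convex shapes but
  not guaranteed for rough or concave boundaries; circularity on real,
  noisy outlines will differ systematically from silhouette-perfect
  synthetic values.
- The drop taper is one of many plausible parameterizations; conclusions
  about drop-like berries transfer only qualitatively.
- Hotelling p-values assume multivariate normality with equal
  covariances; on derived traits (ratios, areas) this holds only
  approximately.
- Rao's F for Wilks' Λ is exact only for special (p, g) combinations;
  elsewhere it is the standard approximation.
- No reflection normalization: a mirrored outline is a different shape.
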