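# Methods

`dermastretch` measures in-surface skin stretch from multi-camera images of
an ink speckle pattern. This note documents the models and numerical choices
behind each stage, what the synthetic scenes do and do not emulate, and the
known limitations.

## Measurement model

A skin patch is represented by material coordinates (u, v) in mm on a flat
reference domain. A pose maps material points to 3-D positions; the optical
chain observes the speckle texture carried along with the surface. The
quantity of interest is the membrane deformation between a relaxed pose and
a target pose, expressed per triangle of a tracked mesh as:

- the in-plane deformation gradient `F` (2×2), solved from the two edge
  vectors of the triangle expressed in each pose's own orthonormal in-plane
  frame;
- the Green–Lagrange tensor `E = (FᵀF − I)/2`, whose rotation invariance
  removes all rigid motion between poses;
- principal strains `e₁ ≥ e₂` of `E`, reported as engineering stretches
  `100·(λᵢ − 1)` with `λᵢ = √(1 + 2eᵢ)` — the *principal stretch* along the
  direction of maximal elongation and the *orthogonal stretch* (negative =
  compression) perpendicular to it. A uniform uniaxial elongation of a
  segment from 10 mm to 13.3 mm therefore reads 33%, which is the convention
  used throughout;
- the axial (mod-180°) principal direction, stored as a canonically signed
  3-D unit vector in the reference surface frame, and the area ratio
  `|det F| = λ₁λ₂`.

Strain is computed in each triangle's own plane (membrane assumption);
out-of-plane bending carries no penalty. Per-triangle values are reported
raw — no smoothing across neighbouring triangles — with optional averaging
deliberately left out of the default path.

## Synthetic scenes

Every photograph in the processing chain is replaced by a rendered scene
with analytic ground truth.

**Speckle texture.** Dark dots on a light background: nominal dot diameter
1.27 mm, target ink fraction 65%, per-dot diameter jitter drawn uniformly
from `diameter·[1−variation, 1]` with variation 0.75. Dots are placed by
seeded uniform sampling with overlap allowed; the realised ink fraction is
measured on the raster and dot placement stops when the target is reached.
Ink coverage saturates like `1 − e^{−λ}`, so requests at or above ~0.9 fail
after a bounded number of dots — beyond that the ink merges into solid
regions useless for patch matching. Rendering is anti-aliased with a 1 px
edge ramp at 10 px/mm.

**Deformations.** All models expose the exact deformed position and the
exact strain from the first fundamental form `G = JᵀJ` of their analytic
Jacobian: rigid motion (zero strain by construction), uniform uniaxial
stretch, a linear stretch ramp (the deformed position integrates the local
stretch, so a 5 %/cm ramp is exact, not approximated), and a radial
out-of-plane bulge/contraction. The bulge couples a C¹ cosine bump in z
with a proportional in-plane dilation so that an outward bulge stretches
the apex both radially and circumferentially (area ratio > 1) while an
inward contraction compresses it circumferentially — the two signatures
that distinguish a puffed from a pouted cheek in the orthogonal-stretch
map. Ramp presets add a start offset so local stretch stays positive over
the patch; a zero-crossing ramp would silently swap the principal and
orthogonal directions halfway across.

**Cameras and rendering.** Pinhole cameras (right-handed, +z viewing,
top-left pixel origin, integer pixel centres) at the corners of a 20×20 cm
square, 30 cm from the patch, focal 3000 px so a central pixel covers
0.1×0.1 mm. Rendering inverse-maps pixels to material coordinates through a
piecewise-linear interpolant of a fine (0.5 mm) forward-projected grid and
samples the texture bicubically; there is no lighting model, as the
emulated targets are matte high-contrast ink. The same pixel↔material map
provides exact ground truth for any tracked image location. Additive
Gaussian intensity noise (sd 0.01 of full scale) is the only imaging
imperfection modelled.

**Desk scale.** Default runs use 800×600 px images of a 60×45 mm patch
with DIC subsets of radius 30 px on a 10 px grid — the study-scale 1 mm
grid pitch at the study's pixel footprint, with the subset radius halved
(3 mm instead of 6 mm) so a full four-condition validation fits in minutes
on one CPU. Full-scale geometry is a config change, not a code path.

## Digital image correlation

Matching is subset-based. Integer displacements maximise the
zero-normalised cross-correlation (ZNCC), which is invariant to affine
intensity changes; ties resolve toward the smallest displacement magnitude,
then lexicographically. Zero-variance subsets are flagged `low_score`
(score 0). Subpixel refinement is two-stage: a quadratic fit of the 3×3
ZNCC surface around the integer peak, then inverse-compositional
Gauss–Newton with a first-order (affine) subset shape function and bicubic
interpolation, converged when the warp-update norm (translation plus
radius-scaled gradient terms) drops below 1e−4 px, or flagged `diverged`
after 50 iterations or on a singular Hessian.

Large unknown motions are seeded by a coarse pass on 4× downscaled images
summarised by a trimmed-least-squares global affine motion; full-resolution
subsets then search only ±10 px around their prediction, and the IC-GN
affine part starts from the global estimate — this is what lets strongly
foreshortened cross-camera pairs (the two cameras view the patch ~37°
apart) converge. The integer stage accepts weak peaks (ZNCC ≥ 0.25) because
unwarped subsets under foreshortening correlate imperfectly; the final
score threshold (0.8) is enforced on the IC-GN score. With calibration
available, cross-camera searches are restricted to a ±20 px epipolar band.

Pose-chain tracking matches camera A→B at the reference pose, A across
poses, and A→B at the deformed pose (seeded at the rounded pose-matched
positions, with the subpixel offset carried through each subset's fitted
local affine), so every surviving point has subpixel coordinates in all
four images. If fewer than half the grid survives, the run aborts — the
regime where reliable correlations cannot be found.

## Reconstruction, calibration and maps

Matched points are triangulated per pair by row-normalised linear least
squares (DLT); near-parallel rays (< 0.1°) are flagged. No bundle
adjustment — the workflow is per-pair, matching how such rigs are used.

Stereo calibration follows the planar-target workflow: per-view DLT
homographies (Hartley-normalised), closed-form intrinsics from the
homography constraints, per-view extrinsics, then joint Levenberg–Marquardt
refinement of both intrinsics, the relative pose and all board poses.
Checkerboard corners are detected as saddle points of the smoothed
intensity (negative Hessian determinant — rotation invariant, and silent at
board borders), ordered via the four extremal corners with all four cyclic
labelings tried and the square-colour parity used to break the 180°
ambiguity (boards with rows+cols odd disambiguate fully). Synthetic
calibration sweeps place boards with strong tilts (±35°) and an 80 mm range
along the optical axis: with a narrow-field rig, a planar target constrains
focal length — and hence reconstruction scale — only through perspective
variation, and a shallow sweep leaves percent-level scale errors.

When reconstruction accuracy is scored under a *fitted* (noisy)
calibration, the reconstruction is first registered to ground truth by a
rigid (Kabsch, no scaling) transform: the absolute world pose of a
reconstruction is not observable from a fitted calibration, but scale and
warp errors remain in the reported error.

Stretch maps project triangle centroids onto the best-fitting plane
(principal-axes fit of the reference vertices) and resample area-weighted
means onto a 1 mm grid, filling interior holes by nearest neighbour within
2 cells. The in-plane strain fraction weights each triangle's principal
direction by |principal strain|·area and measures the summed in-plane
component; it is exactly 1 for a flat reference patch, and drops below 1
only when the reference surface itself is curved. Orientation statistics
double the axial angles, compute the weighted circular mean and circular SD
`√(−2 ln R)`, and halve back, so a tight bundle's axial SD matches its
linear SD; all orientation statistics are invariant to 180° flips. The
stretch gradient is the mean central-difference gradient magnitude of the
gridded field in %/cm (direction-resolved gradients are not reported).
Distance profiles bin grid cells by straight-line distance along an
anchor-to-anchor axis in plane coordinates — an approximation to geodesic
distance that degrades on strongly curved patches. Percentiles are
area-weighted with linear interpolation between order statistics.

## Validation conditions and observed accuracy

Four conditions probe the chain end to end, each scored as the mean
absolute deviation of recovered stretch from analytic ground truth over
tracked triangles: an undeformed patch re-imaged with independent noise
(same view and after a 15° rotation — the noise floor), and a 33% uniaxial
stretch (same and rotated view). A fifth scores the mean 3-D tracked-point
error when triangulating with a calibration fitted on checkerboard corners
carrying enough Gaussian noise for a ~3 px RMS reprojection residual at the
0.1 mm/px footprint. `scripts/acceptance.py` recomputes all five from
scratch over three seeds; the suite's acceptance tests assert the same
bounds at one seed. Tracked desk-scale patches yield ~1 500 points and
~3 000 triangles per run.

## Numerical choices and degenerate inputs

- Delaunay triangulation runs on the reference-image grid coordinates and
  is lifted to 3-D; triangles with any edge longer than 3× the median, or
  with reference area below 1e−6 mm², are removed. Collinear inputs raise.
- Eigen-decomposition of the 2×2 strain tensor is closed-form; orientation
  sign is canonicalised (first non-negligible component positive).
- Degenerate deformed triangles are flagged and excluded from maps and
  summaries rather than propagated.
- Empty profile bins report NaN, never zero.
- All randomness flows from a single integer seed per scene through
  `numpy.random.SeedSequence`; identical config + seed reproduces artifacts
  byte-for-byte.

## What passing tests do and do not show

The synthetic scenes share the real chain's failure modes only partially:
additive sensor noise, viewing-angle foreshortening and miscalibration are
modelled; smudged ink, body hair, specular gloss, non-planar reference
anatomy and pose-to-pose lighting changes are not (a blurred-stripe fixture
stands in for smudging in the matching tests). Accuracy figures obtained
here therefore bound the *algorithmic* error of the chain, not the error of
a physical rig on skin. Human-scale descriptive results (mean regional
stretch, angular SDs, repeatability correlations) depend on real imaging
data and are covered only by property-based analogues on synthetic scenes.

## Known limitations

- First-order subset shape functions: second-order displacement curvature
  inside a subset biases matches; negligible for the smooth warps tested.
- Plane-projected maps and straight-line profiles are approximations on
  strongly curved patches.
- No four-camera joint bundle adjustment; camera pairs are calibrated and
  triangulated independently.
- The contraction preset compresses both axes at its exact apex; its
  distinguishing signature is the orthogonal-stretch sign, not the
  principal one.
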