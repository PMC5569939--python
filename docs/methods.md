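# Methods

This note documents the models, numerical choices and limitations behind
`palsymetry`, in the order data flows through the pipeline.

## Shape model

The 3D morphable model is linear:
`S = S̄ + A_id (α_id ⊙ σ_id) + A_exp (α_exp ⊙ σ_exp)`.
Basis matrices are stored flat with row `3v + c` holding vertex `v`,
coordinate `c` (x = 0, y = 1, z = 2); this is the single flattening
convention in the package, implemented in `model.field_to_mesh` /
`mesh_to_field` and enforced by round-trip tests.  Coefficients are kept in
standard-deviation units and the per-component standard deviations
`σ_id`, `σ_exp` are applied inside `construct_shape`.  The payoff is that the
ridge penalty in the fitter acts on dimensionless, comparably scaled
quantities, so one `λ` works across models of different physical scale.

The container format is a zip archive of `.npy` members plus a JSON header
(format version, names, dimensions).  Member timestamps are pinned to the
epoch so saving the same model twice produces byte-identical files — useful
for caching and provenance checks.  Mesh export is plain Wavefront OBJ with
8-decimal coordinates, preserving vertex order (region indices refer to
vertex positions, so order is semantic).

## Camera and pose estimation

The camera is weak-perspective: `s_2d = f · P · R · X + t` with
`P = [[1,0,0],[0,1,0]]`, `R = Rz(roll) · Ry(yaw) · Rx(pitch)` (right-handed
axes; a fixed, documented composition order is required for reproducibility —
tests compare matrices, not angles, wherever possible).  Image coordinates
are pixel units, origin top-left, v pointing down, matching .pts landmark
files.  Only the image-plane component of a 3D translation is observable
under orthographic projection, so `Pose` stores the identifiable 2D
translation; the depth component is a non-identifiable degree of freedom and
is deliberately not a parameter.

`estimate_pose` solves the scaled-orthographic resection in closed form:

1. center the 3D points and the observations on their centroids;
2. solve the unconstrained 2×3 affine map by least squares;
3. project the affine map to the nearest matrix with orthonormal rows via
   SVD and complete it to a proper rotation with the cross product (the
   result can never be a reflection, regardless of mirrored inputs);
4. refit the scale (ratio of matched variances, optimal given the rotation)
   and the translation in closed form.

On noiseless weak-perspective data this recovers the generating pose to
machine precision; on noisy data it is the standard affine-then-correct
approximation.  Collinear or coincident 3D points leave the pose
unconstrained and raise an error rather than returning garbage.  Angle
recovery from a rotation matrix uses the closed form of the documented
composition; at gimbal lock (|cos yaw| < 1e−9) the pitch/roll split is
unobservable and roll is set to 0 as a deterministic tie-break.

## Landmark fitting

The fit objective is the squared reprojection error over the corresponded
landmarks plus ridge penalties `λ_id‖α_id‖² + λ_exp‖α_exp‖²`.  Because the
projected landmarks are affine in the coefficients at fixed pose, and the
pose has the closed-form solution above at fixed shape, the solver is
block-coordinate descent with two exact sub-solves per iteration — no
derivatives, no line search, fully deterministic.  Initialization is the mean
face (coefficients 0) and the closed-form pose against it.

Defaults: `max_iters = 50`, `tol = 1e−8` (relative residual change),
`λ_id = λ_exp = 1e−3`.  The mild shrinkage keeps the normal equations well
conditioned with 68 landmarks; recovery experiments that need unbiased
coefficients use `λ = 1e−8`.  The pose candidate is accepted only if it does
not increase the residual, and an iterate that would raise the residual
through floating-point effects is discarded and iteration stops — so the
recorded residual trace is non-increasing by construction, which is asserted
on every synthetic fit.  Residuals are reported as ocular-scaled RMSE
(percent of the observed interocular distance) when the observations carry a
scheme with eye subsets; the scaling is constant within a fit, so it affects
reporting only, not the trajectory.

Convergence is linear (typically 50–100 iterations to reach ~1e−9 %IOD on
noiseless data); since one iteration is a 12-unknown linear solve plus a
2×3 SVD, full fits run in milliseconds at the problem sizes used here.

## Landmark evaluation

The interocular distance is the distance between the centroids of the two
eye subsets — centroids rather than corner landmarks to keep the normalizer
robust to single-point noise; the subsets are configurable so corner-based
variants are expressible.  Errors are Euclidean distances divided by the
ground-truth IOD, ×100.  The per-subject report pools the squared normalized
errors of all landmarks of all of a subject's images; the `total` row pools
across subjects (headline) and also carries the unweighted mean of
per-subject values, since both conventions exist in the literature.  No claim
is made that these percentages are numerically comparable to scores computed
with other IOD definitions.

The hybrid merge takes the mouth subset from a designated secondary landmark
source and everything else from the primary, reflecting the empirical pattern
that different fitters specialize in different face parts; non-subset points
are bit-identical to the primary input.

## Region motion, progress, asymmetry

`E(d) = Σ_{v∈d} ‖S_1,v − S_0,v‖²` is computed per region as both sum and
per-vertex mean; the mean is the headline statistic because it is invariant
to region size.  Both meshes must be in model space — fitted meshes are
pose-free by construction — because the measure compares shapes, not camera
geometry.  The test suite includes the deliberate failure mode: a global
translation of `S_1` inflates every region's mean equally, demonstrating why
pose-normalization upstream is mandatory.

Progress is the signed difference of a session's `E_mean` from the first
(baseline) session, per region.  The sign is reported without clinical
interpretation: a gain is positive, but whether "more motion" is always
better (e.g. hyperkinesis, synkinesis) is a clinical question outside this
package's scope, as is any mapping to House–Brackmann, Sunnybrook or
Yanagihara grades.

The asymmetry index `(E_R − E_L)/(E_R + E_L)` lives in [−1, 1].  When both
regions show zero motion the index is undefined and an error is raised —
returning 0 would fake perfect symmetry.  Under a one-sided attenuation
model (affected displacements scaled by ρ) the affected region carries ρ²
of the healthy energy, giving |index| = (1−ρ²)/(1+ρ²) and the inverse
ρ̂ = √((1−|a|)/(1+|a|)), implemented in `attenuation_from_asymmetry`.

Region configs map names to explicit vertex lists or to half-plane rules
("x < 0", "x > 0 and y < 0") evaluated on centroid-relative mean-shape
coordinates.  Rules use a 1e−9 exclusion band around the threshold so exact
midline vertices belong to neither side; mirrored regions on symmetric
models are then strictly disjoint and the ρ² relation above is exact.

## Synthetic data

The generator emulates a small clinical study: by default a compact model
(m = 300 vertices, 8 identity + 4 expression modes), six subjects, three
sessions, left-sided palsy with baseline attenuation 0.5 recovering linearly
to 1.0 by the final session, end-range amplitude of one expression standard
deviation, near-frontal poses (±0.2 rad) at 2–3 px per model unit, and
noise-free landmarks (the emulated setting treats manual annotations as
ground truth; observation noise is available through `noise_sigma`).

The mean shape is a parametric 68-point iBUG-style layout (jaw arc, brows,
nose, eye hexagons, two-ring mouth) plus mirror-paired "dome" filler
vertices; symmetrization against the known mirror permutation makes the
mesh exactly symmetric, so symmetry-based tests are exact rather than
approximate.  Identity basis columns are random orthonormal directions with
geometrically decaying scales (ratio 0.8).  The expression basis is special:
its first column is a smile-like displacement field (y/z motion with a
Gaussian falloff from the mouth), its second the left-masked copy of that
field with midline vertices at half weight, the rest random orthonormal
completions.  Any one-sided attenuation of the motion is a linear
combination of the first two columns, so a landmark fit can represent
palsy-like motion *exactly* — closed-loop experiments (generate → observe →
fit → evaluate) then measure the pipeline's numerical fidelity (observed:
region means recovered to ~0.02% relative) rather than an arbitrary
model-mismatch floor.

What the generator does not emulate: real identity/expression covariance
learned from scans, non-Gaussian annotation errors, occlusion, expression
fields outside the basis span, synkinesis, and detector-specific landmark
biases.  Passing tests therefore demonstrate the correctness and numerical
behaviour of the measurement machinery, not clinical accuracy on patient
photographs — that requires real landmark fitters and graded patient data.

## Problem sizes and determinism

Tests and the acceptance script use m = 120–300, k_id ≤ 8, k_exp ≤ 4,
68 landmarks, up to 50 fit replicates per condition and a 6×3-session
cohort; these sizes keep every experiment deterministic-fast while leaving
all dimensions (m, k, landmark count) fully general in the code — nothing
assumes the synthetic sizes, and the 68-point scheme is a config default,
not a constant.  All randomness flows through `numpy` `SeedSequence`s derived
from explicit seeds; repeated runs are bit-identical, and the CLI writes
byte-identical outputs given identical inputs.
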