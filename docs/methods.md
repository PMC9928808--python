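# Methods

## The coupling model

The knee-joint complex is described by 12 kinematic parameters: lateral
shift, anterior drawer, joint distraction (mm) and flexion, abduction,
external rotation (deg) of the tibia relative to the femur; and lateral
shift, anterior translation, superior translation (mm) and flexion,
lateral rotation, lateral tilt (deg) of the patella relative to the femur.
A coupling model selects a subset of the six tibiofemoral parameters as
inputs — always including flexion, the primary motion — and expresses each
remaining parameter as a polynomial in the inputs with no cross terms:

    y = c0 + Σ_i Σ_{k=1..order} c_{k i} x_i^k.

The packaged 1-DOF model (input: flexion) has 11 output rows; the packaged
2-DOF model (inputs: flexion, external tibial rotation) has 10. Both are
order 2. Inputs pass through prediction unchanged, which is why their
cross-validated error is identically zero. Coefficients assume degrees and
millimetres; radian inputs would silently produce wrong predictions.

Packaged coefficients are stored as decimal strings and parsed at load
time, so serialization round-trips them digit-for-digit; fitted models
serialize with 17-significant-digit reprs, which round-trip floats
exactly.

## Fitting

Coefficients are estimated per output by ordinary least squares on the
pooled observation table (every participant × activity × time point
weighted equally). The solver checks column rank via singular values
(tolerance `max(n,m)·eps·σ₁`) and raises on deficiency rather than
falling back to a pseudo-inverse; the solution itself uses an SVD-based
factorization, not normal equations. Inputs are not centred or
standardized so fitted coefficients are directly comparable with the
packaged rows; the orthogonal factorization absorbs the resulting
conditioning. Whether outputs are solved jointly or one at a time is
immaterial for least squares; the implementation solves all outputs
against one factorization.

## Residual metrics and the error table

Rotations of 1° and translations of 1 mm are weighted equally (unit
written deg|mm). For an n-input model over p observations,

    RMSR_TF = sqrt( 1/((6−n)p) Σ_i Σ_j (y_ij − y'_ij)² )  over the 6−n predicted TF parameters,
    RMSR_PF = sqrt( 1/(6p)     Σ_i Σ_j (y_ij − y'_ij)² )  over all 6 PF parameters.

Leave-one-participant-out cross-validation refits the model on all other
participants' pooled observations and predicts the left-out participant's
trials from their measured input channels. Per-participant, per-parameter
RMSEs pool raw squared errors across that participant's activities and
time points before the square root; since every trial contributes the same
number of samples this equals the RMS of per-activity RMSEs. The table's
`All` row is the RMS of the predicted parameters' RMSEs — input parameters
are excluded, because including their structural zeros would deflate the
pooled error. The `Mean` column is the arithmetic mean of the
per-participant values, not a pooled RMS. Values are kept at full
precision internally and rounded only for display.

## Preprocessing

Raw recordings are conditioned in this order: (1) zero-phase
forward–backward Butterworth low-pass filter (order 4, cut-off 10 Hz,
default sampling 200 Hz) applied on the true-time grid, with reflective
("even") edge padding of length 3 × filter order — zero-phase filtering is
the gait-analysis standard because phase lag would shift events between
channels, and a single-pass option is provided; (2) resampling to 201
points on a uniform normalized-time grid via a cubic spline (linear below
4 samples), exact on affine signals and preserving end points exactly;
(3) translation scaling by `reference_width / participant_width`
(reference 81.7 mm, a typical cohort-mean femoral bicondylar width), i.e.
scaling each knee's translations *toward* the mean-width knee. The
direction of this normalization is a convention; it is invertible by
swapping the ratio, and rotations are never touched.

## Joint coordinate system

Each joint uses two body-fixed axes — the femoral X (flexion axis,
pointing right) and the tibial or patellar Z (longitudinal axis) — plus a
floating axis perpendicular to both. Rotations are the intrinsic
parent-X / floating / child-Z angles; the floating-axis angle is reported
as the angle between the fixed axes minus 90°. Translations are the
components of the parent-to-child origin vector in the (generally oblique)
basis (parent fixed, floating, child fixed): the unique q with
d = q₁e₁ + q₂e₂ + q₃e₃. Projections onto the axes were the alternative;
oblique components were chosen because they make decompose/compose exact
inverses and make a constant child-origin offset along the child axis
shift exactly one translation channel. The two conventions coincide
whenever the fixed axes are perpendicular. Decomposition refuses poses
whose fixed axes are within 0.1° of parallel (gimbal singularity).

Sign conventions for positive directions are configuration
(`JointSpec.signs`), defaulting to +1 for every parameter on a right knee;
left-knee data should be mirrored before decomposition.

## Anatomical frames

- **Femur.** X = axis of an orthogonal-distance least-squares cylinder
  fitted to the posterior/distal condylar surface; L₁ = diaphyseal cone
  axis (proximal); Y = normalize(L₁ × X) (anterior); Z = X × Y; origin =
  foot of the perpendicular from the intercondylar notch apex to X.
- **Tibia.** Z = diaphyseal cone axis (proximal) through the intercondylar
  eminence midpoint; L₃ = line joining the plateau centers (right);
  Y = normalize(Z × L₃); X = Y × Z; origin = intersection of the Z line
  with the plane through the femoral origin perpendicular to Z, evaluated
  at the reference (imaging) pose.
- **Patella.** Y = principal inertia axis with the largest moment (normal
  to the flat aspect), signed by an anterior hint; X = normalize(Y ×
  ridge) for a superiorly directed posterior-ridge vector; Z = X × Y;
  origin = centroid.

Cylinder and cone fits minimize orthogonal distances with
Levenberg–Marquardt (step tolerance 1e−13, bounded iteration count, error
on non-convergence). Initialization starts from each principal direction
of the patch *and* from a coarse Fibonacci-hemisphere scan scored by an
algebraic circle fit of the projected points — a partial arc patch can
make plain principal components point far from the true axis. Axis signs
are resolved deterministically (largest-magnitude component positive) or
by caller-supplied hint vectors; hint vectors must be rotated along with
the geometry for the constructions to be rigid-motion equivariant.
Coplanar or collinear point sets are rejected up front. Cylinder-like cone
data (half-angle → 0) converge to a small half-angle rather than erroring;
callers can inspect the fitted angle. Region selection for the condylar
and diaphyseal patches is the caller's responsibility — the package
accepts pre-selected patches and landmark points, and does no image
processing or automatic landmark detection.

## Synthetic cohort generator

The generator emulates the study conditions a practitioner would collect:
by default 10 participants × 6 activities (open-chain flexion and
extension, level and downhill walking, stair ascent and descent) × 201
normalized-time points of all 12 parameters, driven by the packaged 2-DOF
model as ground truth. Per activity it builds a stylized flexion profile —
open-chain trials sweep 0→100°→(reverse), gait-like trials show a small
stance bump and a larger swing peak capped at 60–90° depending on
activity — and an external-rotation signal
`coupling_fraction · 0.15 · f(t)` plus an independent smooth random
component (3-harmonic Fourier series, 4° marginal sd), so external
rotation is only weakly related to flexion, as observed in vivo.
Participant heterogeneity multiplies every ground-truth coefficient by
`1 + N(0, 0.05)` by default; bicondylar widths are drawn from
N(81.7 mm, 4 mm).

Measurement noise (default 0.5° / 0.5 mm per sample, the order of biplane
X-ray error bounds) is i.i.d. Gaussian per output channel. The driver
(input) trajectories are left clean by default, with a separate
`input_noise_sd` knob: this keeps the generative model within the fixed-
design least-squares framework, so the closed-form coefficient covariance
σ²(XᵀX)⁻¹ describes fitted-coefficient variability exactly and parameter-
recovery tests can use analytic standard errors. Temporal correlation of
real measurement error, soft-tissue artefact, and any biomechanical
constraint structure (contact, ligaments, muscles) are not modelled —
passing tests demonstrate correctness of the estimation machinery under
the stated statistical model, not fidelity of the polynomials to any real
knee.

Randomness is reproducible and parallel-safe: the global seed expands via
`numpy.random.SeedSequence.spawn` into one stream per participant (model
perturbation, width) and one per trial (profiles, noise), so the same
seed always yields bitwise-identical cohorts.

Synthetic bone fixtures place a condylar half-cylinder (radius 22 mm),
conical diaphyses (half-angle 3°), a solid-ellipsoid patella (semi-axes
22 × 9 × 25 mm) and landmark points in a canonical pose whose femoral and
tibial frames are the identity; an optional rigid transform moves
everything, ground truth included. The patellar ground-truth frame is
defined by the inertia of the sampled cloud itself (recorded from the
noiseless sample), since a finite sample's centroid differs from the ideal
solid's.

## Problem sizes and tolerances in the test suite

Study-scale checks use the full 10 × 6 × 201 = 12,060-observation cohort;
cohort fixtures elsewhere use 3 participants and 101–201 points, which
exercise the same code paths at lower cost. Geometry round trips run 1000
random poses at 1e−9; equivariance checks at 1e−8; noiseless surface
recovery at 1e−6; metric oracles (double-loop RMS, normal equations) at
1e−12 / 1e−8. Noisy recovery asserts every fitted coefficient within 4
analytic standard errors of ground truth, and noisy-geometry axis errors
below 0.5° across 50 seeds.

## Known limitations

- The packaged polynomials are only meaningful in the coordinate-system
  convention described above; applying them to parameters defined in
  another convention requires re-expressing trajectories through
  `reexpress_trajectory` with the appropriate fixed offset transforms.
- Coupling coefficients are cohort-level: no per-participant anatomical
  personalization beyond bicondylar-width scaling is implemented.
- No regularization, mixed-effects structure, spline/Fourier bases, or
  statistical inference on residual differences; the model family is
  deliberately the plain polynomial one.
- The trial CSV dialect is a package convention (the columns are the
  canonical parameter names plus participant/activity/time-index and
  bicondylar width); no motion-capture container formats (C3D, etc.) are
  read.
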