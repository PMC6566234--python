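# Methods

This note documents the models, numerical choices and limitations behind
`voxreflect`, in the order of the analysis chain.

## Synthetic phantoms (what the generator emulates, and what it does not)

The generator (`voxreflect.phantom`) emulates agarose-filled microcentrifuge
tubes in an axial 3D scan: solid cylinders with assigned mean signal (or
T1/S₀ for TR-array series) on a uniform grid, surrounded by a low-signal
background.  A voxel belongs to a tube iff its center lies inside the
cylinder — simple, deterministic, and analytically checkable against
πr²L.  The default layout is three tubes of radius 4 mm and length 20 mm
(test 120, control 100, water 60, background 5, arbitrary units) on a
64×64×32 grid at 0.625×0.625×1 mm, i.e. a 40 mm field of view; tube axes
carry a half-voxel axial offset so the voxelized volume is unbiased.  The
water level sits below the contrast-enhanced cell signals, as it does in a
short-TR spin-echo image, but well above the air floor so a single global
threshold separates air from all three tubes.

Noise is Rician: magnitude reconstruction of complex MR data turns additive
complex Gaussian noise into √((S+g₁)² + g₂²) with independent g₁, g₂ of
scale σ (default σ = 2, i.e. SNR ≈ 50–60 in the tubes).  Known
misalignments — a 12-parameter affine and/or a cubic B-spline displacement
field, both in physical mm — are applied by resampling the noisy volume;
regions that map outside the simulated grid are composited onto the
background level (the surrounding bath/air), so downstream thresholding
sees a complete scene.  Identical specs (including seed) are bit-identical.

Not emulated: B0/B1 inhomogeneity, gradient artifacts, partial-volume
mixtures at tube walls (voxels are pure tube or pure background before
resampling), chemical shift, or any cell biology.  Consequently the tests
show the *algorithmic* chain is correct and accurate under magnitude noise
and geometric misalignment; they do not certify behavior under scanner
artifacts absent from the model.

## VOI extraction

Background removal uses Otsu's criterion (maximizing between-class variance
over a 256-bin histogram): deterministic and checkable against exhaustive
search.  Otsu is known to be sensitive to extreme class imbalance — with
tubes occupying only a few percent of the field of view, a very dim tube can
be merged into the background class; the default phantom keeps the water
tube at ~12× the background level, where the split is stable.  Tubes are
26-connected components within a configurable size window; roles
(test/control/water) are supplied by the analyst as seed points or a
left-to-right ordering, never auto-detected.  VOIs are cropped at the tube
bounding box plus a configurable pad (default 4 voxels) with the physical
origin updated so coordinates are preserved.

## Interior distance maps

For each tube mask, the map assigns every voxel its minimum Euclidean
distance (mm) to the tube boundary, the boundary being mask voxels with a
face-adjacent background neighbor (assigned exactly 0).  The solver is a
single-pass min-heap front propagation that carries nearest-boundary-voxel
attribution: when the front reaches a voxel it inherits its parent's source
voxel and stores the exact Euclidean distance to it (ties broken by voxel
index for cross-platform determinism).  Compared with a first-order upwind
Eikonal update, attribution propagation reproduces the analytic values of
the test fixtures exactly (a 3×3×3 cube's center is 1.0; doubling the
spacing doubles every value; translation equivariance is exact) and stays
well inside a 0.6×spacing bound against the exact Euclidean transform on
random blobs.  Its theoretical failure mode — an occluded nearest source in
a strongly non-convex mask — produces errors far below that bound on
tube-like and blob-like shapes.  No signed distance is defined outside the
mask, and there is no sub-voxel boundary localization.

## Registration

**Affine stage.**  The 12 free parameters (3×3 matrix + translation, about
the reference-tube centroid) map reference physical coordinates into the
target scan.  The metric samples the reference distance map at its mask
voxels (dense, deterministic — no stochastic sampling) and compares them
with the target distance map interpolated at the transformed positions,
extended by 0 outside its mask (the boundary value continues smoothly).
Mutual information is computed with linear partial-volume binning (32 bins
between the 1st and 99th percentiles, frozen per registration): hard-binned
MI is piecewise constant in the transform parameters and cannot drive a
quasi-Newton optimizer, while the soft-binned form is differentiable almost
everywhere.  The optimizer maximizes the *normalized* form
NMI = (H_a+H_b)/H_ab: plain soft MI can be inflated by a uniform contraction
of a smooth map (the sampled-value entropy grows while the joint relation
stays functional), which showed up as a spurious ~1.5% scale drift in
self-registration; NMI is invariant to that and shares its maximum with MI
at alignment.  L-BFGS-B (history 10, ≤100 iterations) with finite-difference
gradients and a characteristic-length parameter scaling; initialization is
centroid alignment.  If the optimizer fails to improve the metric, the
initialization is returned with a warning flag.

On the default three-tube phantom, random misalignments (translation ≤5
voxels/axis, rotation ≤10°, per-axis scale 0.9–1.1) are recovered with a
median target-registration error of ~0.2–0.3 voxels; occasional repeats
reach ~1 voxel when a scale/rotation combination creates a shallow metric
valley.  A single cylinder is rotationally symmetric about its axis, so
axial rotation is unobservable from one tube's distance map; the recovery
study therefore registers the full three-tube foreground.

**Elastic stage.**  A cubic B-spline free-form deformation composed after
the affine, T(x) = A(x) + u(x), with zero coefficients giving the identity.
Four resolution levels with image shrink factors 8/4/2/1 and Gaussian
smoothing σ = 4/2/1/0 voxels; the control spacing starts at a quarter of
the VOI extent and is halved between levels by exact dyadic spline
subdivision, so the refined grid reproduces the coarse field before further
optimization.  Decimation is a speed device only and is capped so every
level keeps at least 8 sample planes per axis.  The metric (MI by default,
mean-squares switchable) is optimized by L-BFGS-B with analytic gradients
(the Parzen-window MI derivative; image gradients from central differences
of the smoothed target), per-coefficient bounds of ±10 mm, and a discrete
bending penalty — the mean squared second difference of the control
coefficients, weight 20 — without which the finest level (control spacing
≈ extent/32 ≈ 1–2 voxels) has far more freedom than the images can
constrain and chases noise and edge-interpolation artifacts.  Mean-squares
is provided for same-intensity pairs but is notably more prone to that
overfitting on edge-dominated tube images; MI is the robust default.

A homogeneous cylinder constrains deformation only at its boundary:
interior tangential displacement at scales below the tube diameter is
unrecoverable in principle (the aperture problem).  The warp-recovery study
therefore uses ground-truth warps with ~16 mm control spacing (about the
tube diameter) and ≤2-voxel displacement, which the registration recovers
to a mean composition residual of 0.25–0.45 voxels against a do-nothing
baseline of 0.5–1.2 voxels.

**Resampling.**  Output voxels take linearly (or nearest-) interpolated
input values at their mapped physical positions; anything mapping outside
the input domain is flagged invalid, never zero-filled, and invalidity is
propagated conservatively through interpolation.

## Reflectivity

The global value is the ratio of sums over the common valid mask; the
per-voxel map is (Iᵢ−gᵢ)/gᵢ×100 where gᵢ>0, flagged otherwise.  Voxels
invalid in either volume or with nonpositive control signal are excluded
from sums, map and N.  Both forms are exactly scale-invariant and invariant
to water normalization when both scans share one water reference.

The pipeline computes its ROI averages (the water mean, and the mask for
the reflectivity sums) on masks eroded by 2 voxels (configurable).  After
resampling, tube-boundary voxels are partial-volume mixtures of tube and
background; including them biases the test sums and the water mean low (on
the standard fixture the bias reaches 6 percentage points of R even under
the ground-truth transform).  Erosion of quantitative ROIs is standard
partial-volume hygiene and is recorded in the report.

The color map clips the percent map to a symmetric range (default ±100%)
through a 256-entry diverging lookup table (`RdBu_r`); flagged voxels are
transparent, and the legend carries the table so rendered maps invert to
values within one quantization step.

Paired comparisons use the exact Student t distribution (the relevant
sample sizes are 3–5, where a normal approximation would be wrong), with
documented conventions for degenerate inputs: all-zero differences give
t = 0, p = 1; zero-variance nonzero differences give the limit p = 0.

## Relaxometry

The arrayed-TR spin-echo signal is modeled as saturation recovery,
S(TR) = S₀(1 − e^(−TR/T1)), with the constant echo-time factor e^(−TE/T2)
absorbed into S₀ (TE is fixed across the array, so the factor is
unidentifiable and harmless to T1).  Per-voxel bounded nonlinear least
squares (T1 ∈ [50, 10000] ms, the physical range for agarose/cell phantoms)
with a log-linearized initialization; voxels with flat or TR-decreasing
signal are excluded with a reason code rather than fitted.  Noiseless
nine-TR data is recovered to <0.1%; at 2% Rician noise the median T1 error
is ~3%.  Relaxivity is ordinary least squares of R1 = 1000/T1 (s⁻¹) on
concentration (mM); the slope is r1, the intercept the diamagnetic rate.
T1-based enhancement defaults to comparing mask-mean relaxation *rates* —
contrast agents shorten T1, raising R1 — with a signal-mean alternative; the
mode used is recorded in the output.

## Gadolinium assay

The calibration line ratio = slope·concentration + intercept (bundled
default: slope 0.3244, intercept −1.0944) is inverted to read concentration
from a measured A573/A433 ratio.  The bundled coefficient pair follows the
published convention A = 1/slope (= 3.0826 to 4 decimals) with B = 1.0944,
which is *not* the algebraic inverse of the line (−intercept/slope =
3.3736); both interpretations are first-class (`as_printed`, the default,
and `inverse_consistent`), and constructing an inconsistent pair emits a
warning rather than silently resolving it.  Concentration units follow the
calibration data and are carried as metadata.

## Problem sizes and determinism

The validation studies run on 64³ phantoms: 20 affine-recovery repeats,
3 warp recoveries, 2 pipeline runs, 1000-voxel noisy T1 fits — sizes at
which every ground-truth comparison is exact and the full suite completes
in a few minutes on one CPU.  All randomness flows through explicit
`numpy.random.default_rng` seeds; registration uses dense sampling, so
repeated runs are bit-reproducible.

## Known limitations

* Otsu background removal can merge very dim tubes into the background
  under extreme class imbalance; role seeds do not rescue a tube the
  threshold removed.
* Affine recovery occasionally (few % of repeats) lands in a shallow
  metric valley with ~1-voxel error; a multi-start strategy was judged
  unnecessary for the accuracy target (median < 0.5 voxel).
* The elastic stage regularizes toward smooth fields; genuine deformations
  at scales below the tube diameter are invisible in homogeneous tubes and
  will not be recovered (nor would they affect tube-mean reflectivity).
* DICOM support covers single-frame, single-series directories only; no
  enhanced multi-frame objects or PACS networking.
* No B1 correction, inversion-recovery or Look-Locker T1 models; no
  sub-voxel boundary localization in the distance maps.
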