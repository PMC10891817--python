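# Methods

## Scope and model

The package implements landmark-driven rigid registration for two
workflows: multimodal cardiac CT/US fusion (temporal phase matching followed
by spatial registration and error metrics, with a landmark-count validation
study) and unimodal mirror-based reconstruction of one-sided jaw defects.
Only rigid maps (rotation + translation) are fitted: cardiac and bone
anatomy would be distorted by non-rigid warps, and the landmark counts in
play (3–12) cannot constrain one anyway.

All physical coordinates are LPS millimetres (DICOM/ITK convention).
NIfTI files, which carry RAS geometry, are converted at the I/O boundary by
SimpleITK; Slicer-style FCSV/markups landmark files declare their coordinate
system and are converted on read/write (RAS → negate x and y).  Keeping a
single internal frame with conversions only at the boundary avoids
mixed-frame registration bugs that are otherwise very hard to localize.

Transform direction is explicit everywhere: `fit_rigid` returns the
moving→fixed map and `RigidTransform.inverse()` is provided, rather than
relying on an implicit convention.  The 6-parameter view is intrinsic Z-Y-X
Euler angles in degrees plus translations in mm; any fixed convention works
for parameter-space comparisons (RMSE1) as long as both transforms use it,
and this one is documented and round-trip tested.  Near gimbal lock
(|pitch| ≈ 90°) extraction is flagged with a warning and the canonical
branch (third angle 0) is used.

## Rigid fit

The solver is the closed-form SVD solution of the absolute-orientation
problem without scaling: centre both point sets, take the SVD of the
cross-covariance, and correct a det = −1 candidate by flipping the smallest
singular direction.  Degenerate inputs fail loudly rather than returning an
arbitrary branch: fewer than 3 pairs, or a moving set whose centred second
singular value is ≤ 1e−9 of the first (collinear — rotation about the line
is unobservable), raise a dedicated error.  Coplanar sets are accepted: the
proper-rotation constraint makes the solution unique at rank 2.

The test suite checks the solver against an independent multi-start
Levenberg-Marquardt minimization over the six parameters (agreement within
1e−6 mm FRE on random noisy problems), exact recovery on noiseless
instances, inverse-consistency under role swap, equivariance under a common
rotation, and the classical localization-error law
`E[FRE²] = (1 − 2/N)·FLE²` with `FLE² = 3σ²` by Monte-Carlo.

## Temporal registration

Gated CT provides frames at known phase fractions (0.0–0.9 by tenths).  The
free-running US series has no ECG, so one cardiac cycle is delimited between
two "fully open" valve states; phases are then assumed uniformly spaced
inside the cycle.  CT phase `p` maps to US frame
`start + round(p · (end − start))` with round-half-even tie-breaking (the
rounding rule is a package convention; it is documented, deterministic and
monotone, and endpoints map to endpoints).

Cycle delimitation is interactive by primary design (the clinical criterion
is visual); the automatic path reduces each frame to an openness scalar —
by default the mean intensity in a central ROI box — and takes the first
two consecutive local maxima whose prominence is at least 25% of the signal
range.  Two numerical choices matter here: maxima are plateau-aware (a run
of equal values counts once, at its middle index), and prominence is
computed on a three-fold tiling of the signal, treating it as one period of
a cyclic series.  Without the tiling, a peak adjacent to a truncated final
cycle is systematically under-scored and valid cycles are rejected.

## Error metrics

All three metrics are root-mean-square quantities.  RMSE1 compares the six
transform parameters against the gold standard, with rotation (degrees,
differences wrapped to ±180°) and translation (mm) reported separately and
never summed — they have different units, and a single mixed number would be
meaningless.  FRE is the RMS residual of the registered pairs.  RMSE2 is the
RMS distance between trial-transformed and gold-standard-transformed moving
landmarks; it is symmetric in the two transforms and zero iff they act
identically on the landmark set.  On synthetic data the gold standard is the
generator's ground-truth transform; on real data it is a user-supplied
transform file (no attempt is made to reproduce expert manual alignment).

## Validation harness

The sweep covers N = 3..12 landmark pairs, 10 trials, two observers by
default.  Within a trial, landmark subsets are prefix-nested — the placement
of landmark k does not change as N grows — which is the only design that
makes per-N curves comparable and the study reproducible.  The observer
model is per-coordinate Gaussian localization noise with per-user σ,
optional constant bias, and an optional index inflation σ_k = σ·(1 + γ·k)
(0-based k) emulating that later landmarks are placed on less distinct
anatomy.  Placements are deterministic given (seed, user, trial) via
spawn-keyed seed sequences and are drawn independently for the fixed and
moving volumes.

The optimal landmark count is the smallest N whose pooled mean RMSE2 is
within a configurable tolerance (default 5%) of the curve minimum — an
explicit, computable version of the usual "compromise between speed and
accuracy" narrative.  Boxplot summaries use linearly interpolated quartiles
with the 1.5·IQR outlier rule.  The acceptance bounds (RMSE2 ≤ 15 mm,
FRE ≤ 8 mm, inclusive) are checked per record at the chosen N, with
offenders listed.

## Synthetic phantoms

The cardiac scene is built from additive geometric primitives: a torus
annulus (mean diameter 35 mm, 15% diameter pulsation, maximal at phase 0)
between two contrast-filled chambers with walls, an outflow tube, a
soft-tissue body, and a leaflet disc that closes the orifice away from the
fully open phase — the leaflet is what makes the ROI-mean openness signal
peak at full opening, as a human assessing valve motion would.  All edges
are smoothed over ~1.5 mm so the field interpolates consistently across
grids with different spacings.  Grid spacings default to representative
clinical values (CT 0.47×0.47×1.00 mm; US 0.50×0.50×0.27 mm).  The US
series is rendered through the ground-truth rigid transform (the "probe
pose", default 25°/10°/−8° rotation with a ~25 mm translation), cropped to
a 35° half-angle cone and, when enabled, degraded with mean-one Rayleigh
speckle, additive Gaussian noise and a one-voxel blur.  Twelve labelled
landmarks (8 annulus ring points, 2 trigone analogues, outflow, apex) are
defined per phase; their US-frame truth is exactly the transform pre-image.

The jaw phantom is a U-shaped mandible analogue (body arc, two rami with
condyles) inside a soft-tissue ellipsoid on a grid symmetric about x = 0.
One ramus is displaced by a configurable rigid asymmetry (default 3°,
(1.5, 1.0, 0.5) mm) and carries a spherical "tumour" defect (default 10 mm
radius) replacing bone intensity; the intact pre-defect bone mask is stored
as ground truth, along with six landmark pairs on structures outside the
defect whose original/mirrored correspondence is exact by construction.

What the phantoms do **not** emulate: real speckle statistics and shadowing,
contrast-agent dynamics, anatomical shape variability, breathing motion, or
observer biases correlated with image content.  Passing tests therefore
demonstrate the correctness of the algorithms and the calibration of the
error model — not clinical-grade accuracy on patient data, whose image
quality drove much of the variability in the motivating study.

## Numerical choices

* Resampling (default target 0.342×0.342×0.37 mm, linear) preserves the
  input origin/direction and takes shape = ceil(extent/spacing), so physical
  coverage is never truncated; out-of-grid samples clamp to the edge voxel,
  which keeps linear interpolation inside the input intensity range.
* Mirroring resamples across the sagittal plane with nearest-neighbour
  lookup by default: the operation is then an exact involution on voxel
  columns and bone intensities survive unchanged for re-thresholding
  (linear interpolation is available by flag).
* The reconstructed jaw mask is re-segmented with bit-identical thresholds
  to the original bone mask and restricted to voxels on the defect side of
  the mirroring plane (LPS: LEFT means x > plane).
* Connected components use 26-connectivity; surface voxels are the mask
  minus its 6-connected erosion; surface distances pool nearest-neighbour
  distances in both directions.
* 4D data is stored as a directory of 3D NRRD frames plus a JSON manifest
  (frames, phases or null, source), keeping every frame readable by any
  3D tool.

## Problem sizes

The default test and validation runs use reduced grids chosen to exercise
every code path at full fidelity: cardiac pairs at 96×96×48 CT / 80×80×120
US voxels (full-size rendering is configuration only), sweeps with up to
5000 trials per observer for the trend checks (10,000 aggregate repetitions
per N), 10,000 repetitions for the FLE→FRE law, and 1000 seeded
registrations for the bound-compliance rate.  The acceptance script rebuilds
all of these from a single seed in about a minute on one CPU.

## Known limitations

* No intensity-based or deformable registration; the rigid landmark fit is
  the method under study, and automatic intensity-based alignment of these
  modalities is reported in the field as unreliable.
* No automatic landmark detection or correspondence search — pairing is by
  ordered index with matching labels.
* Bilateral jaw defects are out of scope: mirroring needs a healthy side.
* DICOM is read-only; bone thresholds for real jaw data are required inputs
  with no defaults, since calibrated intensity windows are scanner- and
  protocol-specific.
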