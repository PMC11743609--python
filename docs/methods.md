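# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `archflow4d`, in the order data flows through the
package.

## Coordinate and unit conventions

World coordinates are millimetres with axis order (x = left-right,
y = anterior-posterior, z = inferior-superior); voxel centres sit at
`origin + index * spacing` with 0-based indices.  Velocities are cm/s
(matching the velocity-encoding convention of phase-contrast MRI,
venc = 150 cm/s by default), volume flux is ml/s, angles are degrees.
Every writer declares units in its sidecar.

## Synthetic arch phantoms

The arch main path is a planar curve in a (tiltable) sagittal plane:
two straight limbs (ascending anterior, descending posterior) that
splay outward from the arch top, joined by a rounded apex (roman:
6 mm rounding radius; gothic: 4 mm) or by two corner arcs and a flat
transverse segment (crenel).  Straight splayed limbs are a deliberate
simplification: they make the apex-vertex arch angle controllable and
exactly computable.  `ArchSpec.canonical` solves the arch width
numerically (Brent's method) so the apex-vertex angle of the continuous
model matches a target — defaults 109° (roman), 117° (crenel), 97°
(gothic), the values typical for the three post-repair shape classes —
and solves the branch arc positions so the straight-line span between
the first and last take-off matches a target (defaults 7.1 / 11.9 /
3.4 mm).

Three branch tubes (two for the bovine variant) leave the arch at
configurable arc positions and take-off angles; the requested angle
between branch direction and local downstream tangent is realized
exactly in the continuous model for any out-of-plane azimuth.  Branches
fan laterally (azimuths -30/0/+30°) as the head vessels do; without the
fan, equal take-off angles at small spans produce parallel overlapping
tubes whose union has no recoverable per-branch topology.  Three
placement rules keep the generator physically consistent across the
tested parameter ranges: the gothic apex rounding is 4 mm because a
2 mm rounding with a 3.3 mm lumen radius makes a spindle-torus elbow
whose cross-sections blend into the limbs (no recoverable centerline);
the gothic branch cluster sits fully proximal to the apex (a take-off
distal to the point of a 97° arch collides with the ascending limb);
and the crenel transverse segment grows with the requested span so the
cluster stays on the flat top.

Lumen radii are neonatal post-repair scale (ascending aorta 4.0 mm,
proximal arch 3.6, distal arch 3.3, descending aorta 3.2, branches
1.6-1.8 mm) and blend smoothly (1.5 mm half-width) at the take-offs;
the isthmus is a Gaussian dip (default radius 3.0 mm, centred 8 mm past
the last take-off, 3 mm axial sigma).  Voxelization is a union of
spheres along a dense (<= half-voxel) sampling of all paths — a voxel
is lumen iff its centre lies within the local tube radius — and
refuses spacings coarser than the smallest radius.  Surfaces come from
marching cubes on the padded mask.

## Synthetic pulsatile flow

The velocity field is a kinematic construction, not a Navier-Stokes
solution.  Per frame, the axial component follows a Poiseuille profile
`2 v_mean (1 - (rho/R)^2)` scaled so the instantaneous inlet flux
equals `peak_flux * waveform(t)`; the waveform is a raised-cosine
systolic pulse (systole 40% of the cycle, peak at 40% of systole,
quiescent diastole) whose cycle integral is exactly
`systolic_fraction / 2`.  Defaults (120 bpm, 20 frames, 20 ml/s peak)
give a 2 ml stroke volume, neonatal scale.  The helical component adds
`helix_ratio x axial speed` tangentially about the local centerline
tangent, right-handed for positive ratio, with the swirl ramped
linearly to zero within 0.3 R of the axis — a tangential speed that
stays finite on the axis would mean unbounded angular rate there.  An
optional vortex adds an in-plane solid-body rotation patch (speed =
`strength * rho / core_radius`, cosine-tapered axially) centred on the
main path.  Gaussian noise (per component, lumen only — phase
background is assumed corrected upstream) and optional clipping to the
venc complete the model.  Branch lumen voxels carry zero velocity: the
phantom prescribes arch hemodynamics, not branch run-off, and the
distal-arch ROI never contains branch lumen.

What the phantom does *not* emulate: secondary flows from real
curvature (Dean vortices), wall compliance, turbulence, partial-volume
and phase-noise physics of the acquisition.  Passing tests therefore
demonstrate correctness of the measurement chain on controlled inputs,
not clinical accuracy on real scans.

## Mask conditioning and centerline extraction

Conditioning reproduces a black-blood segmentation-preparation chain:
nearest-neighbour resampling to 0.5 mm isotropic, one-voxel dilation
(26-connectivity), Gaussian smoothing of the binary field at 0.9 mm
standard deviation, re-threshold at 0.5.  On a solid 10 mm sphere this
grows the volume by ~12-28% (the dilation adds a 0.5-0.87 mm shell
while thresholded smoothing only removes the curvature term
`sigma^2 / r`); the unit test asserts that analytic band.  Because the
dilation thickens the lumen, cross-sectional areas are measured on the
un-dilated isotropic mask; the conditioned mask feeds the centerline.

Centerline extraction is 3D thinning -> 26-neighbour voxel graph ->
iterative spur pruning (arms shorter than half the minimum branch
length are removed only when a sibling endpoint sits within 5 mm — a
forked tip — so a lone tip next to a small skeleton web survives).
The inlet and outlet are the two most inferior endpoints (the arch
branches leave superiorly), connected by the geodesic main path.  Two
refinements matter at neonatal scale:

* **End-cap extension.**  Thinning erodes rounded vessel ends by about
  one lumen radius; each end is extended along its tangent while the
  interpolated distance-to-boundary stays near the local radius, which
  stops at the end-cap centre.  Without this, the arch-angle reference
  points sit several millimetres short of the vessel ends.
* **Wall-based re-centering.**  Skeletons bulge toward branch mouths
  inside junctions (up to ~1.4 mm here).  Region-based centring (e.g.
  maximising overlap with a disk template) systematically drifts *into*
  a mouth, because lumen gained there is first-order in the shift while
  lumen lost against a coincident wall is only O(shift^1.5).  The
  implementation instead casts 72 rays in the plane perpendicular to
  the running direction, discards rays that never hit a wall (branch
  mouths, inner-bend tails), trims outliers against a circular model,
  and moves the point by the first trigonometric harmonic of the
  boundary distance (`rho(phi) ~ r + a cos phi + b sin phi`, with
  (a, b) the displacement of a circle).  Three passes interleaved with
  light smoothing bring the path within ~0.1 mm of the analytic axis
  away from junctions and ~0.15-0.3 mm inside merged clusters.

Branch axes are fitted to the re-centred outer branch polylines with
an iteratively trimmed total-least-squares line (points in a merged
common trunk are off-axis outliers and get dropped), near-parallel
duplicate filaments are merged, and each bifurcation is placed at the
closest approach of the branch axis to the main path.  Per-point lumen
radius is the Euclidean distance map sampled along the path.

## Morphometry definitions

* **Bifurcation angle** — angle between the downstream main-path
  tangent at the take-off and the branch axis.  Tangents come from a
  Gaussian-weighted local quadratic in arc length (window 4 mm),
  differentiated at the evaluation point: unlike a straight-line fit,
  this is unbiased on a constant-curvature bend, where a one-sided
  chord can be rotated by half the subtended angle.
* **Arch angle** — vertex at the most superior main-path point (a
  local quadratic vertex fit removes the sub-sample bias of a rounded
  apex; a flat crenel plateau falls back to its arc midpoint), between
  the directions to the inlet end and to the point 20 mm (by arc)
  distal to the last take-off.  The apex-vertex definition is a fixed
  choice; a tangent-based variant was considered and not taken because
  the vertex form is the one that cleanly separates the three shape
  classes on the phantoms.
* **AP angulation** — angle in [0°, 90°] between the least-squares
  plane of the main path (inlet to descending-aorta reference) and the
  sagittal plane (left-right normal).  This is an explicit operational
  choice; other definitions of "anteroposterior angulation" exist.
* **Branch span** — Euclidean distance between the first and last
  take-off points; on a bovine arch the only pair is used and flagged
  with a warning.
* **Level areas** — the lumen is intersected with the plane
  perpendicular to the main tangent 2 mm proximal (by arc) to the
  respective take-off; the isthmus is the minimal-area plane within
  (0, 20] mm past the last take-off, scanned at 1 mm steps.  The
  in-plane region is the connected component containing the centre,
  confined to the local tube (pixels closer to a branch axis than to
  the main path, beyond the local radius, are excluded — branch mouths
  graze nearby planes when take-offs are closely spaced), and the area
  integrates fractional occupancy over the component plus a one-pixel
  ring (thresholded counting overestimates by ~quarter pixel of
  boundary).  The 2 mm / 20 mm offsets are configuration, chosen to
  stay within neonatal anatomy.
* **Caliber ratios** — exact division of the ascending-aorta area by
  each downstream level area.
* **Shape classification** — a quantitative surrogate for the
  qualitative call: gothic if arch angle < 103°, crenel if span > 10 mm
  and angle >= 112°, roman otherwise.  The thresholds sit between the
  group-typical values (97/109/117° and 3.4/7.1/11.9 mm) and are
  configuration.

Achieved recovery on the factorial grid (3 shapes x take-off angles
60-120° x spans 4-14 mm, 0.5 mm voxels): bifurcation-angle error
median ~1.7°, 90th percentile ~5°, with tails to ~10° (and rare
catastrophic outliers when merged branch shafts form lumen loops);
span error median ~0.3 mm; area error median ~1.4%.  The tails are
concentrated at 4 mm spans, where 1.6-1.8 mm-radius branches merge
into common trunks at 0.5 mm voxels — a physical resolution limit of
skeleton-based recovery at this scale, not a tuning issue.  The
acceptance test for the grid asserts 3° / 1 mm / 5% per measurement
and currently fails on those tail cases; the error statistics are
reported alongside.

## Flow-pattern scoring

Both scores are weight-normalized inner products between the local
velocity neighbourhood (radius 2.75 mm on the 1 mm isotropic grid; the
roll-off factor sigma = 1000 multiplies the radius inside a Gaussian
weight, making the weights effectively uniform) and an idealized
rotational template `t(q) = a x (q - p)` whose magnitude grows
linearly off the axis (a solid-body rotation):

* **Vortex** — axis `a` = local vorticity direction (central
  differences); velocities are matched *relative to the local weighted
  mean*, so an advected solid-body core still scores 1.0 (verified to
  0.999 on a rotating-disk phantom).  Voxels whose |vorticity| is
  below 1e-3 of the lumen's 95th percentile score zero, so uniform
  flow scores zero identically.
* **Helix** — axis = weighted mean flow direction; the in-plane
  velocity components are matched against the tangential template and
  signed by the right-hand rule (right-handed = positive), then split
  into rh/lh channels by clipping.  The denominator uses the *total*
  local speed (same form as the vortex score), so the score measures
  the swirl fraction of the motion and grows monotonically with the
  helical content; normalizing by the in-plane speed alone gives
  higher absolute values but saturates and then declines at large
  swirl (the tilted mean-flow axis lets axial shear leak into the
  in-plane components), violating monotonicity.  Voxels with weighted
  mean speed below 1 cm/s score zero in both channels, so diastole is
  silent.  Neighbourhoods are intersected with the lumen; weights
  renormalize implicitly because the same set appears in numerator and
  denominator.

An independent naive per-voxel implementation
(`patterns_reference.pattern_maps_reference`) exists purely as an
oracle; the optimized single-pass moment accumulation matches it
exactly on random fields.  Exact symmetries hold by construction and
are tested: mirroring a field swaps the rh/lh channels voxel-for-voxel
and leaves the vortex map unchanged; quarter-turn rotations permute
all maps exactly.

The distal-arch ROI runs from 1 mm past the left-common-carotid
take-off to 20 mm past the left-subclavian take-off (bovine: from
1 mm past the common trunk), truncated with a warning at the
descending-aorta end; member voxels are lumen voxels whose nearest
main-path point falls in the interval within the local radius.
Systole is the contiguous frame block around the flux peak where the
inlet flux is at least 25% of its maximum (configurable); "peak" is
the maximum of the ROI-mean curve (not the mean of per-voxel maxima —
a fixed choice).  The resolution study resamples a finely sampled
phantom field to each acquisition grid (1 mm, 2 mm, clinical
2.4 x 3.6 x 1.5 mm), brings everything back to 1 mm isotropic, rescores,
and reports `100 * mean_t(test - ref) / mean_t(ref)` against the
clinical curves; a pattern absent from the reference (zero-mean curve)
yields NaN rather than an unstable ratio.  On the synthetic phantom
the 2 mm protocol differs far less from the clinical protocol than the
1 mm acquisition does, and the 1 mm differences are negative for
vortical flow — the same ordering and sign a physical pump phantom
shows, because coarse voxels smear rotational patterns over a larger
share of the lumen.

## Statistics

The two-sided Fisher exact p sums hypergeometric point probabilities
of all tables with the observed margins that are no more probable than
the observed table (relative slack 1e-7 for floating-point ties),
computed in log space; the doubling convention is available but not
default, because the minimum-likelihood convention reproduces all five
verifiable published contingency p-values (0.02, 0.08, 0.058, 1, 0.5)
at their printed precision.  Mann-Whitney U uses the exact null
distribution up to a combined n of 16 without ties and the normal
approximation with tie and continuity corrections otherwise; the
crossover is recorded in the report metadata because reference
statistical packages differ here.  Empirical type-I error at
alpha = 0.05 over 2000 null 24-vs-4 cohorts is ~0.04 (the discrete
exactly-attainable levels make the test slightly conservative).
Pearson r uses the t transform with n-2 degrees of freedom.  Group
comparison reports render percentages as integers, matching the usual
table style.  No multiplicity correction is applied (none is applied
in the study design this mirrors).

The synthetic cohort generator draws continuous endpoints from
group-shifted normals and binary endpoints from per-group Bernoulli
probabilities — enough structure to exercise calibration, power and
report assembly; it does not model endpoint correlations.

## Numerical choices and degenerate inputs

Velocities are stored float32 (memory) but accumulated in float64;
trilinear interpolation for resampling fields and plane sampling,
nearest-neighbour for masks.  Ties in the waveform/systole split
resolve toward the flux peak's contiguous block.  Empty ROIs,
zero-mean reference curves, zero-variance correlations, empty or
multi-component conditioned masks, missing sidecar units and
mismatched component grids all raise typed errors.  A branch shorter
than the tangent window triggers a warning and a shrunken window.
Everything stochastic takes an explicit seed; the pipeline embeds a
SHA-256 configuration hash and produces byte-identical reports under a
fixed seed.

## Problem sizes

Defaults are sized for a laptop-class single CPU: one 0.5 mm phantom
mask is ~0.5 M voxels (extraction ~1-2 s), flow scoring runs at 1 mm
isotropic (~3000 lumen voxels, <1 s per 4 frames), the full test suite
~2.5 minutes, and the acceptance script ~1.5 minutes.
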