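# Methods

This note documents the models implemented in `cardioquant`, the design
choices made where the design was genuinely open, and what the synthetic
data generators do and do not emulate.

## Units and conventions

Physical millimetres (voxel-centre convention) for space, milliseconds
from the R-wave for time, m/s for velocity internally (VENC is accepted in
cm/s, the console unit), mL for volumes, µJ for kinetic energy, ml/g/min
for myocardial blood flow. A periodic time axis (frame after last = first)
exists only in the synthetic phantoms and is never assumed for measured
data.

## The LV flow phantom

The phantom supplies what the flow-component analysis assumes and nothing
more: a closed blood pool with exactly two orifices, a known volume curve
and oracle-computable pathline ground truth.

**Geometry.** A half-ellipsoid chamber (transverse radius `a0` = 33 mm by
default) below a fixed base plane, with two disjoint disks on the base
plane acting as mitral and aortic orifices (radius 14 mm, centres ±16 mm
from the long axis). The long-axis depth is calibrated by bisection so the
voxelised cavity hits the requested EDV to within one voxel (the chamber
centre is deliberately offset from the voxel lattice in y so the voxel
count grows in steps of 1–2 during calibration). Contraction is
self-similar scaling about the base centre, s(t) = (V(t)/EDV)^(1/3).

**Volume curve.** Diastole holds a raised-cosine E wave, a zero-flow
diastasis gap, and a raised-cosine A wave (default durations 0.22 T and
0.18 T, E:A volume ratio 1.5). The curve is made *time-symmetric*,
V(t) = V(T − t): end systole falls at half cycle and ejection is the
mirrored time-reverse of the biphasic filling. This is deliberately
unphysiological (real ejection is a single earlier wave); it buys an exact
conservation structure — see below.

**Interior flow.** For each systolic frame a discrete Neumann problem
∇²φ = 0 is solved on the cavity voxels (finite-volume 7-point Laplacian,
sparse direct solve): wall faces carry the wall (scaling) velocity, the
active orifice carries a uniform plug sized so the discrete fluxes balance
exactly, and v = ∇φ at cell centres. Around the cavity, a shell of
"myocardium" carries the wall velocity (as tissue voxels do in measured
phase-contrast data), a plug column continues each active orifice above
the base plane, and an image (reflected) layer above the closed part of
the base plane enforces zero normal velocity at the wall — plain
zero-padding there would let interpolation leak particles through a closed
valve. Diastolic frames are the exact mirrored time-reverse of systolic
ones: v(x, y, z, T − t) = (vx, −vy, −vz)(−x, y, z, t).

**Why the mirror symmetry.** Backward tracing from end diastole is then
the exact mirror image of forward tracing, so the entered-blood volume
(direct + retained inflow) equals the ejected volume (direct + delayed
ejection) *identically*, not merely approximately — the phantom satisfies
the same conservation a periodic heartbeat must, and floating-point noise
on the order of 10⁻¹³ mm is the only deviation. Without the symmetry, two
independent voxel-counting errors of a few voxels each would separate the
two stroke volumes. `n_frames` must be even so end systole is a frame.

**Ground truth.** Component labels and E/A inflow phases come from a
fine-step reference integrator: the production RK4 tracer run at 1/20 of
the frame interval. Halving that step changes no label (tested). For the
duct (uniform field, x(t) = x0 + vt) and rigid-rotation phantoms the
oracle labels equal closed forms exactly. The rotation phantom snaps its
angular rate to a whole number of revolutions per half cycle by default,
so every particle's end-systolic position coincides with its seed voxel
centre and membership is decided away from the voxelised rim; pass
`snap_revolutions=False` for the literal rate.

**What the phantom does not emulate.** Velocity noise and aliasing,
trabeculae and papillary muscles, torsion, valve leaflets, atrial anatomy
(a plug column stands in for each upstream/downstream compartment),
realistic systolic timing (ES at 50% R-R instead of ~35%), and nonzero
flow at the ED frame itself (inflow ends exactly at the cycle boundary, so
end-diastolic KE is ~0 by construction; KE comparisons on the phantom are
most informative at the wave peaks). Passing tests therefore demonstrate
correct geometry handling, integration, conservation and classification —
not robustness to measurement noise.

## Pathline tracing

Classical fixed-step RK4 with trilinear spatial and linear temporal
interpolation; `substeps_per_frame` = 4 by default (doubling changes no
component label on the phantom). Steps never straddle a frame boundary,
where the interpolated field is only C⁰. RK4 is exact for uniform fields.
The field is defined by interpolation between voxel centres, so a
trajectory passing the outermost centre plane has left the data; it is
frozen there and flagged `left_fov`.

Surface crossings of the ED blood pool are detected at substep resolution
by containment flips and localised by bisection (~25 iterations) on the
straight substep segment. A crossing is attributed to an orifice when it
falls within the disk radius plus one voxel in-plane and within 1.5 voxels
of the disk plane — the interpolated jet edge is about one voxel wide and
localisation is half-voxel accurate; anything else is a wall crossing.
Wall crossings mark the pathline `exited_wall` (components are only ever
assigned to QC-valid pathlines). The dataset verdict is FAIL above a 5%
invalid fraction; no standard threshold exists, so the value is exposed in
`TraceConfig`.

## Flow components

Membership at each end systole uses voxel-centre containment of the
recorded ES position in the corresponding ES mask. Component volumes are
sums of the per-pathline volumes attached at seeding (one voxel each,
never rescaled), so the partition of the EDV is exact by construction.

Mid-diastole is the diastolic frame interval with the *fewest* pathline
crossings of the mitral valve plane, ties broken toward the earlier frame.
The alternative reading — the frame where the geometric line of
intersection with the valve plane is shortest — is noted but not
implemented; the crossing-count reading is the one that yields a unique,
computable frame on data with a detectable diastasis. Retained inflow is
split with the same mid-diastole frame as direct flow. Inflow pathlines
without a recorded valve crossing (wall-adjacent blood whose entry is lost
at mask resolution, a few percent of inflow) are phased by their first
frame inside the ED mask, with a summary warning. Empty components report
volume 0 and no KE entry (never 0/0).

KE of a pathline at a frame is ½ ρ V |v|², with ρ = 1060 kg/m³ and the
velocity sampled from the field at the recorded position; a 27 mm³ voxel
at 1 m/s carries 14.31 µJ.

## ASL forward model

A single mid-ventricular short-axis slice: bright cavity (signal 1800),
myocardial ring (M0 = 1000, inner/outer radius 18/26 mm at 2 mm pixels),
dim background. The tagged image subtracts the perfusion-weighted
difference ΔM = 2 M0 TI e^(−TI/T1) · MBF/60000 over the ring (TI = R-R
interval, default 1000 ms; T1 = 1650 ms). Noise-free, the quantifier
inverts this exactly — the round trip is machine-precision.

**Physiological noise mechanism.** Every acquired image (controls and tags
independently) is rigidly displaced in-plane by a Gaussian shift whose
standard deviation scales with the acquisition window — motion during a
longer readout corrupts the snapshot more. Displaced anatomy sampled by
the static analysis mask makes control/tag pairs inconsistent, which
propagates into pair-to-pair MBF fluctuation. The default amplitude,
0.646 mm at the 307 ms reference window, is the value at which the
reference protocol's mean estimated PN sits at 0.20 ml/g/min (calibrated
once over 1000 replicates with `calibrate_motion_amplitude`; it is an
*effective* parameter of this simplified anatomy, not a literal chest-wall
excursion). Because the response is linear in the displacement SD, PN
scales essentially with the window length, so halving the window halves
PN (a ~50% reduction); the direction and approximate size of the
acceleration benefit follow, and the accelerated protocol wins in ≳99% of
paired replicates. Motion also biases mean MBF slightly low (part of the
ring's ΔM leaves the static mask), and less so under acceleration — so the
accelerated estimate reads slightly higher, the same ordering the
reference-vs-accelerated comparison is designed to tolerate.

**Thermal noise** is additive white Gaussian (default SD 25 signal units),
inflated by √R under SENSE — a g-factor-style SNR loss; noise images
contain thermal noise only. Acceleration is modelled *only* as fewer
acquired lines plus this inflation; aliasing and unwrapping are out of
scope.

## MBF quantification and noise decomposition

Polar resampling takes the mean myocardial signal in 60 angular bins;
empty bins are flagged missing, never interpolated. The spatiotemporal
filter is a wrapped angular boxcar (missing bins excluded from the
window); filtering is applied per pair and segment values are averaged
across pairs afterwards (filter-then-average; the alternative order is not
distinguishable from the published configurations). Global = 1 segment
with the 2π filter; regional = 6 segments with π/3; septal = 3 segments
with 2π/3 restricted to the septal half of the ring (a config value,
default angles π/2–3π/2). Segment means are equivariant under rotation by
whole segment widths.

Thermal noise TN is the noise-image pixel SD propagated through the bin
averaging and the quantification equation into ml/g/min, divided by
√n_pairs; total temporal noise is the sample SD of the per-pair global MBF
over √n_pairs; PN = √max(0, σ_t² − TN²), clamped at zero. With one pair,
segments are still quantified but noise estimation raises.

## Protocol timings

Temporal resolution of the segmented cine phase-contrast sequence is
n_encodes × k_seg × TR; three-directional encoding needs four acquisitions
per line, and 4 × 2 × 6.3 ms = 50.4 ms. The ASL acquisition window is
⌊lines/R × TR⌋ = 307 ms (R = 1) or 153 ms (R = 2); the total imaging
window adds a single lumped 133 ms overhead for fat saturation and the
flip-angle ramp, giving 440/286 ms — the ramp alone (19 TR ≈ 61 ms) does
not account for the overhead, so it is one config value rather than
itemised.

## Problem sizes

The default test and acceptance runs use the full-size phantom (6629
pathlines, 30 frames, ~25 s including the fine-step oracle), a 60 mL
variant for the heavier parametric checks, and 200 paired Monte-Carlo
replicates for the ASL noise comparison (~10 ms per simulated series at
64×64 pixels). All randomness is seeded; phantom construction is
deterministic.

## Known limitations

Regional (π/3-filter) MBF from a single six-pair series is
noise-dominated at the calibrated motion level and can go negative — the
global estimate is the robust quantity, as the filter hierarchy implies.
The PN/TN decomposition assumes motion and thermal noise add in
quadrature and that noise images capture the thermal level exactly. The
flow pipeline assumes the ED segmentation is already resampled to the flow
grid (`resample_mask` is provided); ES frame indices must be supplied by
the phantom or caller. Measured-data concerns — phase wraps, background
phase, navigator gating, manual segmentation variability — are outside the
package's scope.
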