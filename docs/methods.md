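# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, what the phantoms do and do not emulate,
and the design decisions taken where the clinical workflow leaves the
computation under-specified.

## Coordinate conventions

All world coordinates are RAS+ millimetres; voxel indices are 0-based and
the voxel-to-world affine follows the NIfTI convention.  DICOM series are
converted from LPS on read and back on write; slices are assembled by
sorting ImagePositionPatient projected on the volume's slice normal, and
tied positions are an error rather than a guess.  Rigid transforms are
4×4 homogeneous world-to-world matrices, validated to have an orthonormal
rotation block with determinant +1 (tolerance 1e-6).

## Rigid registration

Each modality is registered directly to the T1 base volume with a 6-DOF
transform maximizing mutual information, computed in bits from a joint
intensity histogram (default 32 bins; intensities winsorized at the
[0.5, 99.5] percentiles first, so CT metal and MRI bias tails cannot
dominate the binning).

The optimizer is two-stage and fully deterministic:

1. a coarse Mattes-MI gradient-descent line search over a shrink-4/shrink-2
   pyramid (regular-grid 50% metric sampling, ≤100 iterations per level,
   convergence 1e-6 over a 5-iteration window), which reliably lands
   within ~1–4° and ~0.1 mm of the optimum from initial offsets of
   ±10 mm / ±10°;
2. a derivative-free Powell refinement of the six parameters at full
   resolution against the package's own joint-histogram MI (48 bins,
   ≤200 metric evaluations, parameter tolerance 1e-3), rotating about the
   fixed volume's centre so rotation and translation stay decoupled.

If the final transform scores lower MI than the identity initialization,
the identity is returned with `converged=False` — registration never
silently makes alignment worse.  On the 64³ T1 phantom this recovers 20
random rigid perturbations to worst-case 0.05 mm / 0.18°.

Post-operative MRI is registered with `mask_zero_fixed=True`, which drops
zero-intensity fixed voxels (the resection cavity) from the metric.

Derived statistical maps are moved with `transfer_map`, which resamples
with exactly the carrier volume's matrix; the output is bit-identical to
`resample` with that matrix, and a grid mismatch between map and carrier
is an error.  Resampling itself is scipy `affine_transform` (linear for
images, nearest for masks/labels, zero fill outside the field of view),
so a stored transform reproduces a registered volume exactly.

## SISCOM

The standard normalize–subtract–z procedure: both perfusion volumes are
scaled to mean 100 within a brain mask, subtracted (ictal − interictal),
and standardized against the masked difference distribution itself; z is
clamped to 0 outside the mask.  Suprathreshold clusters use
26-connectivity and a minimum size (default 5 voxels); thresholds 1.5 and
2 are the usual working values.  Choices the clinical description leaves
open, flagged as assumptions: the brain mask defaults to an Otsu
threshold on the base T1 plus largest component and hole filling, and an
optional Gaussian pre-smoothing (FWHM in mm, default 0 = off) is exposed
for noisy camera data.  A zero-variance difference (identical inputs) is
a degenerate-input error, not a silent all-zero map.

## Talairach proportional grid

The frame is built from AC, PC and a midsagittal point: y runs along
PC→AC, z is the component of AC→MS orthogonal to y, x = y × z; VCA and
VCP are the planes through AC and PC perpendicular to the AC–PC line.
The bounding box is supplied as six positive extents from AC along the
frame axes (the posterior extent must exceed the AC–PC distance so the
posterior bound lies behind VCP).

Fixed by the grid definition: 4 even sectors between VCA and the anterior
bound, 4 between VCP and the posterior bound, a single undivided sector E
between the commissures, 8 even level bands above the AC–PC plane, 4
below, 4 even columns per hemisphere from the midsagittal plane outward.

Open conventions, chosen here and configurable via `GridConventions`:
letters run A (most anterior) → D (abutting VCA) and F (abutting VCP) →
I (most posterior); levels number 1 at the vertex through 12 at the
deepest band, matching the original atlas's lettering and vertex-down
numbering.  Band edges are half-open with the edge nearer the AC–PC
plane / VCA inclusive, so AC itself is deterministically E8a; a point
exactly on the midsagittal plane is assigned to the right hemisphere.
Points outside the box get an `in_grid=False` flag, never an exception.

## Trajectories and vessel clearance

Trajectories are straight entry–target segments.  Clearance is the exact
minimum distance from the segment to any vessel-mask voxel centre, which
bounds the true surface distance to within half a voxel diagonal; the
minimum over the first 15 mm from the entry is reported separately
because entry-zone vessels are the dominant hemorrhage risk.  The
pass/fail clearance threshold (default 3 mm) is a toolkit default, not a
clinically validated safety margin — review it per case.  Expected
contact positions are spaced from the target outward
(index 1 deepest, the prevailing SEEG convention).  Entry and target may
also be given as Talairach cells, resolved to cell centres.

## Contact localization

Candidates are 26-connected components of the post-implant CT above a
threshold — absolute when the CT calibration is known (metal sits well
above bone; the phantom uses 1200 against bone at 1000), else the 99.9th
intensity percentile.  Components large enough to hold several contacts
are split at 3D local intensity maxima separated by at least 0.7× the
nominal contact spacing, with voxels partitioned to the nearest maximum.
Each candidate's centre is the intensity-weighted centroid of the
component's top-20% brightest voxels — the "centre of maximal intensity"
made robust to ties and bloom.  Assignment is per-candidate greedy
nearest-trajectory within a tolerance (default 4 mm; adequate because
electrodes are far apart relative to it — a documented limitation, not a
global matching).  Ordering along the axis breaks ties by distance to the
axis, then lexicographically, so naming is deterministic and independent
of candidate input order.

The few-voxel centroid quantizes: on the implant phantom the mean
localization error is ~0.36 voxel with rare per-contact excursions to
~0.6 voxel, so accuracy guarantees are stated on the mean.

## Resection masks

"Interactively drawn" pass markers become a scriptable contract: ordered
markers grouped into strokes.  The mask is the union of brush spheres
(default radius 2 mm) at each marker and capsules along consecutive
markers of a stroke, closed morphologically with a ball of half the brush
radius to fill inter-stroke gaps — both radii configurable.  The "voxel
mesh" is literal: exposed faces of boundary voxels emitted as outward
quads in world mm; for hole-free masks every edge is shared by exactly
two faces.  Containment is voxel lookup at the point's containing voxel.
Burned exports set masked voxels to `marker_intensity` × the volume's
global maximum (default 1.2, shared with point/line burning), which keeps
annotations strictly brighter than anatomy for any modality and lets a
single re-threshold recover the mask (Dice ≥ 0.99 on random marker sets).

## Phantoms

The generators are geometric, not anatomical: every operator above
depends only on geometry, intensity contrast and noise, so concentric
ellipsoids suffice and keep the suite fast.  The T1 head is an
anisotropic brain ellipsoid (semi-axes 0.30/0.36/0.26 of the field of
view — deliberately unequal so rigid rotations are identifiable from the
contour) with a skull shell, a cortical intensity band, anteriorly offset
ventricles, and Gaussian noise (σ = 2); AC/PC/MS truth is recorded with a
23 mm inter-commissural distance (adult mid-range).  Perfusion pairs are
brain-proportional activity (cortex 200, white matter 150 counts/voxel)
smoothed to camera resolution, with focal multiplicative changes applied
to the ictal volume before Poisson noise.  The implant CT renders each
contact as a 1.5 mm metal bead with a linear partial-volume ramp,
composed across beads by maximum (metal does not add), with lateral-only
sub-voxel jitter (σ = 0.2 voxel perpendicular to the shaft — the shaft
fixes axial spacing).  Vessels are smooth spline tubes with exact
centerline truth.

Default problem sizes: 64³ at 2 mm for T1/SPECT-scale work and 102³ at
1.25 mm for the implant CT, so each acceptance property runs in seconds
to a few minutes on one core.  What passing these tests does **not**
show: robustness to MR bias fields, CT beam hardening, partial-volume
effects at real tissue interfaces, brain shift after implantation, or
anatomically realistic perfusion patterns — the phantoms probe the
geometry and statistics of the operators, not scanner physics.

## Pipeline

`run_case` composes the stages in fixed order (registration → SISCOM →
grid → trajectories → contacts → resection); it adds no computation and
takes no clinical decisions.  Absent modalities are skipped with a log
line; a failing stage is recorded while independent stages still run; a
missing base T1 is fatal.  Every artifact is listed in `manifest.json`
with stage, inputs, parameters and SHA-256, and outputs are
byte-reproducible for a fixed configuration and seed (DICOM exports use a
fixed content timestamp for this reason).  Logs are plain text plus a
JSON event stream.

## Known limitations

Deformable registration, inter-subject normalization, subdural grid
geometry, brain-shift correction, automated trajectory optimization,
electrode-collision checks and atlas label lookup are out of scope.
Contact assignment is greedy per candidate; crossing electrodes closer
than the assignment tolerance would need global matching.
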