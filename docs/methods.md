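# Methods

## Scope and design

`dentct` quantifies mineralization phenotypes of single-rooted primary
teeth from calibrated μCT volumes and stained 2D sections.  Because real
patient scans of this kind are rarely shareable, the package pairs every
measurement operator with a synthetic phantom generator of known ground
truth; the test suite and the acceptance script validate the pipeline by
parameter recovery on those phantoms.  What recovery on phantoms shows —
and does not show — about real data is discussed at the end.

## Conventions

- Arrays are (z, y, x) with isotropic voxels; the axial index increases
  **coronally** (slice 0 at the root-apex side).  All slice ranges are
  half-open and 0-based; μm extents convert to slice counts by ceiling
  division, so ROI sizes are bit-reproducible.
- Densities are hydroxyapatite-equivalent mineral densities in mg/cm³
  HA.  Window semantics are fixed so adjacent windows partition the
  density axis: enamel strictly > 1600; dentin closed [650, 1600];
  interglobular strictly < 650; cementum candidates closed [450, 1050];
  pulp strictly < 450.  Every mask records its thresholds verbatim.
- The ROI builders (`build_crown_roi`, `build_root_roi`) are pure index
  arithmetic with a signed `direction` argument (+1 means the ROI
  extends toward increasing indices); the oriented pipeline uses
  direction +1 for the crown (coronal) and −1 for the root (apical).

## Calibration

The grey → density model is affine, fitted by ordinary least squares
over rod mean grey values of a multi-density standard (≥ 2 rods, 5 in
routine use).  Linear HA calibration is the μCT densitometry
convention; no beam-hardening or scatter correction is attempted.
Degenerate inputs (identical greys or identical densities) are rejected
rather than fitted.  On noiseless standards the round trip is exact to
machine precision with r² = 1, which the acceptance script verifies.

## Landmarks

The CEJ is the first slice, scanning from the root toward the crown, on
which enamel forms a topologically complete ring.  "Complete ring" is
operationalized as: the slice background (4-connectivity) splits into
inside and outside, where the inside is the background component at the
enamel centroid and must not touch the image border.  Anchoring the
inside at the centroid makes the test robust to pinholes — single
sub-threshold noise pixels enclosed by a partial enamel arc would
otherwise count as an "inside".  The apical extension of enamel is the
most apical slice containing any enamel voxel.

Landmark detection on noisy volumes runs on masks cleaned by removing
3D connected components below 27 voxels: at noise levels around
sd 100 mg/cm³, isolated dentin voxels cross the 1600 threshold at rates
near 3·10⁻⁵ and would otherwise relocate the apical-enamel landmark by
millimeters.  Real anatomy forms single large components and is
unaffected.  With cleaning, landmark recovery on phantoms is exact
without noise and within the slice-quantization error (≤ 2 slices) at
noise sd 100.

Orientation aligns the estimated root axis (principal axis of the
foreground voxel cloud, signed so enamel lies coronally) with +z by a
single rigid rotation and trilinear resampling; with explicit landmarks
the supplied axis is used and the mesial–distal CEJ chord is optionally
rotated into an axial plane.  A 10° tilt is recovered to well under 1°
on phantoms, and re-orientation is idempotent up to interpolation.

## Regions of interest

- Crown: the 0.5 mm (ceil(500/voxel) slices) coronal of the CEJ,
  including the CEJ slice.
- Root dentin: skip ceil(150/voxel) slices apical of the apical enamel
  extension, then span ceil(500/voxel) slices.
- Cementum: scanning coronally from the apex, the first run of at least
  25 consecutive slices on which cementum forms a complete ring, capped
  at the 50 most apical such slices.  The 25-versus-50 choice in
  practice depends on how much root structure remains; the greedy
  most-apical rule used here is one deterministic reading of that
  judgment call.
- Dentin zones (within the root ROI): mantle = dentin within 150 μm
  Euclidean distance of the outer dentin surface, with cementum
  excluded from dentin but counted as exterior; proximal pulpal =
  within 150 μm of the pulp surface; circumpulpal = remainder.  When a
  thin wall makes the shells meet, the mantle assignment wins and the
  overlap is flagged (`DentinZones.overlap_resolved`) — the outermost
  anatomy is never diluted.  Distances are computed by Euclidean
  distance transforms on the ROI crop, whose masks span the crop
  axially so the cut faces introduce no artificial surfaces.  The three
  zones partition the ROI dentin exactly on every input.

## Segmentation details

Cementum follows a filter-and-mask-back procedure: an 11-voxel median
filter (volumetric by default; a per-slice 11×11 mode is available and
is what the batch pipeline uses, the sheath being axially invariant at
the scales simulated), the 450–1050 window on the filtered volume,
removal of candidate components adjacent to the pulp cavity (the
automated surrogate for manually excluding softer dentin highlighted
next to the pulp), then intersection with original-volume density
> 650.  All quantification downstream uses original, unfiltered
densities.  An empty result warns rather than errors: aplastic cementum
is a real phenotype.

Interglobular dentin is the sub-650 volume inside the crown dentin
*territory*: the ROI dentin mask with internal cavities closed.  Two
operations build the territory — 3D hole filling (captures enclosed
voids) and a morphological closing with a 35 μm ball (recovers voids
cut by the ROI faces, which hole filling would treat as open; the crop
is edge-replicated axially first so the closing sees continuing
anatomy).  Sub-650 components that span the whole ROI axially are the
open pulp chamber/canal and are excluded; voids never span the ROI.

## Local thickness

Thickness is the model-independent maximal-inscribed-sphere measure:
`Th(y) = 2·max{ρ(x) : |x−y| < ρ(x)}`, with ρ the Euclidean distance
map.  The implementation iterates candidate radii in descending order
and marks, at level r, all unassigned voxels whose distance to
`{ρ ≥ r}` is below r.  Two exact reductions keep this fast: levels are
restricted to radii attained on the distance ridge (spheres contained
in a neighbor's sphere can never be a voxel's maximal cover), and each
level's distance transform is cropped to the unassigned bounding box
grown by r.  The result is bit-identical to an exhaustive all-spheres
brute force (shipped as `local_thickness_bruteforce` and used as the
in-test oracle) on every mask tried, and the test suite asserts exact
map equality on structured and random masks up to 40³.

Edge convention: faces where the mask reaches the array border are
treated as the structure continuing through the cut (no background
pad), so an ROI slab of a dentin wall measures the wall, not the slab
height; free faces get a one-voxel background pad.  The oracle shares
the convention.

Digital discretization biases the mean by up to about one voxel
(spheres are strict-interior digital balls); this is accepted and
reported rather than corrected, and analytic solids (spheres, cylinder
walls) are recovered within one voxel in the tests.  For large noisy
masks an optional `level_merge_tol` (0.45 voxels in the batch pipeline)
merges nearby radius levels; the result then never overestimates and
underestimates by well under a voxel on average, which cancels in the
case/control ratios the pipeline reports.

## Histomorphometry

The mineralized area fraction of a section is the dark-pixel percentage
after binarization — mineralized dentin stains dark, so interglobular
area is the complement.  The interactive histogram-threshold step of
manual image analysis is replaced by a deterministic Otsu threshold
with an explicit numeric override; reproducibility is preferred over
fidelity to an undocumented hand adjustment.  Band-layer thickness
(predentin, cementum) is twice the medial-axis distance of the labeled
band mask, equivalent to boundary-to-boundary distances along local
normals for band-like regions and robust to curvature; non-band masks
(no opposing boundary) are rejected.  Replicate sections (n = 3 per
tooth in routine use) summarize as the arithmetic mean.

## Cohort statistics

The statistical layer is deliberately descriptive: per metric, a
control reference band, per-tooth (default) or per-patient
classification against it, and case/control fold or percent changes.
No hypothesis tests are computed.  The band defaults to the 95% t-based
CI of the control mean — consistent with shading one band per metric —
with a population-style mean ± 1.96·SD band available
(`interval_mode='sd_band'`), since with a handful of control teeth the
two readings differ materially.  Classification uses closed bounds: a
value exactly on the limit is "within".  Fold change against a zero
control mean is refused with guidance to report the absolute
difference.

## The phantom as study conditions

The tooth is a solid of revolution: a cone-tapered root (taper factor
0.8 apex/cervix, open apex) around a 0.1 mm-radius pulp canal, a
cylindrical crown with a 0.2 mm enamel shell and cap, a 0.4 mm dentin
wall, and a 200 μm cementum sheath; 10 μm voxels; ~1.2 mm root and
~0.8 mm crown so a default volume is about 220×161×161 voxels.  Default
densities (enamel 2000, dentin 1200, cementum 900, pulp 200, background
0 mg/cm³ HA) sit centrally in the segmentation windows; they are
generator choices, not claims about real tissue.  Noise is additive
Gaussian in grey units before calibration.

Interglobular voids are non-overlapping spheres (20 μm radius by
default) placed by seeded rejection sampling wholly inside dentin (a
one-voxel guard keeps them off the pulp and enamel interfaces), within
the cervical 0.5 mm of crown dentin — the same axial window the crown
ROI measures — so the requested fraction and the measured fraction
share a denominator.  Placement accumulates spheres until the target
voxel count is reached, which makes the realized fraction exact to one
sphere and the void set for a smaller fraction a strict subset of that
for a larger fraction at the same seed (the monotonicity the tests
assert).  Saturation (high fractions, random sequential adsorption
limit) warns and records the realized fraction instead of looping.
Identical spec + seed yields bit-identical volumes.

The simulated cohorts apply multiplicative case effects to the phantom
parameters (defaults: dentin density ×0.9, void fraction ×10 over a 1% control
load, cementum thickness ×0.5) with 1% per-tooth density jitter as
biological variability, five control and five affected teeth — a
deliberately small, rare-disease-sized cohort.  The full pipeline
recovers these constructed effects within a few percent (density),
within ~1% (interglobular fold), and within ~12% (cementum thickness
ratio, limited by median-filter erosion of a 10-voxel sheath), and
classifies every affected tooth below the control density CI.

What the phantoms do not emulate: partial-volume blur at interfaces,
beam hardening and scatter, enamel attrition and root resorption,
irregular (non-axisymmetric) anatomy, multi-rooted teeth, and
calcospherite-shaped (non-spherical) hypomineralized regions.  Passing
recovery tests therefore demonstrates the correctness of the operators
and their composition under the stated geometry and noise model, not
robustness to every artifact of real scans; the landmark and
segmentation stages are the ones most exposed to those differences.

## Problem sizes

Validation runs use one ~220×161×161 phantom per condition, simulated
cohorts of 10 such teeth, 40³ oracle masks, and 400×600 px sections —
sizes chosen so the full suite and the acceptance script each complete
in minutes on a single CPU while every stage still operates well above
its discretization scales.
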