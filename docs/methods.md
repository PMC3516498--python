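# Methods

## Coordinate conventions

World coordinates are radiological RAS in mm: x = left→right,
y = posterior→anterior, z = inferior→superior; "ventrodorsal" is the −y
direction. A voxel's world position is its center; volume extents are
half-open intervals. Coronal slices are native grid planes
(nearest-plane rule, never interpolated), with a deterministic dorsal
tie-break when a requested position falls exactly midway between planes.

## Canonical measurement frame

The frame is defined by the most dorsal points of the two orbital
entries: after alignment their connecting line is parallel to the x-axis
and their midpoint is the world origin, so the frame plane (slice 1) is
y = 0. The rotation is the minimal one achieving this (Rodrigues rotation
taking the inter-entry direction onto x̂). Roll about the inter-orbital
axis is genuinely unconstrained by those two points; it is fixed to zero
unless superior/inferior rim landmarks are supplied, in which case the
mean rim axis is made vertical. Landmarks are user-supplied (JSON), not
auto-detected — operators set the view manually in practice, and
automatic orbital-entry detection is a separate research problem.

Rigid resampling uses trilinear interpolation on the source grid with the
source minimum as fill value (so dark fill never masquerades as bone).
The original protocol's interpolation scheme is unknown; trilinear is
this package's choice.

## Slice measurement

Per slice: threshold → close boundary → fill → count.

**Bone threshold.** CBCT intensities are not Hounsfield-calibrated, so no
absolute default is defensible; the threshold is numeric or `"auto"`.
Auto thresholding is a guarded two-stage 2-class (Otsu) split: if the
upper class of the first split is itself clearly bimodal (mode separation
exceeding four times the summed mode spreads — the background/soft-tissue
/bone case), the bone threshold is the midpoint between those two upper
modes; otherwise the first split stands. For a whole measurement the
threshold is computed once from the volume histogram, because deep slices
near the apex can be dominated by a single tissue class. A constant
histogram raises rather than guessing.

**Boundary closing.** The inner boundary of the bone ring around a seed
point is traced by radial ray casting (1440 rays). Rays whose first bone
hit is absent or beyond 1.6× the median hit radius mark wall
interruptions (fissures/foramina). Each maximal open angular run is
bridged by a straight chord between the nearest bony boundaries flanking
it: chord endpoints are anchored at the innermost hits adjacent to the
run, then refined to the mutually nearest bone pixels within a ±4-pixel
window (kept below half the narrowest bridgeable opening so an endpoint
cannot jump to the far flank). A chord longer than `max_gap_mm`
(default 10 mm, covering the orbital fissures at adult scale) raises an
"unclosable contour" error naming the gap size. Chord bridging was chosen
over morphological closing because it is deterministic, parameter-light,
and directly mirrors how interrupted orbital boundaries are closed in
practice. The bridged bone mask is flood-filled 4-connectedly from the
seed (chords are 8-connected chains, which 4-connected flow cannot
cross); interior islands — e.g. an implant cross-section — are filled,
since the measured quantity is the whole bony cavity cross-section, not
the soft tissue around an implant. The region's outer contour is
extracted at the 0.5 level.

**Area rule.** A pixel belongs to the region iff its center is inside or
on the closed contour; the area is exactly pixel count × pixel area, with
no smoothing correction. This makes a brute-force point-in-polygon count
an exact oracle, and the tests use an independent polygon library for it.

**Stack traversal.** Slice 1 sits at the frame plane; subsequent slices
step `interval_mm` dorsally (the protocol default 4.8 mm gives five
slices from frame to apex in an adult orbit; both are configurable, as is
a frame offset). The seed is re-centered on the previous slice's filled
centroid because the cavity drifts toward the apex. A failing deep slice
raises a partial-result error carrying the completed slices.

**Volume.** `interval_mm × Σ areas` — the Cavalieri estimator, exactly.
Slice 1 at the frame plane means the sum is a midpoint-rule estimate of
the slab extending half an interval beyond the first and last slice
planes; phantom checks compare against exactly that analytic slab.

## Statistics

The pairing unit is the (rater, repeat) cell: the operated orbit's nine
measurements per slice are paired with the healthy orbit's same-cell
measurements. This is the only pairing that yields a within-case
per-slice paired t-test at n = 9, and it is stated prominently because
repeated-measures protocols are often ambiguous on this point. The t-test
is the classical paired t (two-sided p from the t distribution with
n − 1 df). Zero variance of the differences leaves t undefined and raises
a distinct degenerate-variance error instead of fabricating p = 0 or 1.

A slice is flagged significant only when p < alpha AND the operated mean
is smaller — the clinical question is volume loss; the two-sided p is
retained. No multiple-testing correction is applied across the five
slices, matching the protocol this implements. Case categories: A iff
flags 1–4 all set (flag 5 free), C iff no flag, B otherwise; patterns
with ≥ 4 flags that are not category A are tagged "atypical" because the
original taxonomy never encounters them.

Rater reproducibility is summarized per (side, slice) as intra-rater CV
(mean over raters of sd/mean across repeats) and inter-rater CV (sd/mean
of rater means).

## Synthetic phantom

The phantom idealizes each orbit as an elliptic cone (closed-form area
`π·a·b·(1 − d/D)²` at depth d; a rectangular pyramid is available as an
alternative shape) so that every downstream number has an analytic
target; the real orbit's four-wall geometry is deliberately sacrificed
for exact ground truth. Defaults are adult orbital dimensions: rim
40 × 35 mm, depth 45 mm, rim centers ±25 mm, voxelized at 0.3 mm
isotropic (CBCT pixel size). The bone wall is a 2 mm shell around the
cavity plus an anterior rim flange (the facial bone surrounding the
orbital entry), which keeps the rim ring intact under trilinear
resampling. Two radial sector openings per orbit (4 mm and 3 mm wide,
spanning 12–38 mm depth) stand in for the inferior and superior orbital
fissures. The field of view leaves ~12 mm anterior headroom so the orbits
stay in view under head rotations up to ~10°; worse-positioned heads are
excluded in practice, not rescued.

Intensities are abstract units (CBCT is not HU-calibrated): background
100, cavity soft tissue 300, bone 1000, plus seeded additive Gaussian
noise (sd 20, keeping a > 5σ margin below bone). An optional implanted
sphere (18 or 20 mm diameter, the common implant sizes) renders at bone
intensity. The grid is placed so the rim plane falls midway between
voxel-center planes — the generic position, under which center-rule voxel
counting of the cavity is unbiased — and x-coordinates come in ± pairs so
a mirror-symmetric spec voxelizes bit-exactly symmetrically.

What the phantom does **not** emulate: trabecular texture, beam-hardening
and scatter artifacts, soft-tissue anatomy (globe, muscles), the true
four-wall orbital shape, and anatomic variability. Passing phantom tests
therefore demonstrates correctness of the measurement chain on known
geometry — not segmentation accuracy on clinical scans.

`make_asymmetric_pair` shrinks one side's rim and depth by a common
factor, emulating post-operative volume loss with an exact `s³` volume
scaling law; the scale-law test measures the shrunken orbit with a
proportionally scaled interval, since the similarity law applies to the
whole measurement geometry.

## Simulated rater tables

The end-to-end pipeline and the cohort simulations build the 3 × 3 rater
table by adding seeded Gaussian noise (default sd 10 mm², about 1% of a
rim-slice area — a realistic magnitude for manual re-tracing) to the
deterministic per-slice measurements, optionally with a per-rater bias
shared across sides (as a human's systematic tracing style would be).
Under symmetry this yields the textbook null: each slice's directional
flag fires at ≈ alpha/2, so a symmetric case classifies C about
(1 − alpha/2)⁵ ≈ 88% of the time — category C dominates control cohorts
but is not certain for any single case, which is exactly the behavior of
five uncorrected tests.

## Problem sizes and numerical choices

Default phantom grids are ≈ 336 × 225 × 151 voxels; simulations use 2000
cases for null calibration and 20 cases per simulated cohort. Ray casting
uses 0.25° angular and half-pixel radial steps. Nearest-plane ties break
dorsally; boundary-pixel membership ties break toward inclusion (center
on the contour counts). The degenerate all-zero-differences t-test is an
error by default rather than a silent t = 0.

## Known limitations

- Landmarks, and hence the frame, are operator input; their placement
  error propagates directly and is not modeled here.
- The apex-side stopping rule is a fixed slice count (default 5), not an
  anatomical criterion; very shallow orbits need a smaller count or
  interval.
- Bilateral inference treats the nine (rater, repeat) pairs as
  independent; rater-specific biases shared across sides cancel in the
  pairing, but correlated tracing errors within a rater do not.
- Whole volumes are compared descriptively only; the per-slice tests
  carry the inference.
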