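# Methods

## Scope and design

`liverseg` implements the correction and evaluation machinery of a cascaded
liver-segmentation workflow while treating the neural segmenters themselves
as pluggable backends. Two backend roles exist: an *initial multi-organ
segmenter* (volume → label mask with at least liver/spleen/stomach) and a
*liver refiner* (edited, cropped volume → liver ± tumor mask). File-based
backends replay masks produced externally by real networks; mock and toy
backends make the whole cascade runnable and testable on synthetic phantoms.
Training, bundling or running actual network weights is out of scope by
design.

## Canonical grid conventions

All grids are `[row, col, slice]`, 0-based, slice axis along physical z
ascending, spacing `(d_row, d_col, d_slice)` in mm. DICOM loading always
applies RescaleSlope/Intercept; MHD and NIfTI are assumed already in HU;
missing spacing metadata is an error, never silently defaulted to 1 mm.
Orientation standardization rotates each axial slice 90° clockwise (viewing
the slice as displayed: first axis down, second axis right) and then mirrors
left-right; the 2×2 pixel permutation `[[a,b],[c,d]] → [[a,c],[b,d]]` pins
the convention, and `destandardize_orientation` is its exact inverse. The
pipeline evaluates in the standardized frame and the inverse is available
for export.

## Correction stage

* Fluid threshold: strict `HU < 15` (defaults; configurable). The mask is
  deliberately *inclusive* of peritoneal fat, gut fluid and aerated lung —
  none of those voxels can be liver, and the knock-out value (−100 HU) lies
  below the threshold, which makes the correction exactly idempotent.
* Opening and the area filter are per-axial-slice 2-D operations (disk
  radius 2; components kept only when strictly larger than 1500 px). The
  area-filter connectivity (8-neighbourhood) and whether 1500 px should be
  resolution-adjusted are open choices; both are exposed as configuration
  with those defaults.
* Organ knock-out happens before the fluid mask is built; knocked-out voxels
  join the fluid mask harmlessly (they are already −100 HU).
* The liver bounding box is the tightest box over the initial liver label,
  margin 0 by default, clipped to the grid; an empty liver label aborts the
  run with a diagnostic.

## Morphology conventions

Structuring elements are digital disks/spheres `{p : ‖p‖₂ ≤ r}` on integer
offsets (disk r=2 → 13 px, sphere r=3 → 123 voxels), isotropic in *index*
space: radii are specified in pixels, so anisotropic spacing is intentionally
ignored by morphology. Out-of-bounds is background for every operation.
One subtlety: closing's intermediate dilation legitimately extends past the
grid; cropping it before the erosion would clip a border band and break
extensivity. Closing is therefore evaluated on the background-padded domain
(pad by the radius, compose, crop), which preserves the out-of-bounds
convention while making closing extensive and idempotent everywhere.
Opening needs no such padding. Default connectivity: 26-neighbourhood for
object selection (8 in 2-D), 6-neighbourhood for hole filling. Component
ordering is by decreasing size with ties broken by the smallest
lexicographic (flat-index) seed voxel, making largest-object selection
deterministic.

## Post-processing stage order

truncate-to-liver-slices → exclude `HU < 0` (strict; 0 HU retained) →
keep-largest (3-D) → per-slice closing (disk 2) → liver+tumor merge →
hole filling → volumetric closing (sphere 3). The prose that motivates these
rules lists them in this order without an explicit diagram; the order is
fixed here, every intermediate can be emitted for audit, and the stage list
is part of the provenance record. Consequence of the order: the closings run
*after* the sub-zero exclusion, so a thin sub-zero rim (fat at the capsule)
can be re-added at the surface — on phantoms this is < 2 % of the mask and
contains no true lung. Re-running the exclusion after the closings would
remove it but would also re-open the dome boundary; the documented order is
kept.

## Metrics

Surfaces are foreground voxels with at least one face-adjacent background
(or out-of-bounds) neighbour; distances are Euclidean between voxel centers
scaled by spacing. ASD and RMSD pool both directed nearest-distance sets
with denominator `|S(A)|+|S(B)|`; RMSD takes the root *after* the mean
(root-mean-square of the pooled distances). Hausdorff is the symmetric
max of the two directed maxima; a directed variant is exposed. Degenerate
cases are pinned: Dice of two empty masks is 1.0 with a warning; VOE of two
empty masks and RVD against an empty reference are errors; surface distances
require both masks nonempty. Welch's t-test uses unequal variances and the
Welch–Satterthwaite degrees of freedom (via scipy); two elementwise-identical
samples return (t=0, p=1) by convention. Summary tables report sample
standard deviations (ddof=1).

The ROC sweep re-runs the *full* fluid-mask construction at each threshold
over the default grid {0, 5, 10, 11, …, 19, 20, 25, 30} HU (1-HU steps
between 10 and 20, 5-HU steps outside), pooling TP/FP counts over scenes.
The operating point maximizes Youden's J = TPR − FPR; ties are resolved to
the smallest threshold (the most specific choice among equals — on noiseless
phantoms J is exactly flat above 15 HU because no tissue has HU in (15, 40)).

## The phantom: what it emulates and what it does not

Default scene: 96×96×64 voxels at 2×2×3 mm — small enough for seconds-scale
experiments, large enough that the fluid region on central slices far
exceeds the 1500 px area filter. Compartments: liver ellipsoid at 60 HU;
spleen (55 HU) and stomach (wall 40 HU, fluid lumen drawn uniform [0, 10) HU)
placed tangent to the liver so contact boundaries exist while truth masks
stay disjoint; lung at −700 HU above the dome; background fat at −100 HU;
ascites drawn i.i.d. uniform [0, 15) HU as a shell within 12 mm of the
liver's lateral surface (spacing-aware Euclidean distance transform),
keeping an 8 mm clearance from the other organs so free fluid pools against
the liver's free surface rather than forming sub-resolution slivers inside
inter-organ contact gaps. Additive Gaussian noise (default σ = 5 HU,
realistic for abdominal CT) is applied globally; generation is
bit-deterministic given the spec's seed.

Mock segmenter failure modes: `bleed_<organ>` grows the liver label into the
named compartment by deterministic 26-connected rings from the liver front
(lexicographic order within the final partial ring) until a `severity`
fraction is claimed; `undersegment` erodes the liver label by a margin
proportional to severity (up to 6 face-connected iterations).

What passing phantom tests does **not** show: the phantom has no anatomical
realism beyond HU regimes and adjacency — no tumors, partial-volume effects,
beam hardening, respiratory motion, or textured parenchyma. In particular,
with σ = 5 HU noise the i.i.d. speckle inside the fluid lets the per-slice
opening erode much of the thresholded region, so the correction removes only
part of the ascites; real fluid is spatially smoother than i.i.d. noise, so
phantom results under noise are a conservative floor for the correction's
effect, and the threshold-recovery and full-coverage properties are stated
on noiseless scenes where the fluid attenuation range is exact.

## Experiments

The with/without-correction design runs the identical cascade twice per
seeded phantom, toggling only the knock-out and ascites stages:

* *ascites mode*: perfect initial segmentation + a fluid-blind toy refiner
  (HU window [−50, 200], largest component within the bounding box) that
  keeps peri-hepatic fluid unless the correction has knocked it to −100 HU;
* *spleen mode*: an initial segmentation that bleeds 40 % into the spleen +
  a parenchyma-window refiner ([20, 200]) that keeps whatever spleen tissue
  was not knocked out.

Corrected runs lower VOE on every seed and raise mean Dice (Welch p well
below 0.05 over 10 seeds). Problem sizes (10 seeds per mode, 5 ROC scenes,
96³-voxel grids) were chosen so the full experiment suite runs in well under
a minute on one CPU.

## Determinism and provenance

Every pipeline run returns a provenance record: config hash (canonical JSON
of all stage parameters and backend descriptions), input hash (voxel bytes),
per-stage voxel-change counts, final-mask hash, and a hash over the record
itself. Wall-clock timings are deliberately excluded so replaying a run
yields an identical provenance hash.

## Known limitations

* Orientation metadata in written NIfTI is a plain diagonal affine from
  spacing + origin; full direction-cosine handling is not attempted.
* No 4-D/multiphase series support; no DICOM writing; no 95th-percentile
  Hausdorff or lesion-level metrics.
* The mock refiners are HU-window heuristics; they exercise the pipeline's
  contracts and failure modes but are not meant to emulate network output
  statistics.
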