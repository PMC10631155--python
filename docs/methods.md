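# Methods

## Problem

Supine MRI deforms the soft tissue of the thigh: with different amounts of
knee elevation the same muscle presents a differently shaped cross-section
to the transverse imaging plane. `jshape` quantifies that effect. For every
slice of a segmented muscle it fits the covariance (moment) ellipse to the
cross-section and scores how elliptical the section is with the **J index**;
per-muscle means of J are then compared between positioning conditions.

## Ellipse fit

The segmented cross-section is the set of foreground pixels of a binary
mask. Each pixel contributes one point at its physical center,
`(index + 0.5) · spacing` (0-based indices). With centroid `μ` and
population covariance `Σ` (divide by N) of this point cloud, the fitted
ellipse is centered at `μ`, its axes along the eigenvectors of `Σ`, and its
semi-axis lengths are

    a = 2·√λ₁,  b = 2·√λ₂    (λ₁ ≥ λ₂ the eigenvalues of Σ).

The scaling 2·√λ is exact for a uniformly filled elliptical lamina, whose
covariance eigenvalues are `a²/4` and `b²/4`; it is parameter-free and makes
the J index of a true ellipse maximal. The source method pins only the
axis *ratio* and orientation to the eigen-decomposition, not the absolute
scale, so an alternative area-matching scaling (both axes rescaled so
`πab` equals the region area; ratio and orientation unchanged) is available
via `ellipse_scaling="area"`, default off.

Numerical choices:

* **Covariance normalisation** is population (÷N), matching the lamina
  identities and `skimage.measure.regionprops`; pinned so the exact oracle
  tests are well-defined.
* **Orientation** is the major-axis angle to the +x (column) axis in
  [0, 180). If the eigenvalues agree within relative 1e−9 (a circle has no
  principal axis) the orientation is fixed at 0°.
* **Degeneracy**: `λ₂/λ₁ < 1e−6` (near-collinear cloud) raises an error;
  fewer than 3 points likewise.
* Membership in an ellipse is the closed condition `(x/a)² + (y/b)² ≤ 1`
  after translation and rotation into the ellipse frame.

## J index

With A the segmented region and E the fitted ellipse rasterized onto A's
own grid by pixel-center membership,

    J = |A ∩ E| / |A Δ E|,

i.e. shared area over the area in **exactly one** of the two regions. This
is not the Jaccard index `|A∩E|/|A∪E|`; the two are monotonically related
by `J = Jaccard / (1 − Jaccard)`. Large J = nearly elliptical.

Computing the overlap on the rasterized grid (rather than with continuous
polygon clipping) matches how the segmentation itself is defined and makes
the arithmetic exact: `|A| + |E| = 2|A∩E| + |AΔE|` holds as an integer
pixel-count identity on every input, which the tests verify literally.

A slice whose segmentation coincides exactly with the rasterized ellipse
has `|AΔE| = 0`; its continuous-limit J is infinite. Such slices carry a
`degenerate` flag, are excluded from per-muscle means (capping them at any
finite value would bias means), and are written to the output tables with
the sentinel `degenerate`.

Discretization consistency: halving the pixel spacing moves the J of a
fixed muscle-scale shape (semi-axes ≳ 20 mm at ≤ 1 mm pixels) by a few
percent. For much smaller regions the symmetric difference is only a few
pixels wide and J converges slowly with resolution — one reason the
pipeline excludes tiny end-of-muscle slices (below).

## Study aggregation

A study consists of three positioning conditions — high (15°), moderate
(12°) and no (8°) knee elevation, the angles being nominal femur-to-plane
angles — and seven thigh muscles: vastus lateralis, vastus intermedius,
vastus medialis, rectus femoris (quadriceps group) and semimembranosus,
semitendinosus, biceps femoris (hamstrings group).

* **Slice inclusion**: slices with fewer than `min_pixels` (default 10)
  foreground pixels are dropped; covariance fits on a handful of pixels at
  the muscle ends are meaningless.
* **Per-muscle summary**: unweighted mean and sample SD (n−1) of J over
  included, non-degenerate slices, per subject. With several subjects a
  pooled row (subject `ALL`) is added: the unweighted mean of subject
  means. Both levels are emitted because either pooled-slice or
  mean-of-subject-means aggregation may be wanted; comparisons are
  reported at both.
* **Percentage change** of a position vs the reference (no elevation):
  `|mean_J − mean_J_ref| / mean_J_ref × 100`. The magnitude is the headline
  number because the shape change can go either way (some muscles become
  more elliptical with elevation, others less); the signed difference is
  retained in the `diff_j` column.

## Goniometer

Knee elevation is quantified as the angle between the anatomical femoral
axis (two user-supplied landmark points in the volume's physical frame) and
the unit normal of the transverse imaging plane (the slice-stacking
direction, (0,0,1) by default):
`arccos(|unit(distal − proximal) · normal|)`, folded into [0°, 90°] so the
landmark order is irrelevant. Landmark placement is manual by design;
nothing detects the femur.

## Synthetic phantom

The generator produces label volumes with the statistical structure the
analysis assumes, so the full pipeline runs and is testable without MRI
data:

* per muscle, a stack of filled elliptical cross-sections whose semi-axes
  follow `(a₀, b₀) · (4s(1−s))^taper` along normalised length `s` (smooth
  taper to the ends, default exponent 0.15) around a gently drifting center
  track;
* a one-sided **chordal flattening**: the fraction `f` of the region's
  y-extent on the low-y (posterior) side is cut away, a D-shape emulating
  surface-contact compression. Chosen over a volume-preserving squash as
  the simplest one-parameter family with checkable geometry whose J index
  provably degrades; a per-slice shape index does not care about volume
  preservation. `f` is capped at 0.45 so the region never empties.
* optional **boundary noise**: pixels within one pixel of the region
  boundary flip with probability `min(0.5, 0.5·sd/spacing)` — segmentation
  jitter that cannot disconnect the interior. Default sd 0.3 mm ≈ half a
  pixel.

The canonical study (`default_study_spec`) uses the acquisition geometry of
the modelled study — 0.65 × 0.65 mm pixels, 3 mm slices — on a 200 × 200
grid with 40 slices, seven schematically arranged muscles (quadriceps
anterior, hamstrings posterior), and the flattening schedule
hamstrings {none 0.05, moderate 0.15, high 0.30}, quadriceps 0.02
throughout. Muscle sizes are scaled-down schematics (semi-axes 10–20 mm)
so seven non-overlapping regions fit a compact grid; the phantom is a
statistical stand-in, not an anatomical atlas. All randomness derives from
one integer seed via `numpy.random.SeedSequence`, spawned per
(position, muscle, slice); identical specs and seeds give byte-identical
volumes, and a YAML manifest records every generating parameter.

What passing phantom tests show — and what they do not: they validate the
geometry and bookkeeping of the method (fits, overlap counts, aggregation,
determinism) and the qualitative study finding built into the schedule
(hamstring shape changes exceed quadriceps changes across elevation). They
do not show that real muscles deform chordally, and the phantom's
percentage changes are larger than those of real thigh MRI, where the
deformation is subtler.

## Problem sizes

The default test and acceptance runs use the phantom at 8–40 slices per
position on the 200 × 200 grid (840 analysed slices for the full canonical
study) and 48–256 px grids for the geometry checks; these sizes keep every
brute-force oracle exact and the whole suite fast while leaving all
statistical structure intact.

## Known limitations

* No statistical inference across subjects is performed (none is defined
  for this design); the outputs are descriptive.
* The denominator convention (symmetric difference) follows the method's
  stated definition; the earlier seed-shape literature the index descends
  from may normalise differently, so J values are comparable within this
  package but not necessarily with other implementations.
* Absolute axis scaling of the fitted ellipse is a documented choice
  (2·√λ default, area-matching optional), since only ratio and orientation
  are pinned by the eigen-decomposition.
* DICOM ingestion, registration and automatic segmentation are out of
  scope; inputs are already-segmented label volumes (NIfTI) or per-slice
  PNG/CSV masks.
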