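# Methods

`segunc` implements the quantitative machinery of a two-condition contour
editing study: radiation oncologists review and edit deep-learning (DL)
segmentations of the prostate CTV and rectum, once without and once with a
voxel-wise uncertainty map overlaid, and the package measures what changed
— in the contours, in the editing effort, in the ratings and in the time
spent.

## Uncertainty map

The DL segmentation is the mean SoftMax probability of a K-member
cross-validation ensemble (default K = 10), thresholded at 0.5 with ties
going to foreground.  The uncertainty map is the voxel-wise *sample*
standard deviation across members (divisor K−1).  For probabilities in
[0, 1] this is bounded by sqrt(K/(4(K−1))) — ≈ 0.527 for K = 10 — so a few
voxels can exceed the 0.5 display maximum.  Stored maps are never clipped;
the PET export clips at `display_max` and records how many voxels it
clipped.  A calibration block of constant value `display_max` is stamped
into the bottom rows of every slice so that all cases share one display
colour scale in the viewing software; its geometry travels with the map
and every downstream analysis excludes it.

The PET DICOM export is a deliberate packaging trick: a modality-PT slice
stack with the caller's FrameOfReferenceUID overlays cleanly on the
planning MRI in a clinical treatment-planning system.  Pixels are 16-bit
unsigned with RescaleSlope = `display_max`/65535 and intercept 0 (linear
full-range encoding), so a round trip reproduces the map within half a
quantization step (≈ 3.8e-6 for the 0–0.5 scale).  The pixel depth and
linear encoding are this package's own contract; display colouring is the
consumer's job.

## Geometric comparison panel

Six metrics per (reference, test) mask pair, all on spacing-aware voxel
grids with axis order (slice, row, col):

- **Dice** 2|A∩B|/(|A|+|B|); defined as 1 for two empty masks.
- **Surface Dice** (normalized surface distance, default tolerance
  τ = 1 mm): surfaces are border voxel centres (a mask voxel with a
  6-connected neighbour outside; the volume edge counts as outside) and
  distances are Euclidean mm under anisotropic spacing.  This voxel-centre
  discretisation is a deliberate simplification of subvoxel surface-mesh
  formulations.
- **Hausdorff distance**: the true maximum of the two directed maxima,
  not a percentile.
- **Average surface distance**: mean over the pooled directed
  surface-distance sets of both masks.
- **Volume difference** (signed, test − reference) and ratio
  (test/reference, undefined for an empty reference).
- **Added path length** (APL, τ = 1 mm): computed slice-wise because
  clinical editing is slice-wise — per axial slice, 4-connected boundary
  pixels of the edited mask farther than τ (2D in-plane distance) from the
  reference boundary are counted and converted to millimetres with the
  mean in-plane spacing; slices without reference contribute their whole
  edited boundary.

Surface metrics on an empty mask are reported as NaN, never coerced to 0.
All six agree with O(N²) brute-force pairwise-distance oracles to 1e-9 in
the test suite.

## Edit histograms

The edit map codes voxels +1 (added), −1 (removed), 0 relative to the DL
mask.  Added and removed voxels are pooled (a split variant exists) and
histogrammed by the *unblocked* uncertainty value in 0.1-wide bins,
half-open with the last bin closed at `display_max` and an explicit
overflow bucket above it; calibration-block voxels are excluded.  Step-1
edits are binned with the same map even though observers never saw it in
step 1 — that is the comparison of interest.  `compare_conditions` reports
the per-bin percent change 100·(c1−c2)/c1, positive when the second
condition holds fewer edits.

## Observer-study statistics

**VGC.**  Paired ordinal ratings (4-point quality for Q1/Q2, 5-point
confidence for Q3; higher ordinal = better) are compared with visual
grading characteristics: for thresholds from the top of the scale down,
plot the fraction of step-1 ratings ≥ t against the step-2 fraction; the
trapezoidal AUC equals the tie-corrected rank statistic
P(r2 > r1) + ½·P(r2 = r1) (property-tested to 1e-12).  AUC > 0.5 means the
second condition was rated higher.  Uncertainty: case-level bootstrap
(default 2000 resamples) with a percentile — hence asymmetric — 95%
interval; significance: a paired permutation test (default 2000
permutations) that swaps the two conditions within each case with
probability ½, two-sided, without add-one correction (so extreme results
can print 0.00).  Both resample cases only; in pooled-group mode a case
carries all its observers' pairs (fixed-reader analysis).  The interface
is a model/results pair (`VGCModel(...).fit() -> VGCResults.summary()`).

**Wilcoxon signed-rank** (editing times; per-metric distributions):
two-sided, zero differences dropped before ranking, exact null for
n ≤ 15 without tied magnitudes, otherwise tie-corrected normal
approximation with continuity correction.  W+ is reported as the
statistic.  Under the null the exact branch reproduces full sign-pattern
enumeration.

**Fligner–Killeen** compares pooled inter-observer spread between the two
conditions per organ and metric: median-centred absolute deviations are
pooled, ranked, mapped to normal scores and compared with a chi-square
statistic on (groups − 1) df.  Both tests hold their nominal 5% type-I
error within (0.03, 0.07) in seeded simulation.

**Volume-ratio outliers** are flagged descriptively outside per-organ
windows (prostate 0.91–1.1, rectum 0.8–1.25, configurable).

No multiple-testing correction is applied by default.

## Synthetic study generator

The generator is first-class code: it defines the study conditions under
which every pipeline stage is validated, with all effect parameters known.

**Anatomy.**  Per case, a prostate-like ellipsoid (radii ~18–24 mm with
smooth radial modulation ≤ 10%) and a rectum-like curved tube (radius
~9 mm) posterior to it, disjoint by construction, on a 64×96×96 grid at
2.5×0.9×0.9 mm.

**Ensemble.**  Member k's probability is
sigmoid((d + η + s·ξ_k)/w): d is the signed distance to the ground-truth
boundary (mm, positive inside, w = 1.5 mm softness); η is a smooth bias
field *shared* by all members (sd 2.5 mm, correlation 16 mm) — systematic
error the ensemble cannot see; ξ_k are independent smooth member fields
(sd 6 mm, correlation 8 mm) scaled by a smooth agreement factor
s ∈ (0, 1) (probit of a sharpened unit field, correlation 16 mm).  The
shared bias makes the ensemble confidently wrong in patches, and the
agreement factor spreads boundary uncertainty over the whole 0–0.5
display range.  Both ingredients are essential: a homoscedastic member
field concentrates all model error where the ensemble already disagrees,
which would leave the low-uncertainty histogram bins empty — the opposite
of what real edit histograms look like, where the 0.0–0.1 bin carries the
most edits.  Field amplitudes were chosen so that, pooled over the
default study, every uncertainty bin collects several thousand step-1
edits (adequate counting statistics for multiplier recovery).  Random
fields are sampled on a padded coarse lattice (two nodes per correlation
length), Gaussian-filtered, cropped to the stationary interior and
trilinearly interpolated, so the field statistics are homogeneous across
the volume.

**Edits.**  Observers edit only within 3 mm of the DL boundary and only
correctively: a candidate voxel that disagrees with the ground truth is
set to the ground-truth label with probability p₀ = 0.05 in step 1 and
p₀·m_b in step 2, where b is the voxel's uncertainty bin and
m = (0.5, 0.8, 1, 1, 1) by default.  The per-bin step2/step1 count ratio
is then an unbiased estimate of m_b, and the default m₁ = 0.5 produces
the headline ≈50% first-bin reduction.  Piecewise-constant multipliers
(rather than a smooth suppression curve) were chosen precisely so the
histogram analysis recovers the parameters exactly in expectation.

**Ratings.**  Latent case quality z_c ~ N(0,1) shared by both steps
(paired design), observer noise sd 0.5, optional per-question step-2
shift δ (default 0), discretised through fixed cutpoints skewed toward
the upper categories (edited DL contours are mostly good).  δ = 0 yields
AUC ≈ 0.5; AUC is monotone in δ.

**Times.**  Log-normal per-case totals (both organs jointly; per-organ
times are not modelled) with per-observer step-1 medians (7, 4.5, 7, 6
min for obsB..obsE) and step-2 multipliers (1.0, 0.85, 0.86, 0.67):
one static observer and three reductions of 15%, 14% and 33%.

Everything derives deterministically from one master seed; the same seed
reproduces the on-disk bundle byte for byte.

## What the synthetic study does and does not show

Passing tests demonstrate that the pipeline's arithmetic is right and
that designed effects of realistic size are recovered at the study's
scale (35 cases, 4 observers, 10 members).  The generator does not
emulate MRI intensities, deformable or correlated anatomy, observer
fatigue or learning, rater-specific editing styles, or spatially
clustered edit strokes; real-data effect sizes and variances need not
match the defaults.  Conclusions about any particular clinical dataset
require that dataset.

## Numerical choices and scale

Grid compatibility tolerances: 1e-6 mm on spacing, 1e-3 mm on origin
(clinical headers carry rounded floats).  Threshold ties go to
foreground.  Histogram bin width must divide the display maximum within
1e-9.  Degenerate inputs (empty masks, all-zero paired differences,
unpaired cases) are reported as NaN / p = 1 / exclusions with counts,
never silently dropped.  The test suite runs the full default study once
(≈ 1.5 min) plus oracle and calibration simulations (1000 replicates
each); the acceptance script re-runs the default study end to end in
about the same time.
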