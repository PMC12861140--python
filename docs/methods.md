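# Methods

## Pipeline model

A Scheimpflug-style acquisition yields up to 25 grayscale meridional
frames per eye (nominally 1200×620, 8-bit, arbitrary intensity units).
Per frame the pipeline needs three disjoint pixel sets: the cornea, the
iris band below it, and the lateral corneoscleral flanks. Corneal
densitometry (CD) is the mean pixel intensity (MPI) of the corneal set;
the artefact threshold is `T = MPI + 3·SD` with the *sample* (n−1)
standard deviation — with thousands of corneal pixels the denominator
choice is numerically immaterial, but it is fixed so exact tests are
possible. A pixel is an artefact when its intensity is **strictly**
greater than `T`; ties at `T` are not counted (conservative reading;
switching to ≥ is a one-line change in `artefact_percentage`). The
"overall" percentage is computed over the pixel-wise union of the iris
and lateral masks, i.e. pixel-weighted, not the mean of the two regional
percentages; the union is a pure function of the masks and reduces to
the regional values in the obvious limits. Per-eye values are unweighted
means over however many frames are available, with the count recorded.

Two invariances define the metric's character and are asserted in the
tests: adding a constant to every pixel shifts CD by that constant and
leaves all percentages unchanged (mean and threshold move together), and
raising any artefact-region pixel above `T` can only increase its
region's percentage.

## Segmentation stand-in

Clinical Scheimpflug segmentations are device- and operator-specific;
the automatic pipeline here is a deliberately simple, fully reproducible
stand-in built from the classic operators:

* 5×5 median filter (`median_kernel`, pixels);
* Canny edges with `sigma = 1.4` px and hysteresis thresholds derived
  from the frame's Otsu level on the [0, 1] intensity scale
  (high = Otsu, low = Otsu/2);
* corneal boundaries = the two **topmost** of the long near-horizontal
  edge contours (span ≥ width/4 and ≥ 0.6 of the longest candidate;
  principal-axis tilt ≤ 30°) in the upper 75% of the frame. Topmost
  rather than simply longest, because the lower edge of the iris band
  can be as long as the corneal boundaries but always lies deeper;
* cornea = fill between the column-wise interpolated boundary profiles;
* iris band = the half-corneal-thickness strip below the posterior
  boundary restricted to the central third of the width; lateral flanks
  = the same rows in the outer thirds.

All geometry parameters live in `SegmentationParams`. Every downstream
operation also accepts externally supplied label masks
(`provenance="external"`), so any better segmentation can be substituted
without touching the metric code. Masks are validated for dimension
match, pairwise disjointness and non-emptiness on every construction.

## Iris pigmentation index

Photographs are assumed sRGB-encoded with a D65 white point (camera
profiles are rarely recorded in practice; this is the web/DICOM-default
assumption). The sRGB→XYZ→Lab conversion is implemented in-package with
the reference white defined as the sRGB matrix's own image of (1, 1, 1)
— self-consistent by construction, so pure white maps to exactly
(100, 0, 0) and grays to the achromatic axis. Library conversions that
pair the rounded matrix with an independently rounded tabulated white
leave a ~0.005-unit chroma residue on neutrals; the package's conversion
is cross-checked against `skimage.color.rgb2lab` to within 0.02 units in
the tests.

The per-eye reduction of ROI pixels is the **mean** of each Lab
component (median available via `statistic="median"`); the reduction
happens before cohort normalisation. Quantiles use linear interpolation
between order statistics (numpy's default), fixed so the IQR of
{1,2,3,4,5} is exactly 2. Normalisation requires ≥ 4 eyes and strictly
positive IQRs; a zero IQR signals a degenerate cohort rather than being
silently patched. An eye with composite index exactly 0 is classed
`indeterminate` and excluded from two-group comparisons — only the
strict-sign cases are defined as light/dark.

The index is cohort-relative: scores are recomputed from the full
summary list on every call (`score_cohort`), never cached across cohort
edits, and the normalisation constants can be frozen and passed back in
to score new eyes against an existing cohort.

## Statistics

Mixed models are `response ~ predictor` with a per-subject random
intercept, estimated by REML (`statsmodels` MixedLM) with Wald z
p-values on the slope. Alternatives (ML, Satterthwaite/likelihood-ratio
p-values) were considered; REML + Wald is the most common default and
with ~50 subjects the difference is negligible. A fit is flagged
`singular` (non-fatally) when either variance component collapses to
~0 of the total — the random intercept is then redundant (slope = OLS)
or absorbs all residual variance. With one eye per subject the marginal
covariance is spherical for any variance split, so the mixed-model slope
equals the closed-form OLS slope to numerical precision; this oracle
equivalence is asserted at 1e-6.

Group comparisons report per-group plain means and SDs (ignoring subject
clustering, as summary tables conventionally do) with LMM p-values for
the group fixed effect, and the bias summary
`delta = mean_light − mean_dark`,
`relative = 100·delta / mean_dark` — the dark-iris group is the
reference, so the relative figure reads as the overestimation suffered
by light-iris eyes. No multiple-testing correction is applied; the 0.05
significance threshold belongs to the reporting layer only.

## Synthetic data: what it emulates, and what it does not

`make_phantom` renders a parabolic corneal arc (apex row, sag, constant
thickness) sampled from N(mean, SD²), iris/lateral bands at sub-threshold
base intensities with Gaussian texture (SD 1 a.u.), and an **exact**
planted count `round(f·N_region)` of super-threshold pixels per region,
so percentage recovery is testable to one pixel quantum. Defaults:
300×155 px (one quarter of the nominal linear scale, keeping seeded
batches fast — full-size rendering is a parameter, not a different code
path), corneal mean 48 / SD 3 a.u., iris base 25, lateral base 30,
background 5, artefact value 140 a.u. `phantom_batch_specs` spans apex
20–45 px, sag 8–25 px, thickness 18–28 px, corneal mean 42–55 a.u., SD
2–4 a.u. and planted fractions 0–5%.

`make_iris_image` interpolates the ROI's base color in CIELAB between a
pale blue-gray anchor (75, −5, −15) and a dark brown anchor
(28, 14, 28); all three components move monotonically with the
pigmentation level, matching the directional design of the composite
index. Per-pixel Gaussian Lab noise (default 1 unit) is added inside the
annulus; the pupil disk is excluded from the ROI.

`make_cohort` is a statistical emulator of the target study structure:
47 subjects, 91 eyes (39 light / 52 dark by default, exact class sizes;
or Bernoulli eyes and uniform levels), subject intercepts N(0, 1²),
dark-group CD mean 47.2 a.u., planted light-minus-dark difference
3.1 a.u., residual SD 2.9 a.u. Artefact percentages are linear in
(1 − level) with mean-zero noise, calibrated so the group means land
near 2.3/0.8% (iris), 3.9/3.4% (lateral) and 6.5/4.3% (overall); per-eye
Lab summaries follow the anchor gradient with 1.5-unit between-eye
noise. The emitted `pigment_class` is the **planted** class (level below
or above the gradient midpoint): on a perfectly monotone synthetic
gradient the sign rule necessarily splits a cohort near its median rank,
so an unbalanced 39/52 split can only be planted, not emerge — the sign
classifier itself is validated separately on gradient cohorts. The
light/dark CD difference is likewise planted directly rather than routed
through rendered images; `make_eye_bundle` provides the complementary
image route (frames whose planted artefact fractions grow with
lightness) for end-to-end demonstrations.

What passing tests therefore show: the measurement arithmetic, the
normalisation/index algebra, segmentation on arc-shaped phantoms, and
the statistical layer's power and calibration at the study's size. What
they do not show: performance on real Scheimpflug optics (specular
reflexes, tear film, eyelashes, tilt), real iris texture (crypts,
heterochromia, Fleischer rings), camera color-profile error, or any
claim about real-cohort correlation magnitudes.

## Numerical choices and problem sizes

Intensities are treated as real-valued after loading; no requantisation.
Thresholds are not clamped to 255 — a threshold above the intensity
range legitimately yields 0% artefacts. Recovery/calibration checks use
100 replicates of the 91-eye cohort (a few tens of seconds), phantom
batches use 20 frames at quarter scale, and the gradient coherence check
uses 11 noise-free levels. All generators take explicit integer seeds
and are bit-reproducible.

## Known limitations

The segmentation stand-in assumes a single bright, roughly horizontal
corneal arc and will not handle off-axis or pathological geometries; use
the external-mask path there. The pigmentation index is cohort-relative
by design — values are not comparable across cohorts unless the
normalisation constants are frozen and shared. Wald p-values are mildly
anti-conservative for small subject counts; the null-calibration test
bounds this at the emulated study size (rejection rate within
[0.01, 0.11] at α = 0.05) but says nothing about much smaller cohorts.
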