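# Methods

`facescreen` implements a contact-free screening pipeline for Parkinson
disease (PD) built on short "poker face, then smile" face videos.
Hypomimia — the masked-face sign of PD — reduces the amplitude of voluntary
expression and flattens fine expressive texture around the eyes and mouth.
The pipeline quantifies both phenomena from 2-D grayscale frames with
68-point facial landmarks and feeds them to classical classifiers.  Because
no public dataset of such videos exists, the package ships a synthetic
cohort generator with exact ground-truth landmarks; every stage of the
pipeline is validated against that ground truth.

## Face normalization

Raw frames are mapped into a canonical 256×256 frame by a 4-DOF similarity
transform (uniform scale, rotation, translation).  A full 6-DOF affine fit
would admit shear, which distorts the very angles the geometric features
measure, so the similarity restriction is deliberate.  The transform is
determined in closed form by mapping the two eye centers — the means of
iBUG landmarks 36–41 and 42–47 — exactly onto fixed anchors at
(89.6, 102.4) and (166.4, 102.4): inter-ocular distance 76.8 px, eyes at
40% of the frame height.  Two-point alignment is exact (eye centers land on
the anchors to numerical precision), and a least-squares similarity over
all 68 points against an explicit reference set is available behind a flag.
Images are resampled bilinearly; pixels from outside the source frame are
zero.  All downstream angle features are therefore invariant (≤ 0.1°,
verified) to rigid motion and uniform rescaling of the input video.

Landmark detection itself is pluggable.  The package bundles no pretrained
model: the synthetic backend serves the generator's ground-truth boxes and
landmarks (an intensity-threshold detector recovers the ground-truth head
box exactly on synthetic renders), and a documented two-method adapter
interface (`detect_face_box`, `locate_landmarks`) lets users wrap an
external detector such as dlib's ensemble-of-regression-trees predictor.

## Geometric features

All angles are computed on normalized landmarks and reported in degrees,
with the image convention that y grows downward.

* **Corner angles.** Each mouth corner (p48, p54) forms a characteristic
  triangle with the upper- and lower-lip centers (p51, p57); the corner
  angle is the angle at the corner vertex, via the arccosine of the
  normalized dot product.  The *main feature* is the apex-minus-neutral
  change of each corner angle: a stiff, hypomimic mouth changes less.
* **Deviation angles** (auxiliary asymmetry features): the signed angle of
  the mouth axis p48→p54 against horizontal; the signed elevation of each
  corner above the mouth center (midpoint of p51 and p57); and the absolute
  left–right elevation difference at the apex.

Key frames are selected by the mouth-width ratio ‖p54−p48‖ / inter-ocular
distance — a quantity deliberately different from the angle features it
serves, so that frame selection cannot bias the measurement.  The neutral
frame is the ratio minimum within the first 40% of the sequence (subjects
hold a poker face before smiling); the apex is the global maximum; ties
break toward the earlier frame.  A motionless sequence returns (first,
last) with a `degenerate` flag instead of failing.

## Texture features

Two landmark-anchored regions of the normalized face are described:
mouth (landmarks 48–67, margin 0.2, resampled to 64×32) and eyes
(landmarks 36–47, margin 0.25, 128×32).  Two descriptors are concatenated
per region, in the fixed order [HOG mouth, HOG eyes, LBP mouth, LBP eyes]
with a named slice layout (so eye-only and mouth-only subsets can be
compared):

* **HOG** — centered finite-difference gradients, 9 unsigned orientation
  bins over [0°, 180°) with magnitude weighting and circular linear
  interpolation between adjacent bins, 8-px cells, 2×2-cell blocks sliding
  by one cell, L2-Hys normalization with clip 0.2.  A 64×32 patch yields
  (7·3)·4·9 = 756 values.
* **Uniform LBP** — 8 neighbors sampled bilinearly on a circle of radius 1,
  bit set when neighbor ≥ center, mapped to the 59 non-rotation-invariant
  uniform codes, histogrammed over a cell grid (4×8 mouth, 4×16 eyes) with
  per-cell L1 normalization.  The ≥ comparison carries a 10⁻⁹ relative
  tolerance so that exactly flat regions produce the all-ones code despite
  interpolation round-off.  Note that bilinear sampling commutes with
  positive affine intensity maps but not with nonlinear monotone maps, so
  the classical "monotone gray-scale invariance" of LBP holds exactly only
  for gain/offset changes here (as in any interpolated circular LBP).

Texture is extracted from the smile-apex frame only (configurable); the
apex carries the expressive detail that hypomimia suppresses.

## Classifiers and evaluation

One feature row per subject (never per frame) prevents identity leakage
across the train/test boundary.  The split is stratified random — by
default 80 training and 60 test subjects of 140, the proportions of the
target study design.  Features are z-scored with mean/SD estimated on
training rows only; constant training features are zeroed.  The combined
feature set is the column-wise concatenation [geometric | texture] of the
standardized blocks.

Three families are trained with conventional, fully overridable defaults:
RBF-kernel SVM (C = 1, bandwidth by the "scale" rule), 5-nearest-neighbor
with Euclidean distance, and a 100-tree random forest.  The forest
considers **all** features at every split (bagging supplies tree
diversity).  This departs from the common √p per-split subsampling for a
measured reason: the fused matrix joins a 6-column geometric block to a
~8,000-column texture block whose informative columns are individually as
discriminative as a mouth angle, so with √p ≈ 90 candidates the geometric
block is effectively never offered (its share of forest importance was
0.1%) and the combined model silently degenerates into a texture model.
With all-feature splits, nodes that are already texture-homogeneous find
the independent geometric signal and fusion actually occurs.

Scores are monotone class-1 propensities in [0, 1]: tree-vote fraction
(RF), neighbor-vote fraction (KNN), and a logistic squashing of the signed
decision value (SVM).  Evaluation reports the full ROC curve over all
distinct score thresholds; AUC by the trapezoid rule (equal to pairwise
concordance with ties half-weighted, verified exactly against brute force);
and the Youden index J = max(TPR − FPR).  Among J-maximizing thresholds the
one with the highest TPR is chosen, and the reported cut is the midpoint
between the two adjacent distinct scores straddling it.  Accuracy,
precision, recall and F-measure are computed at the Youden threshold;
precision is flagged undefined (not 0) when nothing is predicted positive.
For well-behaved (concave) ROC curves J relates to AUC through
AUC ≥ (1 + J)/2, with the binormal equal-variance closed forms
AUC = Φ(d/√2) and J = 2Φ(d/2) − 1; these two quantities coincide only as
d → 0, and the tests assert the exact forms rather than the folklore
identity J = 2·AUC − 1.

Pearson correlations between facial features (or model scores) and clinical
covariates are computed within the patient group, with two-sided t-test
p-values and Fisher-z 95% confidence intervals; raw p-values are reported
without multiplicity correction, and constant covariates yield a flagged
row rather than an error.

## Sample-size calculation

The a-priori design calculation inverts the noncentral-F power function of
a between-groups repeated-measures ANOVA: with k groups, m repeated
measurements correlated at ρ, and Cohen's effect size f, the
noncentrality is λ = f²·N·m/(1 + (m−1)ρ) with df₁ = k−1, df₂ = N−k (the
G*Power convention for "repeated measures, between factors"; other
conventions exist, hence the explicit statement).  The search returns the
smallest balanced N (multiple of k) whose power reaches the target.  For
f = 0.4, α = .05, power .95, k = 2, m = 120, ρ = 0.5 it returns N = 44
(22 per group); with m = 1 it reduces to the classic two-group result
N = 84, and ρ → 1 collapses any m to the m = 1 answer.

## The synthetic cohort

Each subject carries latent traits: neutral corner angle ~ N(70°, 4°),
smile corner-angle gain ~ N(12°, 3°) truncated at 0, corner asymmetry
~ N(0°, 1.5°), mouth width ~ N(60, 4) px, inter-ocular distance 100 px on a
256-px canvas, and texture contrast ~ N(1, 0.33) clipped to [0.05, 2].
Three group effects act on patients: `effect_angle` lowers the gain mean by
that many SDs (default 1.5 — a large hypomimia effect); `effect_asym`
inflates the asymmetry SD (default 0.5); `effect_texture` multiplies
texture contrast by 1 − value (default 0.5).  With all effects zero the two
groups are statistically identical (verified by KS tests on downstream
features).  The texture-contrast dispersion (0.33) was set so that the
default patient/control contrast separation (standardized d ≈ 1.9)
produces the modality strengths the pipeline is designed around — texture
discriminating more strongly than geometry but neither saturating — rather
than a degenerate, perfectly separable texture channel.

Landmarks are analytic, not detected.  The expression phase follows a
half-sine over the sequence (poker face → apex at mid-sequence → relax), so
frame 0 is always neutral within the first 40% of frames.  At phase φ the
mouth widens by 15%·φ, the lip centers part so that the corner angle equals
neutral + gain·φ in closed form (lip half-opening h = (w/2)·tan(θ/2)), and
the corners rise by (4° ± asymmetry/2)·φ relative to the mouth center.
Consequences used by the tests: the neutral mouth width equals the
`mouth_width` parameter to 0.5 px; the apex-minus-neutral corner-angle
change equals `smile_angle_gain` to 0.5° (the 4° shared corner lift
perturbs the closed form by < 0.2°); the left-minus-right corner elevation
at apex equals `asymmetry` exactly; and regression of measured change on
generating gain has slope 1.00 ± 0.05 over a cohort.

Rendering is deliberately line-art, not photorealistic: a filled head
ellipse (intensity 170) on black, dark lip polygons through the mouth
landmarks, eye outlines with irises, brow and nose strokes, plus sinusoidal
"wrinkle" bands — crow's feet lateral to each eye, perioral and chin bands
around the mouth — with amplitude 10·texture_contrast, and additive
Gaussian pixel noise (SD 3) inside the head.  The wrinkle amplitude is of
the same order as the noise on purpose: HOG blocks are contrast-normalized
and LBP is gain-invariant, so what the descriptors can detect is the local
signal-to-noise ratio of fine structure, which is exactly what
`texture_contrast` modulates.

Clinical covariates (age, disease duration, LEDD, UPDRS, H-Y, MMSE, NMSS,
PDQ-39, HAM-A, RBDSQ, QUIP, FOG) are drawn from plausible scale ranges and
are independent of the facial traits by default, reproducing a null
correlation structure between facial severity and clinical measures
(verified: the nominal-significance rate stays within binomial bounds of
α).  Setting `covariate_link=True` couples UPDRS to smile severity with
population correlation 0.6 for power studies of the correlation analysis.

All randomness derives from the cohort seed plus the subject index (with
separate streams for traits, covariates and each rendered frame), so
cohorts are exactly reproducible and single frames can be re-rendered in
isolation.

**What the generator does not emulate** — and therefore what passing tests
do not show about clinical data: detector noise and landmark jitter (ground
truth is exact), head pose and illumination variation, photorealistic skin
texture, facial tremor, occlusions, and any correlation between facial
signs and clinical severity (absent by design in the default null
configuration).  Results on this cohort validate the machinery, not
clinical performance.

## Problem sizes and statistical checks

The test suite exercises the full study geometry (70 + 70 subjects,
80/60 splits) where the check needs it, and scales elsewhere: oracle
equivalences run on 200 random ROC instances and 1,000 random landmark
sets; the fusion check replicates 10 split/train seeds on one fixed
effectful cohort; the null-AUC check runs 10 zero-effect cohorts × 9
models; the covariate null calibration uses 20 cohorts.  Checks of nominal
coverage (the chance-AUC band, the 5% null-correlation rate) are one-sided
binomial consistency tests at α = .05 around the nominal rate — demanding
the nominal percentage exactly at a few dozen replicates would fail
routinely under its own assumptions.

## Known limitations

* No pretrained face/landmark model is bundled; real-video use requires an
  external detector behind the adapter interface.
* The Youden threshold is estimated on the evaluation scores themselves
  (as in the underlying screening design), which optimistically biases the
  thresholded metrics; AUC is unaffected.
* SVM scores are squashed decision values, not calibrated probabilities.
* Single-face frames only; no video-container decoding (PNG directories).
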