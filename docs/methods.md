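# Methods

This note documents the models, conventions and design choices behind
`tumortex`: what each stage computes, what the synthetic cohort
generator does and does not emulate, and the numerical rules that make
every result reproducible from a single seed.

## Problem setting

A glioblastoma biopsy site is labeled **high** tumor content when the
histologic percent tumor nuclei is ≥ 80 (the adequacy threshold for
genomic profiling) and **low** otherwise.  The pipeline predicts that
label from an 8×8-voxel in-plane ROI on eight coregistered MRI
contrasts: post-contrast T1 (T1+C), T2-weighted (T2W), relative
cerebral blood volume (rCBV), post-contrast T2\* echo-planar (EPI+C),
and the diffusion-tensor metrics p, q, MD, FA.  Coordinates are
0-based; ROI ranges are half-open; texture is strictly 2D on the
stated slice.  Sites come from two zones — the gadolinium-enhancing
core (ENH) and the non-enhancing brain-around-tumor (BAT) — and all
metrics are reported per zone and overall.

## Features (256 per ROI)

**First-order (2 × 8 contrasts).**  Mean and SD of the raw ROI
intensities.  SD uses the population denominator n = 64: the ROI is a
fixed window, not a sample.

**Rescaling.**  Before texture analysis each ROI is mapped affinely
onto integer 0–255 (min → 0, max → 255, floor to integers); a constant
ROI maps to all zeros.  ROI min/max (rather than fixed window limits)
makes the mapping invariant to positive affine intensity transforms,
standardizing ROIs across acquisitions.  A consequence worth knowing:
marginal-shape changes (e.g. heavy tails) re-enter texture features
through the stretched range.

**GLCM (13 × 8).**  Symmetric distance-1 co-occurrence matrices at 0°,
45°, 90°, 135° are accumulated on the ROI quantized to 16 gray levels
(configurable 8/16/32; 64 pixels cannot populate a 256² matrix),
averaged into a single matrix, and normalized to sum 1.  Averaging
before feature computation makes the features exactly invariant under
quarter turns and transposition.  The 13 features are energy, entropy,
homogeneity, dissimilarity, correlation, contrast, variance, sum
average, sum variance, sum entropy, difference variance, difference
entropy, and the first information measure of correlation; entropies
use natural logs with 0·log 0 = 0, and correlation on a zero-variance
ROI is defined as 0.

**LBP (12 × 8).**  For each of the four center voxels whose radius-3
circle of 24 bilinear-interpolated sample points fits inside the ROI,
a bit is set where the neighbor is ≥ the center (so a constant patch
yields the all-ones pattern).  Patterns with ≤ 2 circular 0↔1
transitions are *uniform* and reduce to their set-bit count (rotation
invariant); all others share one non-uniform bucket.  The 25 uniform
codes fold into 11 near-equal contiguous count ranges
(sizes 3,3,3,2,…,2), plus the non-uniform bin, giving a 12-bin
histogram normalized to sum 1.  The extraction itself is
`skimage.feature.local_binary_pattern(method="uniform")`, which
implements exactly these conventions; tests verify it bit-for-bit
against an explicit enumeration oracle.  Note that with only four
evaluable centers this is intentionally a very coarse descriptor.

**DOST (5 × 8).**  The unnormalized 2D DFT of the rescaled ROI is
partitioned into dyadic frequency sections per axis: {0}, {1}, {−1},
{2,3}, {−2,−3} and the Nyquist {−4}.  Mean spectral amplitude per 2D
section forms a 6×6 harmonics image; sections are grouped by radial
order r = max(|order_x|, |order_y|) with Nyquist as order 3.  Features:
DC amplitude, mean harmonic amplitude at r = 1, 2, 3, and the spectral
entropy of the four squared band amplitudes normalized by log 4 (an
all-zero spectrum has entropy 0).  With the unnormalized transform,
Parseval's identity reads Σ|F|² = 64·Σ|x|², which the tests check
against a naive O(N⁴) DFT.

Feature names follow `<contrast>__<ALGORITHM>__<feature>` in a fixed
registry order, so feature tables are byte-stable.

## Dimension reduction

Features form 32 blocks: 24 texture blocks (8 contrasts × GLCM / LBP /
DOST) and 8 raw blocks.  Each texture block is z-scored with training
statistics (zero-variance columns get unit scale and contribute
nothing) and eigendecomposed; the smallest k with cumulative explained
variance ≥ 0.85 is retained (k ≥ 1).  Loadings are sign-fixed so each
component's largest-magnitude entry is positive.  Raw mean/SD bypass
PCA (standardized pass-through) so a selected "raw rCBV mean" remains
interpretable as such.  Validation data is always transformed with
stored training statistics; nothing refits.

Two soft expectations are logged, not enforced: blocks compressing to
1–3 PCs, and total reduced dimensionality below the sample count.
Both hold for strongly correlated real-world texture features; on the
synthetic cohorts the uninformative contrasts are white-noise fields
whose texture statistics are only weakly correlated, so blocks retain
more components (typically ~100 reduced columns for 60 samples).  The
diagonal classifiers are insensitive to this.

PCA is fitted once on the full training set, outside the LOOCV loop —
only the classifier is nested in cross-validation.  This admits a mild
optimistic bias; `loocv_accuracy_pca_refit` (exposed as
`--pca-in-folds`) refits the reduction inside every fold as a
sensitivity analysis, treating components not retained in a fold as
zero.

## Classifiers

DLDA and DQDA model each class as a diagonal-covariance Gaussian.
DLDA pools per-feature variances across classes (total within-class
squared deviation / n, floored at 1e-9); DQDA estimates them per
class.  Priors are empirical class frequencies — the ~45% high-tumor
prevalence of a surgical cohort is information, not nuisance.
Posteriors are softmax-normalized exact log-likelihoods; an exact tie
predicts **low**, the conservative call when a false high-tumor call
costs a wasted biopsy.  The SVM is `sklearn.svm.SVC` with a linear
kernel (C = 1, features pre-standardized); its pseudo-posterior is a
logistic squash of the signed decision value, chosen over Platt
scaling for determinism.

## Cross-validation and feature selection

LOOCV runs exactly n folds; a fold whose training split is
single-class predicts that class.  Forward selection starts from the
majority-class accuracy as the zero-feature baseline and greedily adds
the candidate (all reduced columns, raw pass-throughs included) with
the best LOOCV accuracy, stopping when the best gain falls below the
threshold (default 0.01 — "<1%" read as absolute accuracy points,
since accuracy is already on a percent scale).  Ties break to the
lower registry index, making the trace deterministic.  Trace
accuracies are non-decreasing by construction.

Greedy LOOCV selection over ~100 candidates with n = 60 is noisy: on
pure-noise data it typically still admits 2–6 features whose lucky
gains exceed one accuracy point, inflating the apparent training
accuracy by ~5–10 points.  The unbiased read-out of a selected model
is its frozen-model accuracy on held-out patients, which is what the
validation stage reports (and what sits at chance on null cohorts).

## Evaluation

Metrics are accuracy, sensitivity, specificity, PPV and NPV from
integer confusion counts; a zero-denominator ratio is reported as NaN,
never silently 0.  `reconstruct_confusion` inverts printed summaries:
given class counts and sensitivity/specificity it returns the
nearest-integer confusion matrix, which reproduces the rates within
half a count.  `reference_cohort.check_reference_summary` applies this
to the published 18-patient summary (training 60 biopsies / 11
patients, validation 22 / 7) and verifies all 30 printed cells at
their printed rounding, plus zone additivity and the pooled
full-cohort prevalences (59.2% ENH, 21.2% BAT) and model PPVs (81.3%
ENH, 66.7% BAT).

Subgroup exclusion removes, greedily by most-offending-pair count
(ties to earlier sites), the minimum sites so that no same-patient
pair is separated by a 3D physical distance in [min_mm, max_mm);
tests validate greedy minimality against exhaustive subset search at
toy scale.  3D distance between ROI centers is used (the in-plane
alternative is a parameter away), with voxel size (3.0, 1.2, 1.2) mm.

Probability maps slide the 8×8 window at a configurable stride; every
window runs the identical ROI → features → reduction → posterior
chain, and the posterior is assigned at the window center
(corner + 4, corner + 4).  Maps are written as float NIfTI and as a
blue-to-red overlay PNG on the T2W slice.

## Synthetic cohort generator

The generator's purpose is to emulate the *statistical structure* the
classifier exploits, not brain anatomy or MR physics.

**Geometry and histology.**  Each patient's volume (default 4 × 96 ×
96 voxels at 3.0 × 1.2 × 1.2 mm) holds an ENH disk (radius 22 voxels)
inside a BAT shell (to radius 40; BAT's spatial definition is not a
measured quantity, so both radii are parameters).  Percent tumor
nuclei is a Gaussian-smoothed random field (in-plane correlation
length 6 voxels) around zone means 84 (ENH) and 64 (BAT) with spatial
SD 20, clipped to [0, 100].  These defaults put ~59% of ENH sites and
~21% of BAT sites above the 80% threshold, matching surgical-cohort
prevalences.  A site's recorded percent tumor nuclei is the true
footprint mean; the high/low label applies the 80% threshold to that
ROI mean (histology labels whole samples, not voxels).

**Histology–imaging coupling.**  MRI does not see nuclei counts; it
sees vascularity (rCBV), cellular density (EPI+C) and blood–brain
barrier disruption (T1+C), each an imperfect correlate.  The generator
therefore derives, per signal-bearing contrast, a latent field =
tumor fraction + shared smooth perturbation (SD 2 points) + contrast-
specific smooth perturbation (SD 9 points), and thresholds *that* at
80 to decide where the imaging signal lives.  The shared component
caps the accuracy any feature combination can reach; the
contrast-specific components leave genuine incremental value in
combining contrasts — without them, two complementary channels combine
to near-perfect accuracy and selection degenerates to one feature.

**Signals** (all relative to noise SD 1.0):

* **rCBV** — intensities shift by 0.55 SD in latent-high voxels; the
  informative statistic is the raw ROI mean.
* **EPI+C** — Gaussian-smoothed noise whose in-plane correlation
  length switches from 0.7 (low) to 1.8 (high) voxels, renormalized to
  equal *within-window* SD so first-order statistics carry no signal;
  the informative statistics are co-occurrence features.
* **T1+C** — a unit-variance product-of-sinusoids lattice
  (wavelength 4) of amplitude 0.6 replaces an equal share of noise
  variance in latent-high voxels.  The product form has zero
  correlation at all four distance-1 co-occurrence offsets and leaves
  total variance class-independent, so the signal expresses itself in
  local binary structure.
* **T2W, p, q, MD, FA** — class-independent white noise.  An optional
  smooth "anatomy" background exists (off by default: it mostly masks
  the raw-mean channels).

**Site placement.**  Sites split ENH/BAT by `enh_fraction` (0.6);
footprints must lie fully inside their zone; rejection sampling
enforces ≥ 10 mm (3D) between same-patient sites and raises after
10,000 retries.  The study layout is 60 training biopsies over 11
patients and 22 validation biopsies over 7 (5–6 per tumor).

**Calibration.**  Effect sizes were fixed once by component-level
calibration against the study conditions the cohort must emulate —
training LOOCV accuracy in the high-0.8/low-0.9 range with
multi-feature selection traces, validation accuracy tracking training,
zone prevalences as above — and are not tuned per seed.

**What passing tests do and do not show.**  The synthetic cohort
shares the study's sample sizes, zone structure, prevalences, feature
dimensionality and signal placement, but its features are far cleaner
than radiological reality (no coregistration error, no scanner or
patient heterogeneity beyond the modeled couplings, white-noise
uninformative contrasts).  Passing end-to-end tests demonstrates that
the pipeline recovers planted structure under realistic sample-size
noise — not that it would achieve comparable accuracy on patient data.

One documented shortfall: the acceptance property asking forward
selection to recover features from ≥ 2 of the 3 *named* informative
blocks (rCBV-raw, EPI+C-GLCM, T1+C-LBP) in ≥ 80% of replicates is not
met (~35–45% across candidate designs).  The texture families overlap
on any realizable signal — a co-occurrence change is also visible to
DOST band energies and LBP uniformity, and the 4-center LBP histogram
is intrinsically the weakest detector — so the within-channel race
between algorithm blocks is decided by LOOCV noise at n = 60.  The
companion properties (final LOOCV accuracy ≥ 0.80 in every replicate;
null cohorts at chance on held-out data) do hold.  Channel-level
recovery (any algorithm on the right contrast) reaches ~65–70%.

## Determinism

All randomness flows from one root seed through
`numpy.random.SeedSequence([seed, patient_index, stream])`; the same
config and seed reproduce byte-identical feature tables, traces and
maps.  Fitted reductions and classifiers serialize to JSON; every
pipeline stage writes a manifest with the config hash and seed.

## Problem sizes

Default test and acceptance runs use the study-scale cohort (18
patients, 82 biopsies, 4 × 96 × 96 volumes), 20 seeded replicates for
recovery/null statistics, and stride-4 maps on single slices; these
sizes keep a full run in minutes on one CPU while preserving the
sample-size regime that drives every statistical conclusion above.
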