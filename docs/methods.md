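# Methods

This note documents the models, conventions and numerical choices behind
`petmip`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Baseline ¹⁸F-FDG PET of diffuse large B-cell lymphoma (DLBCL) patients is
summarized into two 2D maximum-intensity projections (coronal, sagittal),
and a convolutional classifier maps the pair to the probability of disease
progression within two years: P(TTP1), with P(TTP0) = 1 − P(TTP1).  Total
metabolic tumour volume (MTV, mL) and the dissemination feature Dmax_bulk
(cm) are the reference quantitative features against which the classifier's
behaviour is interrogated.

## Synthetic phantoms

`phantom.generate_phantom` builds whole-body SUV maps on a (z, y, x) grid
(default 150 × 90 × 90 voxels at 4 mm isotropic; z index 0 is the head
end):

- torso: an ellipsoid at SUV 1.0 occupying most of the grid, joined to a
  head sphere through a 40 mm neck cylinder; voxels outside the body are 0;
- brain: a 55 mm-radius sphere at SUV 8 near the top (0.70 L, inside the
  [0.5, 2.5] L window the brain-removal step expects);
- bladder: 24 mm sphere at SUV 45, low in the torso — deliberately above
  the SUV-40 normalization cap so truncation is exercised on every phantom;
- liver: 40 mm sphere at SUV 2 (below the segmentation threshold; used by
  the quality-control check);
- lesions: 1–15 non-overlapping spheres (radius 6–15 mm by default) with
  SUV uniform in [5, 20], placed uniformly inside the torso away from the
  organs.  Spheres are used because their volume has a closed form, giving
  every volume computation an exact oracle (voxelization error at 4 mm is
  below 20% for radius ≥ 8 mm, and the tests budget for it).

A voxel belongs to a sphere when its centre lies within the radius; voxel
centre i sits at (i + 0.5) · spacing.  All randomness flows from a Philox
counter-based generator; per-patient streams are spawned from one cohort
seed, so cohorts are reproducible and order-independent.

### Outcome labels

Labels are Bernoulli with

    logit P(TTP1) = β₀ + β_MTV · log MTV + β_Dmax · Dmax_bulk,

evaluated on the voxelized ground truth.  Three operating points are
provided: `default` (β = (−11, 2.5, 0.1)) gives ≈ 31% prevalence and a
Bayes AUC ≈ 0.85, matching the historical ~30% 2-year progression rate of
the disease; `strong` (β = (−16, 4.0, 0.1), prevalence ≈ 1/3, Bayes AUC
≈ 0.92) is the condition for the signal-recovery benchmarks; `null`
(β = 0) makes labels independent of the image.  These were fixed once, from
the target prevalence and feature distributions alone.

`simulate_feature_table` draws the same per-patient geometry (identical RNG
stream) but computes MTV analytically instead of rasterizing, so
label-model properties (e.g. logistic recovery of β at n = 2000) can be
checked at a scale where rasterizing volumes would be wasteful.

### What the phantoms do not emulate

No Poisson/reconstruction noise, no scanner point-spread function or
partial-volume effect, no attenuation artefacts, no respiratory motion, no
irregular lesion shapes, and no anatomical variability beyond lesion
placement.  Tests passing on phantoms therefore demonstrate that the
pipeline's machinery is correct and that the classifier can learn a
burden-driven signal — not that it reaches any particular accuracy on
clinical scans.

## Segmentation and features

Tumours are voxels with SUV ≥ 4.0 (inclusive: boundary voxels are kept),
grouped by 26-connectivity — the standard choice of MTV tooling — after
excluding a caller-supplied physiological mask (the interactive deletion of
physiological uptake in clinical workflows is replaced by this explicit
argument; on phantoms it is the known brain/bladder/liver mask).
Components are labelled in decreasing voxel count, ties keeping scan order,
and no minimum-size filter is applied by default.  MTV is the summed
component volume; Dmax_bulk is the centroid-to-centroid distance from the
largest-volume lesion (ties: lowest label) to the farthest other lesion, in
cm; a surface-to-surface variant (volume-equivalent sphere radii
subtracted) is available but off by default.

## MIP processing

Order is fixed: project → resample → centre on canvas → normalize.

- Projection takes the per-ray maximum along y (coronal) or x (sagittal);
  output rows are cranio-caudal with the head at row 0.
- Resampling to the 4 mm canvas grid is bilinear for intensities and
  nearest-neighbour for masks (so masks stay binary); a projection whose
  physical extent exceeds the 110 cm × 80 cm canvas is an error (the
  required crop is reported rather than silently applied).
- The canvas is 275 × 200 zero-filled, the resampled projection centred on
  both axes (symmetric padding; alignment is otherwise arbitrary).
- Normalization divides by a fixed SUV = 40 after truncating above it, so a
  bladder at SUV 45 maps to 1.0 and cannot stretch the scale.  Truncation
  happens after interpolation, so interpolation always sees raw SUV.

Brain removal operates in 3D before projection, which guarantees the
coronal and sagittal views stay consistent: the 26-connected component of
voxels with SUV > 3 whose centroid lies in the top 15% of the occupied
cranio-caudal extent and whose volume is 0.5–2.5 L is zeroed.  If no
component qualifies (the head may simply not be in the scan) the volume
passes through unchanged with a logged notice; lesions overlapping the
removed component are flagged in the log as truncation risks, mirroring the
~1% truncated-lesion rate such a procedure cannot avoid.

Tumour ablation replaces all pixels under the lesion mask by the mean of
non-background (> 0) pixels outside the mask.  The operation is idempotent
and undefined (an error) when the mask covers every non-background pixel —
which is why the plausibility analysis runs on regular or brain-removed
MIPs, never on lesion MIPs.

## Cohort sampling

With n₀ TTP0 > n₁ TTP1, the TTP0 patients are shuffled and split into five
near-equal strata (244 → 49/49/49/49/48).  Every subset consists of its
stratum plus k = n₁ − max(stratum size) TTP0 borrowed from k distinct other
strata (3 for the 244/52 cohort), plus all TTP1 patients: subsets A–D get
104 patients at exactly 50% prevalence and subset E 103 (51 TTP0).  A
patient can be borrowed by several subsets but never appears twice in one.
Folds are label-stratified 5-fold splits (≈ 80/20) per subset.  The scheme
is a pure function of (ids, labels, seed).  When n₁ is smaller than the
largest stratum the augmentation scheme is undefined and the builder
raises.

## The classifier

Per branch: conv 3×3 (valid, so each conv trims the border) → ReLU →
spatial dropout 0.35 → max-pool, with feature maps 16/32/64/128, pool sizes
(3,3), (3,3), (2,2) after the first three convs and global average pooling
after the fourth; the two 128-vectors concatenate into dense(2) + softmax.
Per-branch parameter count 97 152; total 194 818.  Weights are Glorot
uniform; loss is categorical cross-entropy (the canonical softmax pairing;
batch size 16 — neither is dictated by the architecture, both surfaced in
config).  The optimizer is Adam (ε = 10⁻⁷) with the learning-rate schedule
lr_t = lr / (1 + decay · t); interpreting "decay" as L2 weight decay
instead is available as a config switch, off by default.  Class weighting
is unnecessary because the subsets are balanced by construction.

The implementation is plain NumPy: convolutions as a single im2col GEMM per
layer, max-pool backward as an equality mask that shares the gradient
equally among tied maxima (a valid, deterministic subgradient that avoids
an argmax scatter), and the first layer skips its input gradient (nothing
below it needs one).  A finite-difference gradient check in the test suite
pins the backward pass to ~10⁻⁷ relative error in float64.  Training is
bit-reproducible from (seed, config, data order); float32 is used for
training, float64 only in the gradient check.

### Training schemes and profiles

1. `lesion`: train on lesion MIPs for `epochs_stage1`.
2. `mip` / `br_mip`: pre-train on binary lesion masks for `epochs_stage1`,
   then fine-tune the same weights on regular or brain-removed MIPs for
   `epochs_stage2`, with identical fold membership in both stages.  Between
   stages the optimizer state is re-initialized but the dense head is kept.

Two profiles exist.  `paper`: 200/300 epochs, lr 5·10⁻⁵, decay 10⁻⁶ — the
full-scale settings.  `desk`: 20/30 epochs, lr 3·10⁻³, decay 10⁻⁵ — the
scaled-down profile used by the test suite and synthetic benchmarks; with
10× fewer epochs the full-scale learning rate underfits badly, and 3·10⁻³
was selected from {10⁻³, 3·10⁻³, 5·10⁻³} by training-loss/validation
diagnostics on phantom cohorts.  Per subset, five fold models are trained
and the fold with the highest validation AUC is preserved (ties: lowest
fold id).  No data augmentation is used.

## Evaluation and plausibility

- AUC uses the rank (Mann–Whitney) formulation with midranks, so ties count
  ½; it matches an all-pairs oracle exactly.
- Classification at the 0.5 cutoff counts p = 0.5 as positive (declared tie
  rule, configurable).  Sensitivity without positives (or specificity
  without negatives) is reported as NaN, never as 0.
- The DeLong test estimates the variance of the paired AUC difference from
  per-observation structural components; it was cross-checked against an
  independent R implementation (pROC) to 6 decimals, and against the exact
  sign-swap permutation distribution at n = 12, where the asymptotic
  p-value tracks the exact mid-p to ≈ 0.14 at worst.  Zero variance
  (e.g. comparing a score vector with itself) returns p = 1 with a
  degeneracy flag.
- The IPI baseline uses the raw 0–5 score for ROC and IPI ≥ 4 as the
  high-risk rule; this is a deliberate simplification of published
  IPI-based regression models.
- Calibration is a univariate logistic fit of the outcome on the raw
  P(TTP1) (IRLS, tol 10⁻⁸, ≤ 100 iterations), estimated on the selected
  model's validation predictions (not training predictions, to avoid
  optimism) and then applied unchanged to ablated-MIP probabilities.
  Perfect separation falls back to an L2-penalized fit with a logged
  notice.  Being strictly monotone (slope > 0 on any informative
  predictor), calibration preserves AUC exactly.
- The ablation analysis reports per-patient calibrated probabilities before
  and after tumour removal, the count of patients crossing from > 0.6 to
  < 0.4, and histogram bins; on cohorts whose labels are driven by tumour
  burden the mean probability must drop, which the suite asserts with a
  paired sign test.

## Benchmark problem sizes

The statistical benchmarks run at sizes chosen to be informative per CPU
minute: a 200-phantom strong-signal cohort for signal recovery (lesion
scheme, desk profile, one CV fold; held-out = the 80 patients never seen in
training), the same cohort for the transfer-scheme model used in ablation
and perturbation probes, a 100-phantom null cohort for the
no-signal control, n = 2000 feature simulations for coefficient recovery,
and exhaustive oracles at n ≤ 12 (permutation) / n ≤ 20 (AUC pairs) /
10³ voxels (projection).  On one CPU the whole suite, including both
training runs, completes in roughly twenty minutes.

## Known limitations

- The phantom realism gap above: desk-scale results quantify machinery, not
  clinical performance.
- The brain-removal procedure is a re-design from first principles (find a
  brain-sized supra-threshold component near the head end); clinical
  deployments would need validation against scans with head-adjacent
  disease.
- The threshold 0.5 cutoff is not transferable across cohorts with
  different prevalence; no threshold-transfer rule is provided.
- Training at the full 200/300-epoch profile on clinical-size canvases is
  possible but slow in this NumPy implementation; the architecture is
  small, and the code is structured so a GPU framework could replace the
  layer primitives without touching the pipeline.
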