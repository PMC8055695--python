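# Methods

## Overview

`histoprog` implements a weakly supervised survival-prediction system for
whole-slide histopathology together with a cluster-based explanation
pipeline, at a scale that runs on a single CPU in minutes.  The system has
four stages:

1. **ROI masking.** Tumor-probability heatmaps on a superpixel grid are
   binarized at a threshold calibrated to a recall target, denoised by
   removing positive connected components smaller than eight superpixels,
   and dilated with a discrete Euclidean disc of radius *r* (in that fixed
   order).  Prognostic patches are the non-overlapping tiles whose footprint
   is at least half covered by the mask (ties included).
2. **Prognostic model.** A case is a bag of patches sampled from its ROI
   across all slides.  A shared-weight encoder (depth-wise separable
   convolutions) maps each patch to a feature vector; mean pooling and a
   linear Cox head produce a scalar case risk score f(X).  Because the head
   is linear, the case score equals the mean of per-patch scores, which
   gives exact permutation invariance and a natural patch-level risk
   decomposition.
3. **Training and evaluation.** The loss is the negative log Cox partial
   likelihood with Breslow tie handling, approximated per step over the
   sampled batch of cases; risk sets are formed within the batch.  The tune
   split is scored at fixed intervals on a deterministic patch sample; the
   selected checkpoint maximizes a trailing rolling mean (window 10) of the
   tune c-index.  Several models are trained and ensembled: each model's
   scores are standardized on the tune split, averaged, and the ensemble
   re-standardized on tune.  Final scores come from exhaustive inference
   over every selected ROI patch.
4. **Explanation.** Patch embeddings (hand-crafted texture statistics by
   default, or the trained encoder's pooled features) are clustered with
   k-means fit on a training-split sample.  Case-level features are the
   percentages (0–100) of a case's ROI patches per cluster; rows sum to
   100 for tumor-bearing cases.  OLS of standardized risk scores on these
   features (and, separately, on dummy-coded clinicopathologic covariates)
   quantifies explained variance via adjusted R²; forward stepwise
   selection extracts a small descriptive subset, and slide-blocked
   bootstrap summaries rank clusters by mean patch-level score.

## Survival model of the synthetic cohorts

Each case carries proportions z over tumor texture classes; the true log
hazard is η = Σ_c w_c·z_c with per-class weights w_c.  Survival times are
exponential with rate h₀·e^η, discretized to whole months by ceiling, and
right-censored by the earlier of a 120-month administrative horizon and an
independent exponential non-disease censoring time whose rate is set so
~10% of cases are censored before 60 months.  Events are decided on the
continuous scale before discretization, so an event and a censoring in the
same month resolve unambiguously.  The baseline hazard h₀ is solved by
Brent's method on the closed-form expected event fraction
E[λ/(λ+λc)·(1−e^{−(λ+λc)H})] to hit the configured event-rate target
(default 0.37).

Key generator defaults (desk scale): 400 cases, 2 slides/case, 8×8 patches
of 64 px per slide, 4 superpixels per patch edge, tumor fraction per slide
uniform on [0.4, 0.75], planted-class proportion uniform on [0, 0.5].
Texture classes are Gaussian-blob / oriented-stripe patterns over distinct
base colors — cheap, seedable, and separable by low-order color statistics,
which is what makes desk-scale training tractable.  Hazard weights default
to 0 for the two low-risk designations, 1.5 for the mid-risk tumor class
and 8.0 for the planted high-risk class.  The planted weight follows from a
closed-form concordance argument: with z_planted spread uniform on
[0, 0.5], the concordance of the true η under exponential hazards is
roughly E[logistic(|Δη|)], and a weight of 8 puts the ceiling near
c ≈ 0.76, leaving usable headroom for a trained model to demonstrate
recovery; materially smaller weights leave too little signal for any
method to detect at a few hundred cases.

What the generator does **not** emulate: realistic histologic appearance,
stain physics, intra-class morphological variability, pyramidal slide
formats, or correlations between covariates and morphology beyond a mild
tilt of T/N categories toward the planted proportion.  Passing tests
therefore demonstrate correctness of the machinery and recoverability of a
planted signal — not clinical performance on real cohorts.

## Numerical and design choices

- **Binarization** uses ≥ t, so thresholds returned by the recall
  calibration (the k-th largest positive score) are always attainable.
  Recall is pooled over superpixels of all slides; a per-slide variant is
  available.
- **Connectivity** for component removal defaults to 8-neighbor
  (configurable; 4 vs 8 diverges on diagonally touching components and both
  are tested).
- **The circular dilation filter** is the discrete disc
  {(dy,dx) : dy²+dx² ≤ r²}, boundary included; r = 0 is the identity.
- **Patch tiling** is anchored at the grid origin with 0-based half-open
  coordinates; coverage ties at exactly 0.5 are included.
- **Batches without events** are skipped with a logged count — the partial
  likelihood is undefined without an event.  Batch size 32 at a 37% event
  rate makes this rare.
- **Checkpoint ties** resolve to the earliest step; stepwise and cluster
  assignment ties resolve to the lowest index.
- **Color normalization** is one fixed per-channel affine map taking the
  training set's global channel mean/std to a fixed reference (0.5, 0.25 on
  the [0,1] scale).  A per-patch re-standardization would delete the very
  color statistics that distinguish texture classes; a single global map
  mirrors the intent of stain normalization (remove dataset-level color
  shift, keep relative differences).  Augmentation (training only) applies
  one of the 8 dihedral orientations plus bounded brightness/contrast and
  per-channel gain jitter; the evaluation path is deterministic.
- **Cox fitting** maximizes the Breslow partial likelihood by Newton's
  method with step halving; Wald CIs and p-values from the inverse
  information matrix.  lifelines implements Efron tie handling, so it is
  used as an independent cross-check on tie-free data rather than as the
  implementation.  Coefficients beyond |β| > 10 are flagged as possible
  separation.
- **c-index**: a pair is admissible iff the strictly earlier time is an
  observed event; score ties count 1/2.  **Horizon AUC**: positives are
  disease events at ≤ 60 months (boundary inclusive); cases censored for
  non-disease reasons before the horizon are excluded; everyone else is a
  negative.  Both match exhaustive pair-enumeration oracles exactly in
  tests.
- **Quartile thresholds** use linear-interpolation percentiles of the tune
  scores; ties are inclusive toward the extreme groups.  The log-rank test
  compares high vs. low only.
- **Stepwise objective** is adjusted R² by default (plain R² would always
  prefer more features); a flag switches to plain R².
- **Bootstraps** default to 1000 replicates (configurable; the full-scale
  convention of 9999 for the c-index is expressible), all seeded.  Patch
  score CIs resample whole slides to respect within-slide correlation.
- **Desk-scale sizes**: 300 training steps with evaluation every 30 steps,
  32 tune-eval patches per case, embedding samples of ~2000 patches and a
  k grid of {4, 8} are the package defaults; the full-scale settings
  (2M steps, eval every 10k, 1024 eval patches, 100k-patch samples,
  k up to 500) remain expressible through the same configuration fields.

## Leakage discipline

Everything that is fit — the probability threshold, color statistics, score
standardization constants, cluster centroids, the cluster count k — derives
from the train and tune splits only.  The pipeline records the case ids
entering every fitting step in `provenance.json`, and a test asserts that
no validation id ever appears there.  The explanation regressions are
computed on validation cases by design (they describe where the model's
scores come from, not predictive performance).

## Known limitations

- The texture classes are separable by first-order statistics; the encoder
  is therefore not stress-tested on subtle morphology.
- The generator's covariates are only weakly linked to morphology, so the
  clinicopathologic regression explains a modest share of score variance
  by construction.
- Non-disease censoring is independent of risk by construction; informative
  censoring is out of scope.
- The embedding model of the original full-scale system (an image-similarity
  network trained on natural images) is replaced by deterministic texture
  statistics or the trained encoder's features; both satisfy the pipeline's
  only requirement that visually similar patches embed nearby.
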