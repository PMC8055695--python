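# histoprog

Weakly supervised survival prediction from whole-slide histopathology
images, with a cluster-based explanation pipeline — packaged with a
synthetic-cohort generator so the complete method (ROI masking, bag-of-
patches Cox training, survival evaluation, interpretability) is trainable
and testable on a single CPU in minutes.

## The problem

Predicting disease-specific survival (DSS) from routine H&E slides is a
weakly supervised problem: outcomes are known per *case* (a patient with
many gigapixel slides), not per image region.  A standard approach scores a
case as a *bag* of image patches drawn from tumor-containing regions, and
trains the patch encoder end-to-end against a survival loss.  The scores
such models learn are opaque; the second half of this package quantifies
how much of their variance is explained by human-interpretable features
obtained by clustering patch embeddings.

## The model

A tumor-probability heatmap on a superpixel grid is turned into a region
of interest by thresholding (threshold calibrated to a recall target),
removing positive connected components smaller than 8 superpixels, and
dilating with a circular filter of radius *r*.  Patches at least half
inside the mask are eligible for prognostication.

The prognostic model scores a case X as

    f(X) = w' · mean over patches p in X of phi(p) + b

where phi is a small shared-weight CNN with depth-wise separable
convolutions.  Training minimizes the negative log Cox partial likelihood
with Breslow tie handling over each batch of cases,

    L = - sum over events i of [ f(X_i) - log sum_{j : T_j >= T_i} e^{f(X_j)} ],

where T_i is the event or last-follow-up time (whole months) and the sum
in the denominator runs over the batch's risk set; tied events share the
denominator.  Checkpoints are picked by the rolling-mean (window 10) tune
c-index; the top models are ensembled by averaging tune-standardized
scores; final case scores come from exhaustive inference over every ROI
patch.

Evaluation uses 5-year DSS AUC (excluding cases censored for non-disease
reasons before the horizon), Harrell's c-index, Breslow Cox regressions
with standardized scores / per-decade age / dummy-coded categories, and
quartile-threshold Kaplan–Meier risk groups with log-rank tests.

Explanation: k-means clusters of patch embeddings define case-level
features (percentage of a case's tumor patches per cluster, 0–100).  OLS
of the standardized scores on these features measures explained variance
(adjusted R-squared); forward stepwise selection extracts a descriptive
subset; slide-blocked bootstraps summarize patch-level scores per cluster;
and a single cluster's quantitation can be evaluated as a standalone
prognostic score.

Because no public cohort accompanies the method, the package ships a
seedable generator of synthetic cohorts in which procedural texture
classes play the role of histologic patterns: one planted high-risk class
drives a proportional-hazards survival model through its case-level
proportion, so every stage has ground truth.  See `docs/methods.md` for
the generative model, defaults, and what the synthetic setting does and
does not demonstrate.

## Worked example

Train and explain a 400-case synthetic cohort end to end (about five
minutes on one CPU):

```python
from histoprog.config import RunConfig, ExplainConfig, EvalConfig
from histoprog.survmodel import TrainConfig
from histoprog.synthdata import CohortConfig
from histoprog.pipeline import run_pipeline

config = RunConfig(
    cohort=CohortConfig(n_cases=400),
    train=TrainConfig(steps=300, eval_every=30, eval_patches_per_case=32),
    n_models=2,
    eval=EvalConfig(n_boot=200),
    explain=ExplainConfig(sample_patches=2000, k_grid=(4, 8),
                          patch_score_sample=2000, n_boot=200),
    seed=1,
)
result = run_pipeline(config, "runs/demo")
m = result.metrics
print("tune c-index        ", round(m["tune_best_c_index"], 3))
print("val1 5-year AUC     ", round(m["val1"]["five_year_auc"]["auc"], 3))
print("cluster adj R^2     ", round(m["explain"]["cluster_full_adj_r2"], 3))
print("clinicopath adj R^2 ", round(m["explain"]["clinicopath_adj_r2"], 3))
```

which prints (seed 1):

```
tune c-index         0.826
val1 5-year AUC      0.743
cluster adj R^2      0.771
clinicopath adj R^2  0.016
```

Reading: the ensemble recovers the planted prognostic signal (tune c-index
0.83); on the held-out split its score discriminates 5-year
disease-specific death well above chance (AUC 0.74, c-index 0.72,
univariable hazard ratio 2.7 per SD, log-rank p < 0.001 for the high- vs
low-risk quartile groups); the cluster-derived features explain ~77% of
the variance in the scores — the planted high-risk cluster carries the
largest positive coefficient — while the loosely-linked clinicopathologic
covariates explain almost none.  The run directory contains the manifest,
scores, metrics, Kaplan–Meier curve tables and the full explanation
reports (feature matrix, regression coefficients, per-cluster patch-score
summaries).

The same pipeline is scriptable from the shell:

```bash
histoprog run --out runs/demo --seed 1
histoprog simulate --out runs/cohort --seed 7 --write-images
```

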