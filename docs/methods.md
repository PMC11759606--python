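# Methods

`pathomil` implements a weakly supervised pathomics pipeline for H&E
whole-slide images: slides are cut into fixed-size tiles, a patch-level
classifier is trained with slide-inherited (weak) labels, per-patch class
likelihoods are fused into slide-level feature vectors, and those features
drive a metastasis classifier and a penalized Cox survival model.  Because
real slide cohorts of this kind are rarely shareable, the package ships a
synthetic-slide generator that reproduces the statistical structure the
pipeline assumes, so every stage is exercisable and testable end to end.

## The model, stage by stage

**Tiling and normalization.** A slide image is partitioned into the largest
grid of non-overlapping `tile_size x tile_size` squares anchored at the
origin (default 512 px; partial edge tiles are discarded rather than padded,
preserving the fixed-size contract).  A tile is background iff the fraction
of pixels with all three RGB channels >= `white_level` (220) strictly exceeds
`white_fraction` (0.8); background tiles are excluded before normalization
(cheaper; the order is configurable).  Colour is standardized with Reinhard's
method in the original Ruderman l-alpha-beta space: RGB -> LMS -> log10 ->
decorrelated lab, then per channel `(x - mu_tile) * sigma_ref / sigma_tile +
mu_ref`, and back.  A near-constant channel (sigma below 1e-8) is shifted
only, never rescaled.  The reference defaults to the first non-background
tile of the cohort; any reference can be supplied as JSON.

**Patch learning.** Every tile inherits its slide's ER status as training
label (the multiple-instance weak-label assumption, asserted before
training).  Inputs are per-tile, per-channel Z-scored (configurable;
dataset-wide statistics are a documented alternative), training-time
augmentation is random crop (fraction 0.9, resized back) plus independent
horizontal/vertical flips, and optimization is plain SGD on softmax
cross-entropy under the cosine-decay schedule
`eta(t) = eta_min + (eta_max - eta_min)(1 + cos(pi t / T_i)) / 2` with
defaults `eta_max = 0.01`, `eta_min = 0`, `T_i = 50`.  The default
`tiny_cnn` backbone is a compact two-layer softmax network (64 ReLU hidden
units) over the tile resized to 32x32x3 — deliberately small so that the
full pipeline trains on one CPU in minutes; the large ImageNet backbone
names are accepted in the config for interface compatibility but are not
implemented in this build.  Per-epoch learning rate, loss and accuracy are
recorded; a non-finite loss aborts with diagnostics.

**Slide fusion (206 features).** Each slide's bag of patch likelihoods is
summarized twice.  PLH: a histogram over 101 equal-width bins on [0, 1]
(edges k/101, last bin closed), count-normalized to sum to 1 so slides with
different tile counts are comparable.  BoW: each patch is quantized to one
of the same 101 bins ("words"); tf is the within-slide word frequency, idf
is the smoothed `ln((1+N)/(1+df)) + 1` fitted on training slides only and
frozen for test slides.  Each pipeline adds two predictive-label features —
majority vote of hard patch labels (ties resolve to 1) and the indicator
that the mean likelihood is >= 0.5 — giving 2 x (101 + 2) = 206 features
with fixed, documented names (`plh_000..plh_100, plh_label_major,
plh_label_meanprob`, then the `bow_` block).

**Feature selection.** A greedy scan in canonical column order drops any
column whose absolute Pearson correlation with an already-kept column
strictly exceeds 0.9 (absolute: anti-correlated duplicates are equally
redundant).  Constant columns have undefined correlation and are dropped
with a log entry.  The filter is fitted on training rows only.

**Metastasis models.** Random forest, XGBoost and LightGBM (fixed default
hyperparameters, single-threaded, seeded for determinism) are fitted on the
selected features.  Reported per cohort: accuracy, rank AUC with a DeLong
95% CI (chosen over bootstrap for determinism), and
sensitivity/specificity/PPV/NPV at a Youden-optimal threshold chosen on the
training cohort and frozen for test.  0/0 ratios are reported as 0 and
flagged.

**Survival models.** The Cox fit minimizes the negative Breslow partial
log-likelihood plus `(c/2)||beta||^2` with `c = 0.3` by default; `c` weights
the *summed* (not per-observation) likelihood, so shrinkage is mild at
n = 200 — this parameterization is the package's documented reading of an
otherwise ambiguous penalty constant.  The pathomics signature is the linear
predictor of a ridge Cox fit over the selected slide features (there the
penalty is applied per observation, since the feature count is comparable to
the cohort size); the final model combines signature, age, Ki-67 and
metastasis status.  Discrimination is Harrell's C (risk ties count 1/2).
Risk groups come from scanning percentiles 20..80 (step 5) of the training
risk score and keeping the threshold with the smallest log-rank p; the
threshold is frozen before the test cohort is touched.  Under a null risk
score this min-p scan is exploratory by construction and is reported as
such.  The nomogram maps each covariate affinely to points (0 at its
lowest-hazard range end; the largest |coef| x range spans 0..100) and total
points back to survival probability via the baseline survival function at
horizons 36 and 60 months (configurable).

## The synthetic cohort generator

Each slide receives an ER label ~ Bernoulli(`er_prevalence`, default 0.5).
Each tile draws a latent class likelihood p from Beta(8, 2) for ER+ slides
and Beta(2, 8) for ER- slides (the "strong plant": population means 0.8 vs
0.2).  The tile image is painted so that simple statistics are monotone in
p: a pink stroma base (RGB 232/186/212 with sigma = 6 noise), a hue shift of
(-25, -35, 0) x p, and dark purple nucleus-like blobs (count ~
Poisson(2 + 55 p) per 64 px square, radius U(3, 6) px).  Both a trivial
dark-pixel-fraction feature and the tiny network recover p from this
painting; the blob signal survives per-tile Z-scoring, which removes the hue
cue.  Metastasis labels follow a logistic model on (1, mean, sd) of the
slide's latent likelihoods with default coefficients (-4, 8, 0), giving
per-class metastasis probabilities of about 0.92/0.08 under the strong plant
— an attainable-ceiling test AUC near 0.92.  Survival times are exponential
(Weibull shape configurable) with linear predictor `1.0 * risk + 0.3 *
age_std + 0.5 * ki67`, where risk is the standardized slide mean latent
likelihood; censoring is an independent exponential time whose rate is
bisected to the target censoring fraction (default 0.3).  Age ~
N(52.6, 10.4) years and Ki-67 ~ scaled Beta on [0.01, 0.90] provide realism
only.  All randomness flows from a single seed; identical (config, seed)
pairs are bit-identical.

The **null condition** (`null_config`) sets both Beta shapes equal *and*
zeroes the slide-feature weights of the metastasis model.  Equalizing only
the Beta shapes would leave the metastasis label weakly tied to the slide's
mean latent likelihood — a residual signal path, not a null — so the null is
defined as labels that are fair coin flips.

What the generator does *not* emulate: real histology texture, stain
physics, intra-slide spatial correlation of tumor regions, annotation noise,
scanner artifacts, or class-imbalanced cohorts.  Passing tests therefore
demonstrate that the pipeline's machinery is correct and recovers planted
structure under its own assumptions — not that any particular accuracy will
transfer to real slide cohorts.

## Problem sizes and numerical choices

The standard end-to-end study condition is 120 slides x 100 tiles at 64 px
tile size (12,000 tiles; roughly two minutes on one CPU), with the tiny
backbone trained for 10 epochs.  The 64 px tile size is the package's
desk-scale choice for synthetic work — the 512 px default remains the
contract for real slides.  Patch-level unit checks use 60 slides x 40 tiles
with 5 epochs and no augmentation (augmentation costs a few AUC points at
that horizon and is a robustness device, not part of the learnability
check).  Cox recovery uses n = 200 with 30% censoring; log-rank calibration
uses 1000 null simulations of n = 100.  Convergence tolerance of the Cox
fit follows lifelines defaults; ties use Breslow.  Degenerate inputs are
rejected with messages rather than silently coerced (empty likelihood bags,
single-class labels, constant covariates, no events, zero nomogram scale).

## Known limitations

* The tiny backbone is a fully connected network on downsampled tiles; it is
  sufficient for the painted signal but is not a stand-in for modern CNN
  accuracy on real histology.
* The BoW vocabulary is the fixed 101-bin quantization, not a learned
  codebook; the two fusion pipelines therefore share their bin rule by
  design, and their label features are identical pairs.
* The min-p percentile threshold search inflates the training log-rank
  significance; only the frozen-threshold test-cohort separation should be
  interpreted inferentially.
* DeLong intervals assume independent subjects; clustered slides per patient
  would need a clustered variance estimate.
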