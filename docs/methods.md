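# Methods

This note documents the models and procedures implemented in `scintrec`,
the parameter choices that matter, and what the synthetic data do and do
not establish.

## Problem setting

The pipeline predicts a binary recurrence label for localized / locally
advanced prostate-cancer patients from two feature sources: a clinical
table (age, initial PSA, Gleason patterns, grade group, TNM stage,
D'Amico-style risk class, treatment and comorbidity flags) and radiomics
features of whole-body planar bone scintigrams (anterior + posterior
count images). The scientific question the evaluation answers is
comparative: does adding scintigram texture to the clinical features
improve cross-validated discrimination?

## Body-mask segmentation

A scintigram is a grid of Poisson-distributed photon counts.  Off-body
pixels carry near-zero background, so the mask is recovered with plain
morphology:

1. **Threshold** raw counts at ≥ 2.  The cutoff applies to the raw count
   scale, *before* unit scaling (the published description leaves the
   scale implicit; applying it to raw counts makes the threshold
   physically meaningful and is configurable).
2. **Closing then opening**, 3 × 3 square structuring element, one
   iteration each by default (the source procedure names the operations
   but not the element or counts).  Closing is implemented as dilation
   followed by erosion with out-of-image pixels treated as foreground,
   so it is genuinely extensive at the border; opening is the dual.
3. **Small-component removal**: 8-connected components with area < 10 %
   of the largest component are discarded (fraction configurable).  The
   largest component, and any component tied with it, is always kept.
   This is the stage that removes catheter streaks and injection-site
   blobs.
4. **Hole filling**: background regions not 4-connected to the image
   border are set (standard 8/4 foreground/background duality).
5. A final closing + opening separates the body from adjacent structures.

Each stage logs the retained area; an empty intermediate mask raises an
error naming the stage.  On 50 random phantoms the pipeline reaches mean
IoU ≥ 0.90 against the generator's noise-free silhouette, the in-repo
stand-in for expert mask validation.

## Radiomics

Per view: unit-scale the image ((x − min)/(max − min), constant image →
zeros), discretize the in-mask values with a **fixed bin count**
(default 32; level = ⌊(x − min)/range · Ng⌋ + 1, maximum mapped to Ng),
then build four texture matrices:

* **GLCM** — symmetric co-occurrence at distance 1 along 0°, 45°, 90°,
  135°; normalized per direction; features averaged over directions.
* **GLRLM** — maximal same-level runs along the same four directions;
  runs break at the mask boundary; features direction-averaged.
  Conservation: Σ count(g, r)·r = in-mask pixel count per direction.
* **GLSZM** — 8-connected equal-level zones; Σ count(g, s)·s = pixel
  count.
* **NGLDM** — per-pixel count of in-mask Chebyshev-radius-1 neighbours
  with |Δlevel| ≤ α (α = 0, the classic definition); Σ counts = pixel
  count.  The dependence axis is shifted to j = d + 1 in the feature
  formulas so reciprocal weights are defined at zero dependence.

The shipped catalogue is 18 first-order + 17 GLCM + 12 GLRLM + 12 GLSZM
+ 5 NGLDM = **64 features per view**, 128 per patient with `front_` /
`back_` prefixes.  The split is configurable but the default totals are
fixed.  First-order skewness is m₃/m₂^1.5 and kurtosis m₄/m₂² (no excess
correction), both declared 0 on a constant ROI; TotalEnergy uses
pixel_area = 1 because physical pixel spacing is not modelled.  Feature
values are validated against brute-force enumeration oracles (all 2 × 2
configurations and random 6 × 6 ROIs) and are invariant under joint
translation and horizontal mirroring of image + mask.

Degenerate ROIs (no valid pixel pair in a direction) fall back to a
single-entry matrix so features behave like those of a constant ROI; a
warning is logged.

## Design matrices

Categorical variables are one-hot encoded against a fixed schema
(categories are part of the schema, never inferred per fold, so unseen
values are hard errors and encodings are fold-stable).  Full one-hot is
used — no dropped reference level; harmless for tree models, and the
logistic model is fitted with regularization so the collinearity is
benign.  Continuous clinical variables and all radiomics columns are
min-max scaled with statistics **fitted on training rows only** and
applied to test rows with clipping to [0, 1]; a test verifies that
perturbing test rows cannot change the fitted transform.  Records with
missing values are rejected rather than imputed.  Four variants are
built: `damico` (risk class only), `tnm` (T + N stage), `clinical`
(all schema columns), `clinical_radiomics` (clinical + 128 features).

## Rebalancing

SMOTE is implemented directly: pick a minority row, pick one of its
k = 5 Euclidean-nearest minority neighbours (k is the classic default),
and interpolate uniformly on the connecting segment.  Distances are
computed on the assembled numeric matrix, one-hot columns included.
Provenance (seed row, neighbour, λ) is returned for every synthetic row.
Alternative modes: minority duplication, majority reduction (subsampling
without replacement), and a combined mode that subsamples the majority
halfway toward the minority count before SMOTE-ing the minority up to
the target ratio (the source description is ambiguous about how the
methods were combined; the mode flag exposes all readings).

Rebalancing is applied **inside each training fold only**.  Resampling
before splitting would place synthetic near-copies of test points into
the training set and inflate every metric; the pipeline therefore
forbids it.  This is a deliberate strengthening over the published
description, which does not state where resampling sat relative to CV —
a known caveat when comparing absolute numbers.

## Evaluation

Stratified 5-fold CV (per-fold class counts within ±1 of proportional;
deterministic under a seed).  All models share one fold assignment so
pooled out-of-fold scores are paired.  Within each fold: fit the
normalizer on training rows, rebalance the training rows, fit, score the
untouched test rows.  Threshold metrics use the 0.5 cutoff on scores;
ratios with zero denominators are reported as 0 and flagged.  Aggregates
are reported as mean (min–max) over folds; the pooled confusion matrix
concatenates test-fold predictions and therefore totals the cohort size.

AUC is the tie-corrected Mann–Whitney statistic (implemented in-repo,
checked against an exhaustive pairwise oracle).  Paired AUCs are
compared with the **DeLong test** for correlated ROC curves (the
comparison test is not named in the source; DeLong is the standard
choice for same-cohort model comparison, and its variance is checked
against a bootstrap in the tests).  Model families: logistic regression
(max_iter 5000), Gaussian naive Bayes, random forest (100 trees), SVC
with Platt-style calibrated probabilities (CalibratedClassifierCV,
3-fold, ensemble=False), and XGBoost (100 trees, depth 4, hist).
Hyperparameters are the common library defaults, frozen in code for
reproducibility; no tuning is performed.  Feature importances are RF
mean impurity decrease, normalized to sum to 1, top-10 with a
clinical/radiomics tag.

## Synthetic data

The generator defines the study conditions:

* **Cohort** — default n = 354, prevalence 0.2853.  Clinical features
  are drawn from distributions shaped like a real localized-PCa
  population (age ≈ N(70, 7.5); log-normal PSA with median ≈ 11 ng/mL;
  Gleason patterns concentrated on 3/4; T2 most common, T3 ≈ 33 %;
  ISUP grade group derived from the patterns; risk class from a
  simplified three-tier rule).  The label is Bernoulli with
  P = expit(α + latent), latent = Σβᵢzᵢ + u, where the default βs put
  recurrence risk on advanced T stage, N1, high log-PSA, high Gleason
  primary pattern and RP (positive) and RT (negative), u ~ N(0, 0.8) is
  unexplained risk, and α is solved by root finding so the cohort's
  expected prevalence equals the target.
* **Images** — a parametric whole-body silhouette (head/neck/torso/
  pelvis/arms/legs from ellipses and bars, verified 4-connected),
  background 0.3 counts, body 40 counts, Gaussian hot-spot lesions
  (σ ∈ [1, 3] px) whose expected number is
  lesion_mean · exp(0.4 · coupling · latent), an off-body catheter
  streak (1–3 px wide, touching the bottom border, probability 0.15)
  to exercise component removal, and Poisson noise on expected counts.
  Ground truth (silhouette, lesion ledger, catheter position) is
  recorded for every patient.
* **Seeding** — cohort-level and per-patient seeds derive from
  `SeedSequence`, so individual patients re-render bit-identically; the
  pipeline fans a single master seed out to per-stage seeds the same
  way.

What the phantoms do **not** emulate: anatomical tracer distribution,
scanner-specific blur/scatter, patient positioning variation, and any
real association structure between image texture and biology.  Passing
tests therefore establish that the pipeline is *correct and leak-free*
and that it *recovers planted signal*; they say nothing about clinical
performance on real scintigrams, and the published cohort's numeric
results are not reproduction targets (its data were never deposited).

## Problem sizes

The test suite runs the full design at desk scale: phantom geometry
128 × 40 (the full 1024 × 256 geometry is supported and used nowhere the
suite needs speed), cohorts of n = 354 for calibration/recovery checks
(20 replicate seeds each), 50 phantoms for segmentation quality.  These
sizes are the package's chosen desk-scale defaults for its own
verification; all are configurable.

## Known limitations

* 2-D features only; no shape, wavelet or 3-D features (out of scope).
* Feature values are not bit-compatible with any external radiomics
  package; correctness is defined by the in-repo formulas and oracles.
* The exact iteration counts / structuring element of the published
  mask procedure are unstated; the defaults here are documented choices.
* With heavy class imbalance and small folds, per-fold metrics are
  noisy; the mean (min–max) presentation makes that visible rather than
  hiding it.
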