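# Methods

This note documents the statistical model behind `proteoscreen`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## The screening model

The object under test is a feature × sample intensity matrix; the unit of
decision is a *sample* (one measurement run). The method rests on one
idea: a genuine outlier sample should be flagged robustly — by many
different unsupervised detectors, against many different random subsets of
the cohort — whereas a borderline sample's flags should wash out over
perturbations of the "hypothesis space" the detectors are fitted in.

**Resampling.** Each round draws ⌈f·n⌉ samples without replacement
(default f = 0.8) and fits every detector configuration on that subset
only; flags are assigned within the subset, and samples outside it get no
observation that round. The within-subset reading (rather than fit-on-
subset / score-everyone) is deliberate: it makes every flag conditional on
a sampled cohort, which is the point of the perturbation. One master seed
drives the run; per-round substreams come from fixed offsets, so extending
`n_rounds` never changes earlier rounds.

**Vote aggregation.** Votes are counted per *model*, not per model ×
round: a configuration votes "outlier" on a sample iff the sample was
flagged in strictly more than half of the rounds that contained it (ties
count as normal, the conservative direction). Per-sample outlier and
normal votes therefore always sum to the number of configurations — this
is what makes the downstream chi-square test well-posed, since its total
count must be fixed across samples.

**Confirmation.** For each sample with an outlier-vote majority, the vote
split (a, b) is tested against an even split with the one-degree-of-
freedom Pearson goodness-of-fit statistic χ² = (a−b)²/(a+b), no continuity
correction, upper-tail p. Confirmation requires p < α (default 0.05) and
a > b. With 91 voters the smallest confirming split is 55/36. Samples
with a normal-vote majority are excluded from testing entirely — the test
asks "is this candidate's majority too large to be chance?", not "is any
sample unusual?".

**Grouped cohorts.** When group labels are supplied (e.g. tumor vs normal
adjacent tissue), every stage — including preprocessing — runs per group,
because normalization and detector geometry are only meaningful within a
biologically comparable cohort.

## Detector pool

Ten detector families are enumerated over fixed hyperparameter grids into
170 configurations (neighbour counts × distance metrics for LOF/KNN/
AvgKNN; cluster counts × seeds for CBLOF; kernels × ν for OCSVM; neighbour
counts for ABOD; contamination levels for ECOD; tree counts × seeds for
IForest; estimator counts × seeds for FeatureBagging over an LOF base;
pool sizes × seeds for the locally selective LOF/KNN combination). The
grids live in `registry.py`; enumeration is pure (no RNG), and every
configuration carries an explicit seed so stochastic families are
reproducible.

All scorers obey one contract: higher raw score = more outlying; flags are
scores strictly above the (1 − contamination) quantile (default
contamination 0.1); degenerate (zero-variance) data flags nothing.
LOF, OCSVM and IForest delegate to scikit-learn estimators; KNN/AvgKNN are
computed from shared pairwise-distance matrices; the angle-variance
(ABOD), empirical-CDF tail (ECOD), cluster-based score (CBLOF on k-means
partitions with the α = 0.9 / β = 5 large-cluster rule), feature-bagged
LOF, and the locally selective combination (pseudo-ground-truth = mean of
z-normalized pool scores; per-sample local region from kNN unions over
random feature subspaces; top-2 locally correlated detectors averaged) are
implemented in `detectors.py`.

The shipped default selection keeps 91 configurations over seven families
(all LOF, CBLOF, FeatureBagging and LSCP configs; 10 KNN; 16 AvgKNN;
5 OCSVM). The per-family counts follow the published post-selection pool;
the within-family picks are a deterministic synthetic stand-in (smallest
grid values, euclidean/manhattan metrics, rbf kernels first), because the
original per-configuration list is not distributed. Users who run the
benchmark on their own cohort get a selection YAML they can pass instead.

## Model-selection benchmark

Simulated outliers are made by **feature shuffling**: for a target sample,
round(p·F) features are drawn and their values permuted *within that
sample*. This destroys the sample's feature-to-value assignment while
leaving its marginal intensity distribution untouched — so a shuffled
sample is an outlier of controlled severity that survives quantile
normalization (which equalizes marginals by construction). A cross-sample
permutation variant was considered and rejected as the default because it
changes marginals and conflates severity with abundance drift.

For each configuration, accuracy (correct labels / all samples, perturbed
group = positives, contamination set to the true perturbed fraction) is
measured over proportions 10%…100% × groups × repeats (default 10 × 10 ×
10 = 100 accuracies per proportion). The per-proportion coefficient of
variation CV = sd/mean of those accuracies is scanned with the
Mann–Kendall test over suffixes: the *detection point* is the smallest
starting proportion whose CV suffix shows no significant trend (two-sided
p ≥ 0.05). "Stable" = "no significant trend" is the reading adopted here;
the opposite reading would call a still-changing curve converged. The
two-point suffix (start 90%) cannot carry a trend test and counts as
stable only when its CVs differ by < 1e-6.

The cross-configuration vote takes the modal detection point (ties → the
smaller), sets the criterion at the next 10% node (capped at 100%), and
selects configurations with detection point ≤ criterion and mean accuracy
strictly above 90% *at their detection point* (the gate is applied at the
detection point, not across all proportions below the criterion — the
latter reading is stricter and can be obtained by filtering the returned
per-proportion accuracy table).

Fitting is done on the full clean + perturbed matrix each trial
(unsupervised fit-on-everything), since in production the detector never
sees a guaranteed-clean reference.

## Baseline QC

Per sample: identification count (observed features) and mean pairwise
Pearson correlation on log2 intensities over co-observed features (≥ 3
required per pair). Grubbs' test uses the max-deviation statistic
G = max|xᵢ − x̄|/s with the t-quantile critical value
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) quantile at n−2 df;
the reported p-value is the max-statistic (union-bound) p. Iterative mode
removes one point per pass until no rejection. Note that masked pairs of
outliers can defeat the test entirely (two extremes inflate s enough that
neither is flagged) — this is a property of the test, and one reason the
ensemble screen exists. The same two screens drive `curate_clean`, which
strips flagged samples before the benchmark.

## Synthetic generator

`generate()` emulates a label-free proteomics matrix at log2 scale:
per-feature means ~ N(25, 2²) (typical deep-proteome LFQ range), residual
sd 1.0, features in blocks of 20 sharing a per-sample latent factor with
intra-block correlation ≈ 0.6 (co-regulated modules). Missingness is MNAR:
dropout probability is a logistic function of intensity whose threshold is
calibrated by root finding so the realized overall rate matches the
request (within ±0.02 at 50 × 500).

Outlier mechanisms: `shift` displaces a random half of the sample's
features by ±magnitude·sd with random signs — random subset and signs are
essential, because a uniform all-feature shift preserves within-sample
ranks and would be erased exactly by quantile normalization, making the
"outlier" undetectable by construction; `noise` inflates the sample's
residuals; `shuffle` applies feature shuffling.

What the generator does *not* emulate: peptide-to-protein rollup,
intensity-dependent variance (heteroscedasticity beyond MNAR), batch
structure, or biological subpopulations. Passing the recovery tests
therefore shows the machinery is correct and calibrated on clean
log-normal cohorts, not that real-data outliers of every kind are caught.

## Numerical conventions and edge cases

- Missing-fraction filter uses strict ">": a feature missing in exactly
  75% of samples is kept.
- MaxQuant zeros are treated as missing; `Reverse`, `Potential
  contaminant` and `Only identified by site` rows are dropped on read.
- Quantile normalization: tied values within a sample receive the mean of
  their tied quantile means. This tie dialect means strict idempotence and
  exact multiset equality hold on tie-free data only; with ties (e.g.
  after minimum imputation) repeated application can move tied entries by
  the tie-group averaging.
- LOESS normalization: per-sample lowess of log2 values against the
  per-feature median profile, span 0.7, one robustness iteration; the
  fitted deviation from the reference is subtracted.
- Flag threshold uses `np.percentile` (linear interpolation) with strict
  ">", giving ≈ contamination·n flags up to integer rounding.
- Configurations infeasible on a subset (neighbour count ≥ subset size)
  are skipped for that round with a logged warning; a sample never
  observed by any round raises an error advising more rounds.
- A remote lone point can receive its own rbf support region under OCSVM
  and score as an inlier; this is inherent to the estimator and one reason
  the ensemble does not rely on any single family.

## Problem sizes used in the shipped checks

The recovery study runs 20 synthetic cohorts of 60 samples × 200 features
(3 planted 6-sd shift outliers each) through the full 91-configuration
pipeline at 25 resampling rounds; the benchmark harness check uses 3
configurations × 3 proportions × 2 groups × 2 repeats on a 24-sample
cohort. These sizes were chosen to exercise every code path at desk scale
while keeping the whole suite reproducible in minutes; all quantities they
compute are produced at run time.

## Known limitations

- The default 91-configuration selection reproduces published per-family
  counts, not a published per-configuration list (see above); selections
  derived by running the benchmark on your own cohort are preferred.
- Chi-square confirmation treats the 91 model votes as independent
  Bernoulli trials, which they are not (configurations share data and
  often neighbours); the test is a calibrated decision rule, not a valid
  independence-based p-value.
- With contamination 0.1 and fewer true outliers than the contamination
  budget, the most extreme normal samples collect votes; occasional
  confirmed false positives (≈ 2–4% of normals on the synthetic cohorts)
  are expected and should be reviewed against the QC table.
- Detectors are refitted per subset; on very large cohorts (n ≫ 10³) the
  LSCP and FeatureBagging families dominate runtime.
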