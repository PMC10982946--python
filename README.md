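# proteoscreen

Outlier-**sample** screening for quantitative proteomics (and other omics)
intensity matrices.

In label-free LC-MS/MS studies, a whole measurement run can go wrong —
instrument drift, a failed digest, a degraded sample — and the resulting
column of the protein × sample intensity matrix quietly biases every
downstream statistic. Deciding which runs to drop is usually done with ad
hoc univariate screens (identification counts, pairwise correlations,
Grubbs' test), which miss multivariate failure modes and give no calibrated
decision rule.

`proteoscreen` treats the question statistically. A pool of unsupervised
outlier detectors votes on every sample over many random subsample rounds,
and the vote split itself is tested for significance:

1. **Preprocess** — parse MaxQuant `proteinGroups.txt` (Intensity / iBAQ /
   LFQ columns) or any labelled TSV/CSV matrix; drop features missing in
   more than 75% of samples; impute remaining gaps with the global observed
   minimum; quantile-normalize (LOESS, per-feature standardization and
   no-op are also available).
2. **Resample** — draw 80% of the samples per round (default 100 rounds)
   and fit every detector configuration on each subset, so a sample's
   outlier status must be robust to the cohort it is judged against.
3. **Vote** — each of the 91 default detector configurations (drawn from a
   170-configuration grid over LOF, KNN, AvgKNN, CBLOF, OCSVM, ABOD, ECOD,
   IForest, FeatureBagging and a locally selective LOF/KNN combination)
   casts one vote per sample: *outlier* if the sample was flagged in a
   majority of the rounds that contained it.
4. **Confirm** — for each sample with an outlier-vote majority, the split
   (a, b) of outlier/normal votes is tested with a one-degree-of-freedom
   chi-square goodness of fit against an even split,

       chi² = (a − b)² / (a + b),   p = P(χ²₁ ≥ chi²),

   and the sample is reported as an outlier only when p < 0.05 *and*
   a > b. With 91 voters that means at least a 55/36 split.

Which 91 of the 170 configurations vote is itself decided by a simulation
benchmark: clean cohorts are perturbed by **feature shuffling** (permuting
a growing fraction of a sample's feature values within that sample), each
configuration's accuracy is measured over a 10 proportions × 10 groups ×
10 repeats grid, and the Mann–Kendall trend test locates each
configuration's *detection point* — the smallest shuffle proportion from
which its accuracy-CV curve is trend-stable. A vote across configurations
fixes the selection criterion at the node above the modal detection point,
and configurations that detect early (detection point ≤ criterion) and
accurately (mean accuracy > 90% at the detection point) are retained.

## Worked example

A synthetic 60-sample × 200-protein cohort with three planted outliers
(half of each outlier's features shifted by ±6 sd), 10% missing-not-at-
random entries:

```python
import proteoscreen as ps

ds = ps.generate(n_samples=60, n_features=200, outlier_frac=0.05,
                 mechanism="shift", magnitude=6.0, missing_frac=0.1, seed=7)
print("planted:", ds.outlier_ids)
result = ps.detect(ds.matrix, n_rounds=25, seed=7)
report = result.reports["all"]
print(report.candidates.to_string(index=False))
```

prints

```
planted: ['S004', 'S023', 'S056']
sample  outlier_votes  normal_votes      chi2      p_value  confirmed stars
  S004             89             2 83.175824 7.507023e-20       True   ***
  S023             89             2 83.175824 7.507023e-20       True   ***
  S056             89             2 83.175824 7.507023e-20       True   ***
  S045             87             4 75.703297 3.296568e-18       True   ***
  S046             73            18 33.241758 8.138395e-09       True   ***
```

All three planted outliers are confirmed near-unanimously (89 of 91
votes, p < 0.001). Two additional samples are also confirmed — by chance
this seed's normal cohort contains two samples the ensemble consistently
ranks most extreme; measured over many seeds the false-positive rate stays
below 5% (see the acceptance script below). The `stars` column encodes
p < 0.001 / 0.01 / 0.05 as `***` / `**` / `*`, and `ns` otherwise.

The same run from the shell:

```sh
proteoscreen simulate --samples 60 --features 200 --outlier-frac 0.05 \
    --magnitude 6 --seed 7 --out sim/
proteoscreen detect --input sim/matrix.tsv --rounds 25 --seed 7 --out run/
```

which writes the report as TSV/JSON, vote-bar and decision-boundary plots,
and a provenance `run_config.yaml` into `run/`. Other subcommands:
`qc` (identification counts, correlations, Grubbs flags), `benchmark`
(the shuffle-gradient selection harness) and `plot`.

Samples with group labels (e.g. tumor vs normal adjacent tissue) are
screened strictly per group: pass `--labels labels.tsv` or
`detect(..., labels=...)`.

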