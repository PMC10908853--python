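# Methods

## The resampling model

`csbboost` balances a binary training set of size `N` by simultaneous
cluster-weighted under-sampling of the majority class and cluster-weighted
SMOTE over-sampling of the minority class, so that each class ends up with
about `N/2` rows and the balanced set has (almost) the original size.

Each class is clustered separately with K-means (k-means++ seeding, best of
`n_init = 10` restarts by inertia, Euclidean distance). The number of
clusters is chosen by sweeping `K ∈ [k_min, k_max]` and maximising the mean
silhouette

    s(i) = (b(i) − a(i)) / max(a(i), b(i)),

where `a(i)` is the mean distance from point `i` to the other members of its
cluster and `b(i)` the smallest mean distance to the members of another
cluster. Ties in mean silhouette go to the smaller K (parsimony); a point in
a singleton cluster scores 0 (the within-cluster term is undefined with no
co-members, and 0 is the neutral value); `a = b = 0` (coincident points)
also scores 0. The default sweep cap is `min(10, ⌊n/5⌋)` so each candidate
clustering averages at least five points per cluster; a class with fewer
than `2·k_min` rows is not clustered at all (`K = 1`).

Majority cluster `i` with `O_i` of the `N_ma` majority rows gets weight
`w_i = O_i / N_ma` and retention quota `s_i = ⌊w_i · N/2⌋`; rows are drawn
uniformly without replacement inside the cluster. Minority cluster `i` gets
`w′_i = O′_i / N_mi` and synthesis quota `s′_i = ⌊w′_i · N/2⌋ − O′_i`,
clamped at 0 if the cluster already exceeds its share. Synthetic rows are
SMOTE interpolations `x + u(z − x)`, `u ~ Uniform(0,1)`, between a uniformly
chosen cluster member `x` and one of its `k` nearest same-cluster neighbours
`z` (self excluded, effective `k = min(k, m−1)`, default `k = 5`; a lone
point is copied verbatim). The neighbour pool is restricted to the point's
own cluster — balancing is applied *within* each group — with a whole-class
pool available behind `smote_pool="class"`.

### Numerical choices

- **Flooring.** Quotas use `⌊·⌋`, not rounding: with weights
  (0.128, 0.791, 0.080) and `N = 750` the middle quota is
  `⌊0.791 · 375⌋ = ⌊296.625⌋ = 296`, and the worked example's totals
  (374 + 375 = 749 of 750) only come out under flooring. The floor is
  computed as `⌊x + 1e-9⌋` so weights that are exact ratios `O_i/N_class`
  cannot land one unit low through binary-float rounding (`0.3 · 50` is
  `14.999999999999998` in IEEE doubles).
- **No total repair.** The flooring shortfall (at most one row per cluster
  and class) is left as is; quotas are never bumped to hit `N` exactly.
- **Plan validation.** Pipeline-computed weights sum to 1 within 1e-12;
  plans accept externally supplied weights whose sum is within 5e-3 of 1 so
  that 3-decimal table-rounded weights can be replayed.
- **Odd `N`.** `N/2` enters the floor as a real number; no special casing.
- **Ties and degenerate inputs.** An exactly balanced input makes
  resampling a no-op (flagged in the report), as does a minority class with
  fewer than two rows. A single-class input is an error.
- **Scaling.** Features are used unscaled by default (a z-score switch
  exists); clustering and SMOTE then operate in the original units.
  Categorical features must arrive numerically encoded, and SMOTE
  interpolates over those codes — a documented limitation, not a feature.

## Classifiers

The final-stage models are authored in-package so their behaviour is fully
specified: greedy binary CART on Gini impurity with thresholds at midpoints
of consecutive distinct sorted values and deterministic tie-breaking (lowest
feature index, then lowest threshold); bagging as bootstrap-resampled trees
combined by majority vote; a random forest adding a uniformly random feature
subset (default `⌊√d⌋`) at every split. Hard labels come from the vote with
ties at exactly 0.5 predicted positive — the minority is the event of
interest, so the tie goes to detection. `predict_scores` returns mean leaf
scores in [0, 1] for ROC use; for ensembles the vote fraction and the mean
score can disagree near 0.5, and labels follow the vote. Zero-gain splits
are allowed (otherwise XOR-like interactions would be unlearnable), and a
model that never split reports feature importances as NaN rather than a
fabricated uniform vector. External boosters (XGBoost) plug in through a
registry behind the same fit/score contract and are deliberately not
reimplemented.

## Evaluation stack

Confusion-matrix metrics use the standard definitions; any metric with a
zero denominator is reported as NaN and named in the report's `undefined`
list, never coerced to 0. The report carries both actual prevalence
(`(TP+FN)/n`) and detection prevalence (`(TP+FP)/n`), because summaries in
the field sometimes label the latter "prevalence": a quantity that varies
between models on a fixed test set can only be the detection rate. AUC is
the trapezoidal area under the threshold-sweep ROC curve (ties grouped),
which equals the Mann–Whitney pair-probability with half credit for ties;
the test suite checks that identity against an independent all-pairs oracle.
Cross-dataset comparison uses per-dataset average ranks (best = 1, ties
averaged) summarised by the median, plus column means.

## Synthetic data

The generator draws each class from a Gaussian mixture: the premise of
cluster-weighted balancing is that classes have internal group structure,
and a mixture is the simplest model with controllable groups. A spec fixes
`n`, the imbalance ratio IR (minority size `round(n/(1+IR))`), per-class
components (weight, mean, covariance) and a label-noise fraction; ground
truth component labels are returned so clustering recovery can be scored.

Two canonical scenarios:

- **Separated** — components ≥ 12σ apart and the minority placed outside
  the majority's region entirely. Silhouette selection must recover the
  generating K here, and a shallow tree must classify perfectly; this
  validates machinery, not difficulty.
- **Overlapping** — minority components centred 1–2 majority σ from
  majority means. Class imbalance only degrades a classifier when classes
  overlap (with separation, even a biased classifier is perfect), so
  benefit-of-balancing experiments use this scenario. Its parameters were
  fixed from that reasoning: majority mixture (0.5, 0.3, 0.2) at (0,0),
  (6,0), (0,6) with σ = 1.8; minority (0.7, 0.3) at (2,2), (6,3) with
  σ = 1.2.

`case_study_fixture` reproduces the worked clinical example's structure
exactly: 695 majority rows in clusters of (89, 550, 56) and 55 minority
rows in clusters of (44, 11) — the unique integer sizes whose 3-decimal
truncated weights are (0.128, 0.791, 0.080) and (0.8, 0.2) — with centres
≥ 10σ apart so the silhouette sweep recovers K = 3 and K = 2 and the whole
pipeline, not just injected assignments, reproduces quotas (48, 296, 30) and
(256, 64) and balanced counts 374/375.

What the synthetic data does *not* emulate: categorical survey variables and
their marginals, survey weighting, missingness, label noise correlated with
features, and non-Gaussian cluster shapes. Passing tests therefore show the
algorithm's arithmetic, determinism and qualitative benefit under cluster
structure with overlap — not performance on any particular real dataset.

## Problem sizes and seeds

The test suite and the acceptance script run the worked example at its
natural size (750 rows), oracle comparisons at n ≤ 30 with hundreds of
random instances, balance properties across 200 generated datasets of
110–240 rows (IR 2–50, sweep cap 4), K-recovery over 40 seeded draws of 400
rows, and the benefit experiment at n = 2000, IR = 30 with 100-tree forests
(depth 10) — sizes chosen so the full suite completes in well under a minute
while every claim is still exercised at meaningful scale. One master seed
drives every stage through stage-named derived streams (CRC32 offsets), so
any stage can be replayed in isolation and identical configs give
bit-identical outputs.

## Known limitations

- SMOTE over integer-coded categoricals produces non-existent category
  values; real categorical handling (e.g. SMOTE-NC style) is out of scope.
- Multiclass imbalance, borderline/adaptive SMOTE variants, instance
  weighting and cost-sensitive losses are out of scope.
- K-means assumes roughly isotropic clusters in the given feature scale;
  enable `scale_features` when units differ wildly.
- The KEEL reader covers the dialect used by the common imbalanced
  benchmark collection, not full ARFF.
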