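# csbboost

Cluster-based SMOTE both-sampling for imbalanced binary classification.

Binary datasets in clinical risk prediction, fraud detection and fault
diagnosis are often heavily imbalanced: the event of interest (the minority
class) is rare, and classifiers trained on the raw data drift toward
predicting the majority class everywhere. Pure under-sampling throws away
majority information; pure over-sampling duplicates or inflates the minority.
`csbboost` does both at once, cluster by cluster, so the balanced training
set keeps the original size *and* the internal structure of each class:

1. Split the training set (size `N`) into majority (`N_ma` rows) and
   minority (`N_mi` rows) classes.
2. K-means each class; the number of clusters `K` maximises the mean
   silhouette `s(i) = (b(i) − a(i)) / max(a(i), b(i))`.
3. Weight each majority cluster `w_i = O_i / N_ma` and retain
   `s_i = ⌊w_i · N/2⌋` of its rows by uniform sampling without replacement.
4. Weight each minority cluster `w′_i = O′_i / N_mi` and synthesise
   `s′_i = ⌊w′_i · N/2⌋ − O′_i` new rows by SMOTE restricted to that cluster
   (each synthetic point lies on the segment between a cluster member and
   one of its `k` nearest same-cluster neighbours, `k = 5` by default).
5. Merge; train an ensemble classifier (built-in bagging / random forest, or
   an external booster such as XGBoost via the adapter registry) on the
   balanced set.

The package also ships the full evaluation stack (confusion-matrix metrics,
Cohen's kappa, ROC/AUC, cross-dataset median-rank aggregation), CSV and KEEL
`.dat` readers, and a Gaussian-mixture generator of imbalanced datasets with
known ground truth.

## Worked example

A 750-row training set with 695 majority rows in three clusters of sizes
(89, 550, 56) and 55 minority rows in two clusters of sizes (44, 11):

```python
from csbboost import ResampleConfig, case_study_fixture, fit_resample

train = case_study_fixture(seed=5).dataset
balanced, report = fit_resample(train, ResampleConfig(seed=17, k_neighbors=5))
print("K:", report.majority_k, report.minority_k)
print("majority quotas:", sorted(report.majority_plan.quotas.tolist(), reverse=True))
print("minority quotas:", sorted(report.minority_plan.quotas.tolist(), reverse=True))
print("balanced counts:", report.majority_out, report.minority_out)
```

prints

```
K: 3 2
majority quotas: [296, 48, 30]
minority quotas: [256, 64]
balanced counts: 374 375
```

The silhouette sweep recovers K = 3 and K = 2; the majority cluster weights
are 0.128 / 0.791 / 0.080 (so 48 + 296 + 30 = 374 rows are retained) and the
minority weights are 0.8 / 0.2 (so 256 + 64 = 320 synthetic rows are added
to the 55 originals, giving 375). The balanced set holds 749 of the original
750 rows — one row short from quota flooring, by design.

## Command line

```sh
csbboost simulate --config sim.yaml --seed 1 --out data/
csbboost resample --config run.yaml --seed 1 --out out/
csbboost evaluate --config run.yaml --seed 1 --out out/
```

Configs are flat YAML files whose keys mirror `csbboost.cli.RunConfig`
(input path, label column, split fraction, resampling and classifier
hyper-parameters). `evaluate` trains the chosen classifier on the raw and
the balanced training set, scores both on the identical held-out 25% test
fold, and writes paired metric reports plus their deltas.

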