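# sqda — sparse quadratic discriminant analysis

Classifying samples from high-dimensional expression profiles (tumor vs
normal tissue, tissue types, disease subtypes) usually falls back on linear
rules that assume every class shares one covariance matrix, because with
p ≫ n the per-class sample covariances needed by quadratic discriminant
analysis (QDA) are hopelessly singular.  Yet gene networks rewire between
disease states: the classes genuinely differ in covariance, and that
difference carries signal a linear rule throws away.

`sqda` implements a sparse QDA that makes per-class covariance estimation
tractable in the large-p small-n regime:

1. **Rank and block.** Features are ranked by the absolute pooled two-sample
   t statistic and partitioned, top down, into consecutive blocks of equal
   size (default 100).  Each class covariance Σ_k is modelled as
   block-diagonal on this ordering.
2. **Penalized positive-definite correlation fit.** Each block's correlation
   matrix is estimated per class by

   &nbsp;&nbsp;&nbsp;&nbsp;R̃_λ = argmin_{R ≻ 0} ‖R − R̂‖²_F / 2 − τ log|R| + λ|R⁻|₁

   where R̂ is the block's sample correlation matrix, R⁻ is R with its
   diagonal zeroed, τ (default 1e-4) is a small log-determinant barrier
   that enforces positive definiteness and λ ≥ 0 soft-thresholds
   off-diagonal entries to exact zeros.  The estimate is rescaled by the
   sample variances to give a sparse positive-definite covariance block.
3. **Variable selection by blocks.** Each block's cross-validated
   misclassification error (sparse fit at a fixed screening λ = 0.2) is
   computed; blocks within an *error margin* (default 0.05) of the best
   block are retained, so selected feature counts are multiples of the
   block size.
4. **Per-block λ tuning and classification.** For each retained block one λ
   is chosen by cross-validation (shared across classes; ties go to the
   smallest λ).  The final rule is maximum-likelihood Gaussian
   classification, argmax_k log N(x; μ̂_k, Σ̃_k), with the block-diagonal
   per-class covariances.

The package also provides the standard comparators used to benchmark such
classifiers — DLDA/DQDA (diagonal variants), DLDA2/DQDA2 (diagonal
estimators combined with the same block selection), SCRDA
(shrunken-centroids regularized discriminant analysis,
Σ̃ = αΣ̂ + (1−α)I with soft-thresholded centroid scores), k-nearest
neighbor, and a cross-validated top-gene screen — plus a synthetic-data
generator covering four covariance regimes (ISSC/ISDC/DSSC/DSDC:
independent or blockwise-AR(±0.95) structure, same or different across
classes) and a multi-replicate benchmarking harness.

## Worked example

Fit the rule on simulated data where the two classes share 400 informative
features (mean shift 0.5) and differ in covariance — the first two AR(0.95)
blocks of 200 features have their correlation signs rewired in class 2:

```python
from sqda import SQDA, SimulationSpec, generate

spec = SimulationSpec("DSDC", p=1000, n_train_per_class=50, n_test_per_class=500,
                      signal_count=400, ar_block=200, seed=7)
train, test = generate(spec)
result = SQDA(train.X, train.y, block_size=100, error_margin=0.05, seed=7).fit()
print(result.summary())
pred = result.predict(test.X)
print("test error:", (pred != test.y).mean())
```

```
sparse block-selected discriminant rule
----------------------------------------------------------
classes: 1, 2
block size 100, 10 blocks, 3 selected (300 features)
error margin 0.05, screening lambda 0.2, 5-fold CV, seed 7

block  cv error  selected  lambda
    0    0.0600     False
    1    0.0000      True    0.01
    2    0.0300      True     0.3
    3    0.0000      True     0.2
    4    0.0900     False
    5    0.1300     False
    6    0.1900     False
    7    0.5200     False
    8    0.4300     False
    9    0.4800     False

test error: 0.002
```

The ten blocks are the |t|-ranked features in runs of 100.  Blocks 1–3 sit
within 0.05 of the best per-block CV error and are kept (300 features);
pure-noise blocks err near 50% and are dropped.  Each retained block gets
its own sparsity level, and the resulting quadratic rule misclassifies 0.2%
of the 1000 test samples — a linear or diagonal rule cannot exploit the
sign-rewired correlations and errs at roughly 20% on this regime.

The same workflow is available from the shell:

```sh
sqda simulate --setting DSDC --p 1000 --signal-count 400 --seed 7 --out data/
sqda fit --data data/X_train.tsv --labels data/y_train.tsv --seed 7 --out model.json
sqda predict --model model.json --data data/X_test.tsv --out labels.tsv
sqda benchmark --setting DSDC --methods sqda,dlda2,dqda2 --replicates 10 --scale 0.1 --out results.tsv
```

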