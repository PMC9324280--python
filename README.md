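# radstab

Stability-oriented feature selection and classification for tabular
(radiomic-style) feature data.

The package implements a complete two-class discrimination pipeline for a
samples × features table with repeated (replicate) measurements:

1. **Preliminary filtering** (`radstab.prefilter`) — variance gate, ICC
   agreement across the two replicate measurements (two-way mixed-effects,
   single measurement, absolute agreement; ICC ≥ 0.9 with F-test p ≤ 0.05
   by default), and a univariate association gate (Student's t or
   Mann–Whitney U, routed by a per-class Shapiro–Wilk normality check).
2. **Ensemble feature selection** (`radstab.selection`) — a family of five
   selectors built around elastic-net penalized logistic regression:
   - `enet`: single fit, nonzero coefficients;
   - `rent`: K subsampled fits sieved by three coefficient criteria
     (nonzero frequency, sign stability, t-test against zero mean);
   - `boosted-rent`: each fit replaced by an AdaBoost chain of elastic nets
     with boost-weight-aggregated coefficients;
   - `bagged-rent` / `bb-rent`: the above wrapped in Q bootstrap bags,
     keeping features nominated in more than η·Q bags
     (defaults N=25, K=200, Q=150, η=0.5).
3. **Stability metrics** (`radstab.stability`) — mean pairwise Jaccard
   index, the variance-based Nogueira stability score with its asymptotic
   two-population z-test, and a resampling experiment comparing selectors
   on shared subsamples.
4. **Modeling** (`radstab.modeling`) — Z-score normalization, five
   classifiers (linear SVR, logistic regression, random forest, perceptron,
   kNN) with internal grid search, maximally balanced stratified k-fold CV,
   ROC AUC, Youden-index thresholds, class-stratified percentile bootstrap
   CIs, a reciprocal-weighted five-fold linear ensemble whose decision
   threshold is normalized to 1, and threshold recalibration on a second
   cohort.
5. **Synthetic data** (`radstab.synthetic`) — cohort generator with planted
   effect sizes, correlated feature blocks (optionally carrying redundant
   block-level signal), replicate measurement noise with a controllable ICC
   spectrum, optional log-normal skew, and a covariate-shifted second
   cohort.

A packaged fixture (`radstab.fixtures.load_final_ensemble`) reconstructs a
published five-fold linear ensemble (17 distinct features) used by tests and
the acceptance report.

## Tests

```
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the two
reduced-scale statistical reproductions (selector recovery and the
stability-ordering experiment) take several minutes each.

## CLI

All stages are exposed through one entry point (`radstab` or
`python -m radstab.cli`):

```
radstab simulate  --seed 7 --n-samples 200 --n-features 422 --out data/
radstab prefilter --table data/primary.csv --replicate data/replicate.csv --out report.csv
radstab select    --method bb-rent --table data/primary.csv --replicate data/replicate.csv \
                  --config cfg.yaml --seed 7 --out selection.json
radstab stability --table data/primary.csv --replicate data/replicate.csv \
                  --methods enet,rent,boosted-rent,bagged-rent,bb-rent --runs 100 --out stab/
radstab train     --table data/primary.csv --replicate data/replicate.csv \
                  --classifier svr-linear --seed 7 --out model.json
radstab predict   --model model.json --table data/test.csv --labels-col label \
                  --threshold recalibrate --out pred.csv
```

A YAML config can override prefilter thresholds, selector hyperparameters
(`selection: {N, K, Q, eta, criteria: {...}, enet: {...}}`) and the selector
method. Every stage writes a manifest embedding the seed and a hash of the
effective configuration; identical seed + config reproduce outputs
byte-for-byte.

Full-scale BB-RENT (Q·K ≈ 30k boosted chains) is computationally heavy by
design; progress is logged per stage, and reduced N/K/Q values are
recommended for exploration.
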