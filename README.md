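# evohis

Evolutionary hyperparameter tuning for binary medical-style classifiers.
Three population metaheuristics — particle swarm optimization (PSO),
gravitational search (GSA) and the firefly algorithm (FA) — evolve the
hyperparameters of an SVM (soft-margin cost) or an MLP (learning rate and
momentum) to maximize a weighted combination of prediction accuracy,
specificity and sensitivity measured by stratified 10-fold cross-validation.

Features:

- **data**: CSV/ARFF loading, mode/mean imputation, min-max normalization,
  Weka-style supervised resampling (with-replacement, bias-to-uniform-class
  knob), and a seeded synthetic-data generator with controllable class
  separation, imbalance, label noise and missingness.
- **objectives**: pooled confusion counts, PAC/SEY/SPY, weighted-sum
  scalarization `Z = w1*PAC + w2*SPY + w3*SEY` (default weights
  0.95/0.025/0.025), class-weighted precision/recall/F.
- **classifiers**: SVM and MLP adapters (scikit-learn backed) with all
  tunables bounded in [0, 1]; the MLP uses one hidden layer sized to the mean
  of the input and output layer widths; confusion counts are pooled over CV
  test folds.
- **evolvers**: from-scratch PSO, GSA and FA over bounded real boxes, with
  clamped bound repair, best-ever elitism, per-evaluation archives and full
  seed determinism.
- **pareto**: nondominated filtering, union min-max front normalization,
  generational distance and spacing.
- **stats**: exact (DP-enumerated) Wilcoxon signed-rank test and one-sample
  t-test with confidence intervals, plus a repeated-runs harness.
- **his**: pipeline orchestration — the 16-configuration grid
  `{svm, mlp} x {none, pso, gsa, fa} x {resample off, on}` with a single
  master seed fanning out to folds, resampling and each cell's evolver.

## CLI

```sh
# generate a synthetic dataset
printf 'n_instances: 200\nn_features: 5\nclass_separation: 4.0\nseed: 1\n' > spec.yaml
evohis synth --spec spec.yaml --out data.csv

# one configuration
evohis run --data data.csv --label label --positive pos \
    --classifier mlp --evolver fa --agents 20 --iters 50 --seed 7 --out out/

# the full 16-cell grid (writes per-cell JSON, archives, a summary CSV
# and the best configuration)
evohis grid --data data.csv --label label --positive pos --seed 7 --out grid/

# Wilcoxon comparisons of one technique against the rest, over one or
# more grid-output directories
evohis stats --results grid/ --reference FMLP --out stats.csv
```

Technique labels combine evolver and classifier (`PSVM`, `GMLP`, `FMLP`, ...),
with `Basic-` for the untuned classifier and a `+RS` suffix for resampled
cells.

## Library example

```python
from evohis import (EvolverConfig, HISConfig, SyntheticSpec, make_synthetic,
                    run_grid, select_best)

ds = make_synthetic(SyntheticSpec(n_instances=200, n_features=5,
                                  class_separation=3.0, seed=0))
results = run_grid(ds, HISConfig(seed=0, evolver_cfg=EvolverConfig()))
best = select_best(results)
print(best.config.classifier, best.config.evolver, best.best_z)
```
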