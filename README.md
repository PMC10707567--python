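# maacnn

Multi-atlas attention CNN for classifying subjects from resting-state fMRI
functional connectivity.

## The problem

Resting-state fMRI cohorts such as ABIDE are distributed as per-subject ROI
time series under several brain parcellations ("atlases" — AAL, CC200,
Harvard-Oxford, ...). Each atlas gives a different *view* of the same brain:
for an atlas with *n* ROIs, the subject is summarised by the Pearson
functional-connectivity (FC) matrix

ρ<sub>uv</sub> = Σ<sub>t</sub>(u<sub>t</sub>−ū)(v<sub>t</sub>−v̄) /
√(Σ<sub>t</sub>(u<sub>t</sub>−ū)² Σ<sub>t</sub>(v<sub>t</sub>−v̄)²)

whose strict lower triangle is flattened into S = n(n−1)/2 features. Single
views discard complementary information; this package implements a multi-view
classifier that learns how much to trust each view:

1. **Per-view compression** — a stacked denoising autoencoder (two DAEs,
   masking-noise corruption 30% / 10%, greedy layerwise training) maps each
   view's S raw FC features to a shared F-dimensional code.
2. **Attention fusion** — global average pooling collapses each view to a
   scalar summary per subject; an MLP + softmax turns the summaries into
   nonnegative view weights c<sub>i</sub> summing to 1, and the fused
   representation is x̂ = Σ<sub>i</sub> c<sub>i</sub> x′<sub>i</sub>.
3. **Classification** — a 1-D CNN (conv → ReLU → batch-norm → max-pool →
   dropout blocks, one projection skip connection `output = shortcut(x) +
   main(x)`, L2-regularised dense head, softmax) produces two-class
   probabilities; the disorder class is positive.

Evaluation is stratified k-fold (or leave-one-out) cross-validation with
every fitted stage — standardisation, SDA, feature selection, classifier —
restricted to training-fold rows, enforced by a leakage-instrumentation
guard. A synthetic multi-atlas cohort generator with planted covariance
effects makes the full pipeline testable without any real imaging data.

All neural components run on numpy (float64, manual backpropagation verified
against finite differences), so results are reproducible to the bit for a
fixed seed on any machine.

## Worked example

```python
from maacnn import ModelConfig, make_cohort, preset_spec, train_maacnn

cohort = make_cohort(preset_spec("separable", seed=1))   # 3 views, 40+40 subjects
report = train_maacnn(cohort.view_features(), cohort.labels,
                      ModelConfig.test_scale(folds=5), seed=1)
print(report.table())
print("attention:", {k: round(v, 3) for k, v in report.attention_weights.items()})
print("leakage:", report.leakage)
```

prints

```
protocol: 5-fold stratified CV   seed: 1   config: bd7281812e333ec9
fold    ACC%    SEN%   SPEC%    AUC
   0 100.00 100.00 100.00   1.00
   1 100.00 100.00 100.00   1.00
   2 100.00 100.00 100.00   1.00
   3  93.75 100.00  87.50   1.00
   4 100.00 100.00 100.00   1.00
mean  98.75 100.00  97.50   1.00
attention: {'synA': 0.27, 'synB': 0.488, 'synC': 0.242}
leakage: {'n_checks': 50, 'n_violations': 0}
```

The cohort plants a correlation shift of 0.6 on 8 edges of every view, so a
well-behaved pipeline should recover the classes almost perfectly: mean
cross-validated accuracy 98.75%, AUC 1.0. The attention weights are the mean
softmax weight each view received; `leakage` confirms that all 50 fit calls
(5 folds × [3 standardisers + 6 DAEs + 1 head]) saw training rows only.

The same stages are scriptable from the shell:

```bash
maacnn simulate --preset separable --seed 1 --out cohort/
maacnn features --data cohort/ --views synA:10,synB:12,synC:14 \
       --phenotypes cohort/phenotype.csv --out feats/
maacnn evaluate --features-dir feats/ --views synA,synB,synC \
       --phenotypes cohort/phenotype.csv --folds 5 --seed 1 --out run/
maacnn ablate   --features-dir feats/ --views synA,synB,synC \
       --phenotypes cohort/phenotype.csv --seed 1 --out run/
```

`maacnn train --config run.yaml` drives the whole pipeline (raw `.1D` files →
features → per-fold SDA → attention+CNN CV) from a single YAML file; see
`docs/config.md` for the schema and `docs/methods.md` for the model details
and the full-scale (F = 2000) defaults.

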