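# Methods

This note documents the model, its assumptions, the parameters that matter,
and the design decisions taken where the design was genuinely open. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Functional-connectivity features

For each subject and atlas, the T × n ROI time-series matrix is reduced to
the n × n matrix of pairwise Pearson correlations, and the strict lower
triangle is flattened row-major — (1,0), (2,0), (2,1), (3,0), … — into
S = n(n−1)/2 features. The set of retained entries is forced by symmetry and
the unit diagonal; the *order* is a free choice, and row-major is fixed and
documented so feature indices are stable across runs and machines.

Numerical choices:

* A zero-variance (constant) ROI makes the correlation undefined; all
  affected entries are set to 0 and a warning names the ROI indices. Silent
  NaNs would otherwise poison the autoencoder.
* Correlations are clipped to [−1, 1] against floating-point overshoot and
  the matrix is re-symmetrised exactly.
* Fewer than two time points is a hard error: the formula is undefined.
* Features enter the pipeline as raw r values; no Fisher z-transform is
  applied. The variance-stabilising transform mainly matters for inference
  on the correlations themselves, which this pipeline never does.

Two widely quoted atlas feature counts disagree with n(n−1)/2: a 160-ROI
parcellation is often listed with 12 880 features (n(n−1)/2 = 12 720) and a
116-ROI one with an input width of 6 770 (= 6 670). This package always
derives S from the ROI count; for those two named atlases the published
*hidden* widths (6 440 and 3 380) are kept, since they remain compressive
against the derived input widths.

## Stacked denoising autoencoder

Each view is compressed by two chained DAEs trained greedily: DAE-1 maps the
S standardised features to a hidden code of roughly half the width, DAE-2
maps those codes to the F-dimensional representation shared by all views
(F = 2000 at full scale). Per-atlas full-scale widths: AAL 6670→3330,
CC200 19900→9950, HO 6105→3050, then hidden→2000 in stage 2; custom atlases
use the halving rule ⌈M/2⌉.

* **Corruption**: masking noise — each coordinate independently zeroed with
  probability 0.30 (stage 1) / 0.10 (stage 2), a fresh mask per sample per
  epoch. The loss is the mean squared reconstruction of the *clean* input.
* **Architecture**: rectifier encoder, linear decoder. A linear output with
  MSE suits unbounded z-scored inputs; a squashing output would not.
* **Standardisation**: per-feature zero mean / unit variance, statistics fit
  on the training fold only and reused for held-out folds.
* **Optimiser**: SGD with momentum 0.9; full-scale defaults are learning
  rate 1e-4, 200 epochs, batch 32. Batch size and weight initialisation
  (He-scaled Gaussian) are implementation choices.
* **Frozen encoders**: after pretraining, only the two encoders are applied
  (no corruption, no decoders), and they are not fine-tuned with the
  classifier. Joint fine-tuning is a possible extension, deliberately not a
  default.

Inference is corruption-free and bit-deterministic: repeated transforms of
the same input are identical arrays.

## Attention fusion

Encoded views X′ ∈ R^(n×N×F) are fused per subject. Global average pooling
collapses each view to its scalar mean, giving an N × n summary matrix; a
one-hidden-layer rectifier MLP (hidden width max(4, 2n)) maps the n
summaries to n logits, and a softmax yields weights c with c ≥ 0, Σc = 1.
The fused representation is x̂ = Σᵢ cᵢ x′ᵢ — a convex combination, so every
fused coordinate is bounded by the per-coordinate min/max across views, an
invariant the tests assert.

Two readings of the pooled summary are supported: per-subject weights (the
default, the standard squeeze-excitation reading) and a single global weight
vector obtained by averaging summaries over the batch
(`global_weights: true`). Softmax normalisation is likewise a choice: it
makes the convexity invariant testable; `normalize: none` exposes raw
unnormalised weights. The attention branch is trained jointly with the CNN
by backpropagating the classification loss through the weighted sum; the
encoded features themselves receive no gradient.

## 1-D CNN classifier

The fused vector is treated as a one-channel sequence of length F. Each
block applies same-padded 1-D convolution, ReLU, batch normalisation, max
pooling, dropout — in that order. One skip connection spans the first two
blocks: the span input is passed through a 1×1 convolution that adjusts the
channel count (identity when the shapes already match) and max-pooled by the
same factors as the main path so lengths align, then added to the main
path's output. The exact depth/widths of the architecture are configurable;
the full-scale defaults are 3 blocks with channels (16, 32, 64), kernel 5,
pool 2, dropout 0.3, dense width 128, λ = 1e-4 on the L2 penalty over
convolution and dense weights (never biases or batch-norm parameters). The
head is flatten → dense+ReLU → dense(2) → softmax; column 1 is the positive
(disorder) class, the decision threshold is 0.5, and a probability exactly
at the threshold resolves to the control class.

Training: cross-entropy + L2, SGD momentum 0.9, full-scale lr 1e-4 over 200
epochs. Non-finite losses or activations abort with a diagnostic rather than
propagating NaNs.

## Cross-validation and metrics

* **Stratified k-fold** (default 10): per-fold class proportions within one
  subject of the global proportions, so sensitivity and specificity are
  defined in every fold. Fold metrics are averaged arithmetically.
* **LOOCV**: singleton test folds pooled into one confusion matrix before
  computing metrics, since per-fold SEN/SPEC are undefined for singletons.
  The two aggregation modes are labelled in the report and never mixed.
* **Metrics**: ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPEC = TN/(TN+FP) with
  the disorder class positive; undefined ratios are reported as missing with
  a warning, not as 0. AUC is the Mann–Whitney statistic of the
  positive-class probability (ties ½).
* **Leakage instrumentation**: the CV driver registers the held-out indices
  before any fitting; every fit routine (standardiser, DAE, RFE, head)
  reports the row indices it received and any overlap is counted. A full run
  exposes `n_checks`/`n_violations` in its report.
* **RFE baseline**: recursive feature elimination around an L2 logistic
  regression, dropping 10% of the *remaining* features per round, never
  overshooting the target, fit on training folds only.
* **Ablation harness**: four arms under identical folds — (1) single view +
  RFE + CNN, (2) single view + SDA + CNN, (3) all views + RFE + attention,
  (4) full model. The shared fold digest is recorded so arm comparisons are
  like-for-like.
* **Seeds**: one master seed fans out through `numpy.random.SeedSequence`
  into split/initialisation/corruption streams; reports embed the seed and a
  config digest, and identical (config, seed) pairs produce bit-identical
  report digests.

## Synthetic cohorts

The generator emulates the statistical structure the classifier assumes:
several parcellations of the same subjects, class-dependent differences in a
subset of inter-ROI covariances, per-site batch effects, and views of
differing informativeness. Per view, a base correlation matrix (off-diagonal
Gaussian entries, scale 0.1, repaired to positive definiteness by eigenvalue
clipping and unit-diagonal renormalisation) is shifted by `effect_size` on
`n_affected_edges` randomly chosen edges for the disorder class in
informative views, and perturbed per site by a symmetric Gaussian offset
(scale 0.02). Time series are i.i.d. draws from the resulting multivariate
normal.

Default study conditions (`scale="test"`): three atlases of 10/12/14 ROIs,
T = 120 time points, 40+40 subjects, 2 sites. Presets: `null` (no effect),
`separable` (δ = 0.6 on 8 edges, all views), `complementary-views` (δ = 0.45
on 4 view-specific edges), `noise-view` (two views, only the first
informative).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: temporal autocorrelation and hemodynamics (the
pipeline consumes only pairwise correlations, so temporal structure is
irrelevant to it, but real BOLD effective sample sizes are smaller than T),
head-motion artefacts, realistic site demographics, heavy-tailed noise, and
the far weaker effect sizes of real clinical cohorts. Desk-scale recovery
results demonstrate that the machinery is correct and leakage-free, not that
comparable accuracy is attainable on real imaging data.

## Desk-scale configuration

`ModelConfig.test_scale()` runs the identical pipeline at reduced
dimensions: F = 16 codes, SDA learning rate 0.05 over 150 epochs, a 2-block
CNN with channels (8, 16), kernel 3, dense width 32, dropout 0.1, learning
rate 0.01 over 100 epochs, 5 folds. The larger learning rates are
appropriate for the much smaller weight matrices (tens of features instead
of thousands); with the full-scale rate of 1e-4 the tiny autoencoders stay
far from convergence within the epoch budget and their codes lose the
planted class signal. These are the problem sizes used throughout the test
suite and the acceptance script.

## Known limitations

* No GPU path and no automatic differentiation: the numpy engine is built
  for reproducibility and testability at moderate scale, not for training
  full-size (F = 2000, 19 900-feature) models quickly.
* Encoders are never fine-tuned with the classifier.
* No multi-site harmonisation or covariate modelling; site effects are
  emulated in the generator but not corrected by the pipeline.
* Single-label binary classification only; multi-head attention, view
  embeddings and architecture search are out of scope.
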