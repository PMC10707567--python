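# Run configuration (YAML)

`maacnn train --config run.yaml` drives the full pipeline. All keys of the
`model:` section are optional and default to the full-scale settings
(F = 2000, lr 1e-4, 200 epochs); `maacnn evaluate/ablate` fall back to the
desk-scale configuration when no `--config` is given.

```yaml
views:                 # view name -> directory of rois_<subject>.1D files
  synA: cohort/synA
  synB: cohort/synB
atlases:               # view name -> ROI count (feature dim is n(n-1)/2)
  synA: 10
  synB: 12
phenotypes: cohort/phenotype.csv   # columns: subject_id, label[, site, age, sex]
seed: 1
out_dir: run/
protocol: kfold        # kfold | loocv

model:
  folds: 5
  threshold: 0.5       # decision threshold on the positive-class probability
  sda:
    code_dim: 16       # F, shared across views
    epochs: 150
    learning_rate: 0.05
    momentum: 0.9
    batch_size: 32
  cnn:
    input_dim: 16      # must equal sda.code_dim
    n_blocks: 2
    channels: [8, 16]
    kernel_size: 3     # odd
    pool_factor: 2
    dropout_rate: 0.1
    l2_coefficient: 1.0e-4
    dense_width: 32
    skip_span: [0, 2]  # shortcut wraps blocks [start, stop); null disables
    learning_rate: 0.01
    momentum: 0.9
    epochs: 100
    batch_size: 32
  attention:
    global_weights: false   # true: one weight vector shared by all subjects
    normalize: softmax      # softmax | none
    hidden_width: null      # default max(4, 2 * n_views)
```

Labels may be `ASD`/`HC` strings or `1`/`0`. Rows with missing labels are
excluded and reported; duplicate subject ids are an error. Per-view `.1D`
files are whitespace-delimited T × n matrices, optionally with one leading
`#` header line; column order must match the atlas's ROI order.

Outputs under `out_dir`: per-view feature CSVs, `eval_report.json` (per-fold
and mean metrics, fold assignments, seed, config digest, leakage counters,
provenance block), `eval_report.txt` (human-readable table), and
`attention_weights.csv` (mean weight per view).

CLI exit codes: 0 ok, 2 configuration error, 3 data error, 4 runtime
failure.
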