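# kneeload

Interpretable prediction of the supporting-knee resultant joint moment from
bilateral sagittal-plane joint-angle curves.

One movement cycle (a tennis serve) is represented as a fully connected
temporal graph of 101 time-normalized nodes carrying six joint-angle
features.  A stack of graph convolutions followed by a GRU and a shared
affine head maps the 6 × 101 angle matrix to the 1 × 101 resultant-moment
curve.  Layer-wise relevance propagation (LRP) with an epsilon rule — and a
gated-signal rule for the GRU — attributes each prediction back to the
joint-angle inputs, yielding per-joint contribution curves normalized to
[0, 1].  Evaluation covers MAE/MSE/R², pooled-SD Cohen's d, paired t-tests
with a normality pre-check, and a 1D statistical-parametric-mapping paired
t-test over the 101-node curves (random-field-theory threshold with a
permutation alternative).

Because no motion-capture data ship with the package, a configurable
synthetic serve simulator generates three-phase (preparation / flight /
landing) bilateral angle curves together with joint-moment components
produced by a known generative mapping — so training, explanation recovery,
and statistics are all testable offline against known ground truth.

The neural network (graph convolutions, GRU, Adam, backpropagation) is
implemented directly on NumPy: the models are small, no GPU is assumed, and
the relevance engine needs the full forward cache anyway.

## Layout

| Module | Contents |
| --- | --- |
| `kneeload.synthetic` | serve-trial simulator, generative ground truth, CSV round-trip |
| `kneeload.preprocess` | zero-phase Butterworth filter, 101-point time normalization, resultant moment, 8:1:1 rotating-fold splits |
| `kneeload.graph` | 101-node complete temporal graph, invariant checker, TSV dump |
| `kneeload.model` | GCN-GRU network, baseline GRU, Adam training, JSON checkpoints |
| `kneeload.pso` | particle swarm optimizer and hyperparameter search wrapper |
| `kneeload.lrp` | epsilon-rule LRP through head, GRU, and graph convolutions |
| `kneeload.stats` | regression metrics, Cohen's d, paired t, 1D SPM paired t |
| `kneeload.pipeline` / `kneeload.cli` | stage orchestration, manifests, report |

## CLI

Every stage is a verb of the `kneeload` command; a single YAML file
configures a full run:

```bash
kneeload run --config run.yaml --out out/ --seed 1
kneeload report --data out/
```

with, e.g.:

```yaml
seed: 1
simulate: {n_participants: 30, trials_per_participant: 12}
preprocess: {cutoff: 10, order: 4, fold_id: 0}
train: {n_gcn_layers: 3, gcn_width: 64, gru_width: 64, epochs: 100, learning_rate: 0.001}
explain: {epsilon: 1.0e-6, norm: global}
evaluate: {alpha: 0.05, spm: rft}
```

Individual stages: `kneeload simulate --config cfg.yaml --out out --seed 1`,
`kneeload preprocess --in out --cutoff 10 --order 4 --fold 0`,
`kneeload train --data out`, `kneeload predict --model out/train/model.json
--in trial.csv --out pred.csv`, `kneeload explain --model out/train/model.json
--data out --split test --out contrib.csv`, `kneeload evaluate --data out`.

Each stage writes a `stage_manifest.json` recording parameters, the seed,
and SHA-256 hashes of its outputs; identical configurations reproduce
identical hashes.

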