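# fetalvit

A dual-head Vision Transformer (ViT) pipeline for grayscale
ultrasound-style images, written for researchers who want a compact,
fully-inspectable NumPy implementation of joint **health-class
classification** and **continuous severity regression**, together with
quantitative evaluation of where the model's attention lands.

Clinical fetal-ultrasound datasets are typically private; the package
therefore ships a synthetic **speckle-phantom generator** (fan-shaped
sector images with multiplicative Rayleigh speckle, four health classes,
a continuous severity score in [0, 3], and exact lesion masks) so that
every stage — preprocessing, training, attention scoring, statistics —
runs end to end with no external data.

## The model

An H×W image is min-max normalized, split into non-overlapping P×P
patches, and each flattened patch is embedded linearly:

    E = flatten(patches) · W_E + b_E,          E ∈ R^{N×D},  N = HW/P²

Sinusoidal positional encodings are added (`PE(pos, 2i) =
sin(pos/10000^{2i/D})`, cosine on odd channels), and the tokens pass
through a stack of pre-norm encoder blocks with multi-head
self-attention

    Attention(Q, K, V) = softmax(Q Kᵀ / √d_k) V,
    Q = E W_Q,  K = E W_K,  V = E W_V

followed by a ReLU MLP, residual connections throughout.  An optional
cross-attention block lets the final layer query an earlier layer's
keys/values.  Tokens are mean-pooled into a feature vector x ∈ R^D and
fed to both heads:

    Prob_class    = softmax(W_class · x + b_class)        (classification)
    SeverityScore = w_severity · x + b_severity           (regression)

Training minimizes the composite loss

    L_total = L_class + λ · L_severity

(cross-entropy plus λ-weighted MSE, default λ = 0.5) with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8), decoupled weight decay, and early
stopping on validation loss.  Forward pass **and analytic gradients**
are pure NumPy; the gradients are verified against central differences
in the test suite.

## Attention evaluation

Saliency maps are produced by attention rollout (identity-augmented,
head-averaged, renormalized per-layer attention matrices multiplied
through the stack) and scored against binary annotation masks R with:

| metric | definition |
|---|---|
| CoG Shift | Euclidean distance between map centroid and mask centroid (px) |
| AFR | % of the top-10%-by-weight attention area inside R |
| WRS | attention-weighted mean of exp(−d²/2σ²), σ = √(\|R\|/π), in (0, 1] |
| AED | % of total attention energy outside R |
| ODM | mean attention/mask IoU across a frame sequence |
| IoU / DSC | standard overlap coefficients (%) |

The statistics module adds a classification report (per-class
precision/recall/F1, weighted and macro averages, Cohen's κ), MAE/RMSE,
residual-density comparison, normal-approximation confidence intervals,
Cohen's d (pooled-SD and mean-SD conventions) and percent-change /
A-B comparison tables.

## Worked example

The reference dual-head calculation on a 3-feature pooled output:

```sh
$ fetalvit worked-example
Dual-head worked example
  transformer output : [2.0, -1.5, 0.5]
  logits             : [1.00, -1.55, 1.95]
  class probabilities: [0.273, 0.021, 0.706]
  severity score     : 2.05
```

The classification head assigns 70.6% probability to the third class,
and the severity head reports a continuous score of 2.05 (on the
package's default scale, between "moderate" and "severe").

A full synthetic run:

```sh
fetalvit generate-data --out data --n 500 --seed 1
fetalvit train --data data --out run --max-epochs 20 --seed 1
fetalvit evaluate --data data --checkpoint run/checkpoint.npz --out eval
fetalvit attention-metrics --data data --checkpoint run/checkpoint.npz --out attn
fetalvit ablation --out abl --n 240 --seed 0
fetalvit lr-sweep --out lrs --n 200
fetalvit lambda-sweep --out lam --n 240
```

Each command writes CSV/JSON outputs plus a `provenance.json` (config
hash, seed, versions) into its run directory.

## Layout

```
src/fetalvit/
  preprocess.py   resizing, min-max normalization, seeded augmentation
  model.py        patches, embeddings, attention, dual heads, forward/backward
  train.py        losses, Adam, early stopping, sweep/ablation harnesses
  attention.py    rollout extraction, CoG/AFR/WRS/AED/ODM/IoU/DSC, overlays
  stats.py        classification report, κ, CIs, Cohen's d, A/B tables
  phantom.py      speckle phantom generator with lesion masks
  config.py       validated YAML/JSON run configuration
  io.py           manifests, PNG/TIFF images, npz checkpoints
  cli.py          the `fetalvit` command
```
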