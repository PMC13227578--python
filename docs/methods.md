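# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model

The network is a small Vision Transformer with two output heads sharing
one trunk. Design points that the underlying method description leaves
open, and the choices made here:

- **Encoder block.** Pre-norm composition: `x += MHA(LN(x))` then
  `x += W₂·ReLU(W₁·LN(x))`, feed-forward width 4·D. Defaults D = 32,
  depth 2, 2 heads, patch size 16 on 64×64 inputs (16 tokens) — small
  enough to train quickly on one CPU while exercising every
  architectural element; all configurable.
- **Multi-head attention** is implemented as parallel single-head
  attention blocks over D/heads-dimensional slices whose outputs are
  concatenated, with *no* output projection, so `heads=1` reproduces
  the single-head formula `softmax(QKᵀ/√d_k)V` exactly.
- **Pooling.** Mean over token embeddings (no CLS token). A final layer
  norm precedes pooling.
- **Cross-attention** (optional, off by default): one block whose
  queries come from the final encoder output and whose keys/values come
  from a configurable earlier block (default: the first). Gradients
  flow through both paths.
- **Positional encoding.** 1-D sinusoidal over the row-major patch
  index by default; a factored 2-D variant (half the channels encode
  the patch row, half the column) is available. Disabling it makes the
  network provably invariant to patch permutation — the property test
  pair that shows the encoding carries spatial information.
- **Class count.** Default 4 (healthy/mild/moderate/severe); 2- and
  3-class configurations are fully supported — the method description
  uses three classes in its reference calculation and four in its data
  description, so neither is privileged by the code.
- **Initialization.** Glorot-uniform from a configurable seed; layer
  norms start at identity.
- **Gradients.** Reverse-mode differentiation is hand-derived in
  `model.backward` and checked against central differences (relative
  error < 1e−5 across parameter groups, with and without
  cross-attention/multi-head) in the test suite.

## Training

`L_total = L_class + λ·L_severity` exactly as written: λ (default 0.5,
the balanced setting) multiplies the severity MSE only. The literature
this follows also describes its λ narratively as a *classification*
priority, which contradicts that formula; the code implements the
formula, and the sweep harness interprets the trade-off accordingly
(raising λ emphasizes the severity task).

- Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e−8; weight decay is decoupled
  (θ ← θ − η·γ·θ), matching the common AdamW convention, since γ is
  described as a weight decay rather than an L2 penalty.
- Early stopping: patience 5 epochs, minimum improvement 1e−4
  (absolute) on validation `L_total`; the returned parameters are from
  the best-validation epoch.
- Batch size 16; cross-entropy clamps −ln p at −ln 1e−12 when a true
  class receives zero probability.
- **Epochs to convergence** (learning-rate sweep) is defined as the
  first epoch realizing 95% of a run's total validation-loss
  improvement. A multiplicative band around the run minimum was
  rejected: minima under large-step training are sharp outliers and the
  band reading is dominated by per-epoch noise.
- **Severity accuracy** (λ-sweep reporting only, never training) is
  100·(1 − MAE/range) with range 3, the span of the synthetic severity
  scale.
- Ablation variants: `no_positional` skips the encoding;
  `no_self_attention` removes the attention sub-layer (the MLP path
  remains); `single_head` drops the severity head and forces λ = 0.

## Synthetic phantoms

The generator emulates the *structure* of a private fetal-ultrasound
dataset, not its content: 500 images, four classes, a continuous
severity label, and expert-style binary anomaly masks.

- Geometry: 60° sector (apex top-center) on a 64×64 canvas.
- Tissue: constant 0.5 background plus a smoothed Gaussian random field
  (amplitude 0.15).
- Speckle: multiplicative Rayleigh noise with unit mean — the standard
  first-order approximation of fully-developed ultrasound speckle. No
  point-spread-function convolution, ray acoustics or anatomy is
  simulated.
- Lesions: bright ellipses, count fixed by class (mild 1, moderate 2,
  severe 3), semi-axes ∝ (0.6 + 0.45·severity) and contrast
  ∝ (0.5 + 0.5·severity), centers uniform inside the sector. The mask
  marks lesion pixels exactly; healthy phantoms have empty masks.
- Severity bands: healthy [0, 0.5), mild [0.5, 1.5), moderate
  [1.5, 2.5), severe [2.5, 3] — chosen so MAE values land on a scale
  comparable to published severity-error magnitudes.
- All randomness flows through one `numpy` generator per call; a spec
  plus seed reproduces images bit-for-bit.

**What passing tests on phantoms do and do not show.** Phantom class
labels are decodable from pooled first-order lesion statistics
(area/contrast). Consequently: (a) the learnability checks demonstrate
that the pipeline extracts real signal; (b) component ablations that
rely on *spatial context* are not discriminative here — removing
self-attention does not hurt, and in most seeds slightly helps, because
attention contributes estimation variance but no information on this
task. Conclusions about attention's value on real anatomy cannot be
drawn from phantoms of this family. Likewise, classification and
severity are positively coupled by construction, so the λ trade-off
manifests mainly on the severity side.

## Attention metrics

The five alignment metrics follow their prose definitions; the exact
algebra is therefore a documented package choice:

- AFR thresholds the map at the 90th weight percentile (top 10% of
  pixels), configurable.
- WRS uses a Gaussian kernel of the distance to the mask centroid with
  σ = √(|R|/π) (equivalent circle radius), normalized so that full
  concentration at the centroid scores exactly 1.
- ODM is the mean per-frame attention/mask IoU; a frame-to-frame map
  overlap reading is available behind a flag.
- Centroids are intensity-weighted for maps, uniform for masks; pixel
  centers at integer coordinates, 0-based, origin top-left.
- Degenerate inputs (empty mask, zero-energy map) raise a dedicated
  error; two empty regions compare as IoU = DSC = 100 by convention.

## Statistics

- Cohen's d defaults to the mean-of-SDs standardizer, which is the
  convention consistent with the published effect size recomputed in
  the tests (3.37 for 87.6 ± 1.1 → 90.8 ± 0.8); the pooled-SD form
  (3.33 on the same inputs) is also exposed.
- Cohen's κ uses the standard (p_o − p_e)/(1 − p_e) formula. For the
  10-sample reference confusion matrix this yields 0.85; the published
  summary of that same table prints 0.83, which the standard formula
  cannot produce from the printed supports and rates. The
  implementation is not adjusted to match it.
- Percent changes are reported at 2 decimals (1 decimal in improvement
  tables); 85.2 → 93.1 is 9.27% by arithmetic, one ulp below the
  published 9.28%.
- Confidence intervals are the normal approximation mean ± z·sd/√n;
  zero-division cases (never-predicted class, zero baseline) are
  reported as flags, not exceptions, in batch reports.

## Problem sizes

The default experiment sizes — 200–400 phantoms, ≤ 30 epochs, 5 seeds
for directional comparisons, 3 seeds for learnability — were chosen so
that a full suite run completes in a couple of minutes on one CPU while
keeping the directional statistics reproducible across seeds.

## Known limitations

- No GPU path, no pretraining/transfer weights, no DICOM or Doppler
  input, no 3-D/4-D data.
- The phantom family cannot validate claims that depend on spatial
  context or on competing task objectives (see above).
- KDE-based residual comparison assumes continuous residuals; constant
  samples are approximated by a narrow normal spike.
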