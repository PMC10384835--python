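# Methods

## Problem and model

`ptnfall` classifies short multichannel inertial recordings (acceleration in
g, angular velocity in °/s) into *fall* vs *activity of daily living*
(ADL). The discriminating structure of a fall is temporal: a free-fall dip
of the acceleration magnitude toward 0 g, a sharp impact spike of several g
lasting well under 0.3 s, then near-motionless rest at 1 g. Threshold
detectors that only look at the peak confuse falls with abrupt sit/lie
transitions; the model here sees the whole sequence.

The classifier is a hybrid convolution/transformer over *patches*: each
sliding window of `W` samples is reshaped per channel into an `n × n` grid
(`n = ⌊√W⌋`, row-major in time, samples beyond `n²` dropped), so a trial
becomes a sequence of `N` blocks of shape `n × n × C`, where `C` is the
merged channel count across sensors (channel-axis concatenation in fixed
sensor order). Two 3×3, stride-2, padding-1 convolutions with ReLU
(channel plan `C → 2C → 2C`) extract local features from each block; the
result is flattened and linearly projected to a token of width `D = C²`.
A learnable positional table (`N × D`, Gaussian init σ = 0.02) is added.
`L` pre-LN encoder sub-layers follow — `X′ = MSA(LN(X)) + X`,
`X = MLP(LN(X′)) + X′` — with `h`-head scaled dot-product attention
(`d_k = d_v = D/h`) and a GELU MLP of width `4D`. A final LayerNorm, a
global average pool over tokens, and one linear layer produce the
two-class logits; softmax is applied at inference, while training uses the
logits directly under cross-entropy.

### Assumptions

- The two classes are separable from windowed second-order statistics and
  temporal shape; no per-channel amplitude normalisation is applied beyond
  ADC unit conversion.
- Sequence order carries information only through the positional table:
  attention itself is permutation-equivariant, and pooling is
  permutation-invariant (verified as a property test).
- Every window inherits its trial's label; a window of a fall trial that
  does not contain the impact is still labelled fall. Trials are therefore
  classified as whole patch sequences, not window-by-window.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window_seconds | 2.0 | s | a fall event lasts ≈ 2 s; the window covers it |
| stride_seconds | window/2 | s | satisfies S < W with 50 % overlap; smaller strides duplicate data heavily |
| target_seconds | trial length | s | uniform duration; long ADLs split, falls resampled |
| heads `h` | 3 | — | divides both D = 9 and D = 81; larger h adds redundant parameters at these widths |
| layers `L` | 6 | — | deeper stacks do not improve accuracy at these token widths |
| mlp_ratio | 4 | — | standard transformer hidden-width ratio |
| attn_scale | `sqrt` | — | scores divided by √d_k; `linear` (÷ d_k) is exposed for comparison |
| batch / lr₀ / decay | 32 / 0.001 / 0.95 | — | smartphone-scale recipe; waist-unit scale uses 16 / 0.001 / 0.98 |
| epochs | 50 (30 in the bundled study) | — | best epoch selected on validation loss, so extra epochs are harmless |

The attention-score normaliser deserves a note: dividing by `d_k` rather
than `√d_k` only rescales the softmax temperature, and both variants are
implemented; `sqrt` is the default because it keeps score variance
independent of head width.

## Numerical design

All arithmetic is float64 NumPy under a small reverse-mode autodiff tape
written for this package; convolution is im2col gather + matmul, so its
backward pass is a scatter-add. This makes every forward/backward bitwise
deterministic given (weights, input), which the reproducibility tests
assert; it also keeps the dependency set to the scientific-Python base.
Finite-difference checks of every operator and of the assembled network
gradient are part of the suite. LayerNorm uses ε = 1e-5; softmax and
cross-entropy are computed in log-space with max-subtraction; Adam uses
(0.9, 0.999, 1e-8). Weight init is Glorot-normal from a per-model seeded
generator; the classifier carries a bias. Non-square windows (e.g. 1 s at
200 Hz → W = 200, n = 14) lose their trailing `W − n²` samples, a logged,
deterministic truncation. Degenerate inputs fail loudly: stride ≥ window,
trials shorter than one window, head counts not dividing `D`, and patches
smaller than 4 samples per side under the conv embedder (two stride-2
layers need them) all raise configuration errors; an all-zero confusion
matrix and empty train/validation sets are rejected.

Model selection: the learning rate at epoch `e` is `lr₀·γᵉ`; after each
epoch the validation loss and metrics are recorded and the weights of the
minimal-validation-loss epoch are restored at the end (selection on the
training loss is available via `select_on="train"`).

The train/test split is chronological — the first 80 % of the
deterministically ordered recordings train the model — and grouped at
source-recording granularity, so subsegments and overlapping windows of one
recording never straddle the split. A raw sample-level split
(`by_trial=False`) exists for comparison but leaks windows and is off by
default.

## The synthetic generator

The simulator is phenomenological: it shapes the acceleration-*magnitude*
profile of each activity and distributes it over axes through a slowly
drifting orientation unit vector, adding white Gaussian sensor noise. It
emulates two scales: 3 s, 50 Hz, 3-channel trials (smartphone-style) by
default, and 12 s, 200 Hz, 9-channel trials (waist-unit-style, second
accelerometer as an attenuated copy, gyroscope as smoothed noise with an
event burst) via `SimConfig.sisfall_scale()`.

- **walk / jog** — 1 g plus a 1.5–3 Hz sinusoid of amplitude 0.3 g; peak
  magnitude stays below 2.5 g by construction.
- **still** — 1 g plus noise.
- **sit / lie (confounders)** — a Gaussian transient whose peak is drawn
  from U(2.0, 3.5) g followed by a sigmoid level-off and (for lie) a
  reorientation of the gravity axis; *no* free-fall dip. About two thirds
  of these cross a 2.5 g threshold, so a magnitude-threshold detector's
  specificity falls as the confounder fraction rises — the failure mode the
  learned model must avoid.
- **fall** — pre-fall gait, a ramp to a 0.2 g magnitude floor over 0.35 s,
  an impact spike drawn from U(3.5, 5.5) g with σ = 0.06 s, rest at 1 g
  with 0.01 g noise, a gyroscope burst spanning the event, and a topple of
  the orientation vector.

Trials are emitted in a deterministically shuffled class order (seeded by
the master seed) so a chronological split contains both classes on both
sides, as a real mixed recording campaign would.

What the generator does **not** model: subject-specific biomechanics,
near-falls and recoveries, sensor drift/saturation, magnetometer channels,
and the 34 distinct activity protocols of real fall corpora. Passing the
bundled end-to-end test therefore shows the pipeline learns the canonical
fall signature against threshold-defeating confounders under realistic
noise — not that it matches any particular accuracy on the public
datasets, which must be obtained by pointing the readers at those corpora.

## The bundled study

The acceptance script and the end-to-end test run the same frozen
conditions: 400 falls + 400 ADLs (confounder fraction 0.2) at the
smartphone scale; 2 s windows, 1 s stride (N = 2 tokens of 10×10×3
patches); C = 3 model (D = 9, h = 3, L = 6, 7 421 parameters); batch 32,
lr 0.001, decay 0.95, 30 epochs; first 600 recordings train, 200 held out.
These sizes keep a full run around twenty seconds on one CPU while leaving
the threshold baseline clearly beatable (it scores ≈ 92–95 % here). The
conv-embedder model and the flatten-only variant train on identical splits
and seeds, so their accuracy difference isolates the local-feature
embedder.

## Design choices that were genuinely open

- **Conv embedder size.** With the `C → 2C → 2C` stride-2 plan the conv
  path holds *fewer* parameters than a dense flatten-and-project of the
  whole patch (993 vs 2 709 at n = 10, C = 3) — stacked small kernels
  shrink the patch before the token projection. Parameter counts still grow
  with window size, as expected.
- **Fall duration normalisation** uses linear resampling onto the target
  grid, not cropping: the impact may sit anywhere in the recording, and
  cropping could drop it.
- **Positional encoding** is learnable rather than sinusoidal; at N ≤ a few
  dozen tokens a table is simpler and at least as expressive.
- **FLOP accounting** counts multiply-adds of the matrix products only;
  element-wise work is a small constant factor at these sizes.

## Known limitations

- The NumPy training loop is single-threaded-friendly but not suited to
  datasets beyond a few thousand windows; the architecture, not the engine,
  is the point.
- Metrics are reported per sample (one patch sequence = one uniformised
  trial); event-level aggregation across subsegments of one long recording
  is not implemented beyond the grouping used for the split.
- The UniMiB-style reader expects the two-file `acc_data`/`acc_labels`
  layout; other exports of that corpus need reshaping first.
- Per-sample detection time is measured and logged in the window ablation
  but never asserted — it is hardware-dependent.
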