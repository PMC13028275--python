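# Methods

## Model

The classifier fuses two frozen feature extractors at the embedding level.
The transformer branch is a standard pre-norm ViT (patch embedding, learned
class token and positional embeddings, multi-head self-attention + GELU MLP
blocks, final layer norm) read out at the class token, `z_t`.  The CNN branch
is a strided 3×3 convolution stack with batch normalization and ReLU, read
out as the per-channel global average of the final feature maps, `z_c`.  The
trainable head is

    z_p = W [z_t ; z_c] + b,        logits = C z_p + c,        p = softmax(logits)

with concatenation fixed transformer-first (so the reference widths 384 and
2560 give a 2944-wide input and, with the default projection width
P = 2048, a 2048 × 2944 projection matrix).

All layers are NumPy implementations with manually derived gradients for the
head.  Branch parameters are initialized from a seed and kept frozen during
head training; `apply_freeze_policy` exposes the general policy (trainable
tail fraction, with every batch-norm layer frozen to running statistics
regardless of position) and audits trainable/frozen parameter counts.
Because embedding-level (SMOTE) batches enter at the fusion point, the frozen
default also makes the gradient-isolation property structural: synthetic
feature batches cannot move branch weights, which the tests assert by
bit-exact parameter snapshots.

**Fusion-point normalization.**  The head carries a non-trainable
per-dimension affine normalization `(z − μ)/σ` calibrated once, on
training-fold embeddings, before optimization begins.  Raw class-token and
GAP coordinates live on very different scales; without this whitening the
effectively linear head conditions poorly and converges slowly.  The buffers
are frozen after calibration and stored with the checkpoint; as a fixed
affine map they commute with SMOTE's convex interpolation, so balancing in
raw and normalized coordinates is equivalent.  Calibration uses training
data only and is therefore leakage-safe.

## Data pipeline

Each image is rendered at two resolutions from the *same* spatial crop —
default 224 px for the transformer and 448 px for the CNN (the low end of the
448–600 px range the CNN path supports), grayscale replicated to three
channels and normalized with ImageNet statistics (the pretraining
distribution of the reference backbones; configurable).  Whether the two
branches should share one crop or sample independently is a genuinely open
choice; sharing keeps the views of a sample consistent, and the test suite
verifies the pairing by cross-resolution correlation.

Training augmentation: RandomResizedCrop (scale 0.6–1.0, aspect 3/4–4/3),
brightness/contrast jitter (±20 %; hue/saturation are undefined on
single-channel input), Gaussian blur (σ ≤ 1), and batch-level MixUp
(α = 0.2) / CutMix (α = 1.0) applied with probability 0.5, mutually
exclusive per batch, with one λ per batch and the same relative patch
geometry on both views.  CutMix label weights use the realized pixel area of
the CNN view, so they match the painted area up to one row of quantization.
Setting every magnitude to zero reproduces the deterministic eval path
(center square crop + resize), a property the tests rely on.

Stratified splitting allocates per class by floors of the requested
fractions with remainders by largest fractional part (ties to
train > val > test), making split sizes a pure function of the class counts;
only membership depends on the seed.  K-fold partitions each class
round-robin after a seeded shuffle, so per-class fold sizes differ by at
most one; `k = 1` degenerates to a single fold.  The default experiment
protocol is a 70/15/15 holdout, with cross-validation available inside the
training portion for model selection, which keeps one untouched test set.

## Feature-space SMOTE and leakage control

`smote_balance` oversamples every minority class to the majority count using
k = 5 same-class Euclidean nearest neighbors (the classic default; shrunk
automatically for classes smaller than k + 1).  Originals are kept unchanged
and first; synthetic rows are provenance-flagged and carry no record id.  A
single-sample class has no neighbor and is duplicated with a warning.
Balancing the reference class distribution 320/150/130 to the majority
yields 3 × 320 = 960 samples.  Note that this arithmetic holds for the full
distribution; inside a 70 % training fold the same policy yields
proportionally fewer rows — the operation is generic and the audit reports
the realized counts.

`leakage_guard` checks that (i) no synthetic row is tagged validation/test,
(ii) train and evaluation record ids are disjoint, and (iii) embedded
records are covered by the split plan; `train_model` refuses to run when the
audit fails, and validation/test metrics are computed on real images only.

## Training

AdamW (decoupled weight decay 0.05) with cosine annealing
`lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos(πt/T))` from lr 1e-3 to 0 over
the epoch budget (default 80 for the hybrid head; learning rates are
package defaults, fully configurable).  The loss is weighted cross-entropy
with label smoothing ε = 0.1 and inverse-frequency weights
`w_c = N/(K n_c)` computed from the training-fold counts.  When a balanced
embedding set is supplied, one embedding batch is interleaved after each
image batch, entering at the fusion point.  The best checkpoint is the
highest validation accuracy, ties to the earliest epoch.  With augmentation
disabled the loop caches the (deterministic) fusion-point embeddings once
and trains the head on them, which is exact and fast.

Multi-seed protocol: each seed gets its own stratified split, model
initialization and run; reports carry per-seed metrics and their arithmetic
mean.  Default three seeds.

## Synthetic data generator

The generator emulates the qualitative phase-contrast appearance of the
three classes: dark elliptical somata (intensity 0.25 on a 0.5 background),
a bright halo ring built as the positive part of a difference-of-Gaussians
of the soma mask (peak 0.45 × halo intensity above background, just outside
the soma rim), dark thin processes drawn as jittered random walks (astrocyte
processes branch once with probability 0.6; cortical neurites are longer,
straighter and fewer; SH-SY5Y cells have none and their positions cluster),
a linear illumination gradient in a random direction, and additive Gaussian
noise (σ = 0.03).  Default per-class counts reproduce the reference
imbalance (320 cortical / 150 SH-SY5Y / 130 astrocyte); images default to
256 × 256 8-bit PNG (the native resolution and bit depth of real Incucyte
exports is unspecified, so these are deliberate desk-scale choices).  Each
record is rendered from a substream keyed by (seed, record index), making
outputs byte-identical across runs and independent of generation order.

What the generator does *not* emulate: optical point-spread structure,
debris and focus drift, density-dependent morphology changes, or any
within-class biological variability beyond parameter jitter.  Passing tests
on this fixture therefore demonstrate pipeline correctness and learnability
mechanics, not expected accuracy on real microscopy.

## Desk-scale test conditions

The tests and examples run the hybrid with small random-weight branches
(transformer: 32-dim, 2 blocks, 64 px view; CNN: 16/32/64 channels, 96 px
view; projection width 64) on a balanced 300-image, 128 px synthetic set.
Under the no-augmentation (cached embedding) regime this configuration
reaches ≥ 90 % accuracy on the untouched test split within 30 epochs on one
CPU in a few seconds.  With the full augmentation stack the frozen-feature
head needs substantially more data/epochs to close the train–eval
distribution gap; the augmented path is exercised for correctness and
determinism rather than accuracy.

## Numerical choices and edge cases

* Probabilities are clamped at 1e-12 inside the loss (with a warning) when a
  supported class receives zero mass; non-finite logits raise.
* Argmax ties resolve to the lowest class index; precision/recall with an
  empty denominator is 0 and the affected classes are flagged in the report.
* PR curves sweep all distinct thresholds in descending order; the area
  helper uses the step-integral (average-precision) convention.
* `cosine_lr` clamps t > T to `lr_min` with a warning; epoch 0 training
  returns the initialization and an empty history.
* Images smaller than a 64 px minimum side are upsampled before cropping,
  with a logged warning.
* Relative improvement is displayed to one decimal: (61.03, 34.76) → +75.6 %
  and (58.82, 34.76) → +69.2 % by direct arithmetic.
* Unparseable prompting outputs count as incorrect for accuracy and are
  excluded from every precision denominator — a conservative, documented
  scoring choice; refusal handling and exemplar selection are configuration.

## Known limitations

The branches are reduced-scale stand-ins initialized from a seed; no
pretrained ImageNet weights ship with the package, and requesting them
raises.  Backbone fine-tuning (non-zero trainable tail) is expressed through
the freeze-policy audit but the optimizer only trains head parameters.
Real vision–language APIs are intentionally outside the test surface; the
harness ships the mock backend only.
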