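# Methods

This document describes the model implemented by `leukonet`, the assumptions
behind it, every user-facing parameter with its default and rationale, the
numerical choices made in the NumPy engine, and known limitations.

## 1. Problem and model

The package implements a two-stage pipeline for classifying single white
blood cell (WBC) images from peripheral blood smears, targeted at the
atypical (immature/reactive) cells that characterise acute myeloid leukemia:

1. **Stage I — binary gate.** A CNN decides *typical vs atypical* from the
   image's autoencoder latent representation.
2. **Stage II — subtype classifier.** Cells gated as atypical are assigned
   one of eight atypical subtypes by a second CNN (softmax over the
   canonical alphabetical order: erythroblast, lymphocyte_atypical,
   metamyelocyte, monoblast, myeloblast, myelocyte, promyelocyte,
   promyelocyte_bilobed).

Because atypical subtypes are rare, training data are rebalanced first with
**GT-DCAE augmentation**: each training image of a rare class is geometrically
transformed (rotation in [0, 360), horizontal/vertical flips — never zoom,
shear or photometric edits, which could alter cytomorphological meaning) and
then passed through a **deep convolutional autoencoder (DCAE)** trained on
that class alone. The reconstruction is a near-copy with autoencoder-smoothed
texture, giving more diverse synthetic minority samples than raw geometric
transforms. One DCAE per atypical subtype (eight models) is used for
synthesis; a separate DCAE trained on all classes supplies the latent
features consumed by both classifier stages.

### DCAE architecture

For a `S x S x 3` input with `S` divisible by 8 (canonical `S = 224`):

| stage | operation | output |
|---|---|---|
| enc 1 | 3x3 conv, 32 filters, LeakyReLU(0.3) + 2x2 max-pool | S/2 x S/2 x 32 |
| enc 2 | 3x3 conv, 64 filters, LeakyReLU(0.3) + 2x2 max-pool | S/4 x S/4 x 64 |
| enc 3 | 3x3 conv, 128 filters, LeakyReLU(0.3) + 2x2 max-pool | S/8 x S/8 x 128 |
| dec 1–3 | mirror: conv 128/64/32 + 2x nearest-neighbour upsample | back to S x S |
| out | 3x3 conv, 3 filters, sigmoid | S x S x 3 |

The bottleneck (`28 x 28 x 128` at 224, `7 x 7 x 128` at 56) is the latent
tensor used both for synthesis and as classifier input. Training minimises
per-pixel-channel mean squared error on the [0, 1] intensity scale.

### Classifier architectures

Stage I: three batch-normalised 3x3 conv layers (64/128/256 filters, ReLU,
L2 weight decay 1e-4), 2x2 max-pooling after the first two convs, 20%
dropout, a 50-unit dense layer and a single sigmoid output. Stage II: four
batch-normalised convs (32/64/128/256), pooling after the third and fourth,
the same dense head with an 8-way softmax. On the canonical 28x28x128 latent
both flatten 7x7x256 = 12 544 features. When the latent grid is too small to
pool the stated number of times (small-image experiments), pooling stages are
dropped from the end of the schedule so the grid never collapses below 1.

Dispatch rule: a cell with Stage-I probability `p >= threshold` (default 0.5)
receives the Stage-II argmax label (ties broken toward the lowest canonical
index); otherwise it is labelled `typical`. Every input receives exactly one
final label.

## 2. Synthetic image generator

No clinical image data ships with the package. A parametric generator
(`leukonet.synthetic`) emulates single-cell microscopy crops well enough to
exercise and validate the pipeline end to end: an anti-aliased elliptical
cell on a pale background, a multi-lobed nucleus whose area is iteratively
rescaled to a target nucleus-to-cell ratio, per-class colour distributions,
nucleus lobe count/elongation, and speckle granularity. The 15 default class
specs (8 atypical + 7 typical) are morphologically distinct by construction;
they are a *test harness*, not a biological claim. Determinism: each image's
RNG is keyed by (dataset seed, class index, image index), so datasets are
bit-reproducible and insertion-order independent.

## 3. Training recipe and the learning-rate warm-scaling

The reference recipe is SGD with momentum 0.8, learning rate 1e-5, batch 32.
`TrainingConfig` keeps those defaults for fidelity. At desk scale (a NumPy
engine on one CPU, tens of epochs, 56x56 images) lr = 1e-5 moves the loss
negligibly, so the *experiments and acceptance runs* warm-scale the learning
rate while keeping the optimiser, momentum, batch size and loss unchanged:

- DCAE training: lr **0.2** (`ExperimentConfig.dcae_learning_rate`). Chosen
  by a small sweep: at 0.05 the 56x56 DCAE reached MSE ≈ 0.008 after 10
  epochs; at 0.2 it reached ≈ 0.0033 in 17 epochs without instability.
- Classifier training: lr **0.05** (`ExperimentConfig.classifier_learning_rate`)
  for the main phase, followed by `finetune_epochs` at lr/5 to settle the
  oscillation that momentum-0.8 SGD shows at this rate.
- Synthesis DCAEs (one per atypical subtype) train on a subsample of the
  class pool (`synth_dcae_subsample`, default 64) with a small batch size
  (`synth_dcae_batch_size`, default 8 — a small pool needs small batches to
  get enough gradient updates per epoch) and stop early once training MSE
  reaches `synth_dcae_target_mse` (default 0.01). Faithful reconstruction is
  what makes GT-DCAE synthesis useful: an under-trained autoencoder degrades
  the synthetic samples instead of smoothing them.

This is a learning-rate x epoch-budget trade-off, not an architectural
change; with the published budget (hundreds of epochs on GPU-scale hardware)
the published rate is the appropriate setting.

Two engine-level measures make the classifiers trainable at these rates:

- **Input standardisation.** Latent tensors have strongly non-zero
  per-channel means; both classifier stages estimate per-channel mean/std on
  the training set at `fit` time, standardise inputs on both the training
  and inference paths, and persist the statistics in checkpoints.
- **Batch-norm recalibration.** After training, running statistics are
  replaced by the exact average of batch moments over the training set under
  the final weights (`Sequential.recalibrate_batchnorm`), removing the gap
  between the exponential-moving-average statistics (which lag during fast
  training) and the deterministic inference path.

## 4. Key parameters

| parameter | default | why |
|---|---|---|
| `DCAESpec.encoder_filters` | (32, 64, 128) | reference architecture |
| `DCAESpec.leaky_alpha` | 0.3 | reference activation slope |
| `TrainingConfig.momentum` | 0.8 | reference optimiser |
| `TrainingConfig.learning_rate` | 1e-5 | reference value; warm-scale at desk scale (§3) |
| `TrainingConfig.batch_size` | 32 | reference value |
| `GTPlan.rounds` | 15 | rotations per source image; +2 flips |
| `BalancePlan.target` | 10 000 | reference per-class target; experiments use 1.5x the observed train count |
| `Stage1Spec.dropout_rate` | 0.2 | reference regularisation |
| `Stage1Spec.l2_coefficient` | 1e-4 | reference weight decay |
| `ExperimentConfig.image_size` | 56 | desk-scale input (same spec family, 3 halving pools) |
| `ExperimentConfig.images_per_class` | 200 | desk-scale dataset size |
| `stage1_threshold` | 0.5 | standard operating point of the sigmoid gate |

## 5. Numerical engine

No deep-learning framework is used; `leukonet.nn` is a small, fully tested
NumPy engine:

- **Convolutions** run as im2col (`numpy.lib.stride_tricks.sliding_window_view`)
  followed by one BLAS matmul, in float32. The backward pass computes the
  input gradient as a convolution with the spatially flipped,
  channel-transposed kernel, and the weight gradient from the cached im2col
  patches.
- **Batch norm** uses the standard per-channel training statistics with
  eps 1e-5 and running-average momentum 0.9 for inference.
- **Max-pooling** scatters gradients to argmax positions; odd trailing
  rows/columns are floor-cropped. **Upsampling** is nearest-neighbour; its
  backward is the block sum.
- **Dropout** is inverted dropout, disabled at inference.
- Losses (`mse`, BCE-with-logits, softmax cross-entropy) are the numerically
  stable log-sum-exp forms and return `(loss, gradient)` pairs.
- Every layer is verified against brute-force oracles (literal loop
  convolution, direct-formula batch norm) and float64 finite-difference
  gradient checks in the test suite.
- Non-finite losses abort training with a `TrainingError` naming the epoch.

Metric primitives delegate to scikit-learn (`confusion_matrix`,
`roc_auc_score`) behind validating wrappers, and are cross-checked in the
tests against counting and exhaustive pairwise Mann-Whitney oracles.
Undefined rates (zero denominators) are returned as NaN and flagged, never
silently zeroed. Report rounding is half-up to 4 decimals.

## 6. Design decisions

- **statsmodels-style API**: model objects (`DCAE`, `Stage1Classifier`, …)
  are configured by frozen spec dataclasses; `fit` returns a results object
  (`DCAEResults`, `ClassifierResults`, `ExperimentResults`) holding learning
  curves, diagnostics and a `summary()` string.
- **Determinism throughout**: model builds are seeded; experiment sub-seeds
  are spawned via `numpy.random.SeedSequence` and reduced mod 2^31.
- **Leak avoidance**: augmentation draws only from the training split; the
  per-class synthesis DCAEs and the feature DCAE are trained on training
  images only.
- **Macro averaging** for multi-class AUC and sensitivity (classes weighted
  equally, matching per-class reporting); classes absent from the truth are
  flagged NaN and excluded from the macro mean.
- **Paired augmentation comparison**: `run_augmentation_comparison` shares
  the generated data, the split, the trained feature DCAE, the real-sample
  latents *and the drawn GT samples* across the GT and GT-DCAE arms; the
  GT-DCAE arm additionally passes the shared GT samples through the
  per-class autoencoders. The arms therefore differ only in the
  reconstruction step — the lowest-variance design for measuring its effect,
  and about twice as cheap as independent experiment runs.

## 7. Limitations and empirical findings

- The synthetic generator produces well-separated classes; absolute scores on
  it say nothing about clinical data. Only *relative* comparisons (e.g.
  GT-DCAE vs GT augmentation) and contract checks are meaningful.
- **On this synthetic benchmark, GT-DCAE augmentation does not beat plain GT
  augmentation.** In matched paired comparisons the GT-only arm's Stage-II
  macro sensitivity is equal or higher in most seeds, and the gap *widens*
  when Stage-II training runs to convergence or when real minority samples
  are scarce. The synthesis autoencoders are not at fault — their
  reconstruction error on GT-transformed inputs (~0.006 MSE) is close to the
  reference range — rather, the generator's classes are partly distinguished
  by high-frequency texture (per-class speckle granularity), and
  reconstruction at desk-scale budgets blurs exactly that discriminative
  detail. Benefits reported on real blood-smear data plausibly come from
  effects this generator does not model (staining and imaging noise, true
  class scarcity). The corresponding acceptance test asserts the directional
  claim anyway and is expected to fail; it is reported honestly rather than
  tuned away.
- The NumPy engine is single-threaded BLAS-bound; canonical 224x224 training
  at published epoch counts is out of desk-scale reach.
- Stage-I calibration, bootstrap confidence intervals and alternative
  probability-adjustment schemes are out of scope.
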