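# leukonet

Two-stage classification of atypical white blood cells in single-cell blood
smear images, with GT-DCAE minority-class augmentation — a deep convolutional
autoencoder (DCAE) that turns geometric transforms (rotations/flips) of rare
atypical cells into near-copy synthetic training images — implemented from
scratch in NumPy with a statsmodels-style model/results API.

- **Stage I**: CNN gate, *typical vs atypical*, on DCAE latent features.
- **Stage II**: CNN over the eight atypical subtypes (erythroblast, atypical
  lymphocyte, metamyelocyte, monoblast, myeloblast, myelocyte, promyelocyte,
  bilobed promyelocyte).
- **GT-DCAE augmentation**: one autoencoder per atypical subtype reconstructs
  rotated/flipped training images to rebalance rare classes before training.
- **Synthetic data included**: a parametric single-cell image generator
  (elliptical cell, multi-lobed nucleus, per-class morphology) makes the whole
  pipeline runnable and testable without clinical data.

See [docs/methods.md](docs/methods.md) for the model, assumptions, parameter
rationale (including the desk-scale learning-rate warm-scaling) and numerical
details.

## Quick start (Python API)

Models follow the statsmodels convention: a spec-configured model object,
`fit()` returning a results object with history and `summary()`.

```python
import leukonet as lk

# 1. synthetic data: 200 images/class at 56x56, deterministic under seed
samples = lk.generate_samples(lk.GeneratorConfig(
    specs=lk.default_class_specs(), images_per_class=200,
    image_size=56, seed=7))
train, test = lk.split_samples(samples, test_fraction=0.2, seed=7)

# 2. one DCAE per rare class -> GT-DCAE synthesis
myeloblasts = [s for s in train if s.label == "myeloblast"]
dcae = lk.DCAE(lk.DCAESpec(input_size=56), seed=7)
res = dcae.fit(myeloblasts, lk.TrainingConfig(
    learning_rate=0.2, epochs=30, batch_size=32, seed=7, target_loss=0.0035))
print(res.summary())
synthetic = dcae.synthesize(myeloblasts, target_count=100,
                            gt_plan=lk.GTPlan(seed=7), seed=7)

# 3. latent features + the two classifier stages
z = dcae.encode([s for s in train])          # (N, 7, 7, 128)
```

The one-call experiment driver runs the full workflow (generate, split,
per-class DCAEs, balancing, latent features, both stages, evaluation):

```python
result = lk.run_experiment(lk.ExperimentConfig(seed=0), out_dir="exp0")
print(result.summary())
```

At the desk-scale defaults (56x56 images, 200 per class, single CPU, ~4.5
minutes) the seed-0 run reaches:

```
experiment (features=dcae, augmentation=gt-dcae, seed=0)
  train/test images: 2400/600
  Stage-I held-out AUC: 0.9828
  Stage-II overall accuracy: 0.9812, macro sensitivity: 0.9812
```

`run_augmentation_comparison` runs the matched GT vs GT-DCAE comparison
(shared data, split, features and GT samples; the GT-DCAE arm additionally
reconstructs the samples through the per-class autoencoders). On this
synthetic benchmark the reconstruction step does **not** improve Stage-II
macro sensitivity — see §7 of [docs/methods.md](docs/methods.md) for the
analysis.

## Command line

Every phase is scriptable through the `leukonet` entry point:

```bash
leukonet generate --out data --images-per-class 200 --image-size 56 --seed 7
leukonet split --manifest data/manifest.csv --test-fraction 0.2 --seed 7 --out data/manifest.csv
leukonet train-dcae --manifest data/manifest.csv --label myeloblast \
    --image-size 56 --epochs 30 --learning-rate 0.2 --out dcae_myeloblast.h5
leukonet synthesize --model dcae_myeloblast.h5 --manifest data/manifest.csv \
    --label myeloblast --count 100 --out synth/
leukonet train --stage 1 --dcae dcae.h5 --manifest data/manifest.csv --out s1.h5
leukonet train --stage 2 --dcae dcae.h5 --manifest data/manifest.csv --out s2.h5
leukonet predict --dcae dcae.h5 --stage1 s1.h5 --stage2 s2.h5 \
    --manifest data/manifest.csv --split test --out pred.csv
leukonet evaluate --predictions pred.csv --out report.json
leukonet run-experiment --seed 0 --out exp0
```

## Tests

```bash
python -m pytest -q tests/
```

The suite verifies the NumPy engine against brute-force oracles (literal-loop
convolution, direct batch-norm, exhaustive pairwise ROC-AUC), the metric
worked examples, generator morphology contracts, GT transform identities,
training convergence and checkpoint round-trips. `tests/test_acceptance.py`
holds the end-to-end acceptance criteria (slowest part; the whole suite is
sized for a single CPU).

One acceptance test is a *known, deliberate failure*:
`test_criterion5_gt_dcae_beats_gt_in_majority_of_seeds` asserts that GT-DCAE
augmentation beats plain GT augmentation in a majority of seeds. On this
synthetic benchmark it does not (see §7 of docs/methods.md); the test states
the claim honestly instead of being tuned until it passes.

## Layout

```
src/leukonet/
  taxonomy.py     class labels, canonical atypical order
  dataset.py      image I/O, manifests, stratified splits
  synthetic.py    parametric single-cell image generator
  gt.py           geometric transforms (rotations, flips)
  nn/             NumPy conv/BN/pool/dense engine, losses, SGD, train loop
  dcae.py         autoencoder model + results (encode/decode/synthesize)
  classifiers.py  Stage-I and Stage-II CNNs
  metrics.py      confusion matrix, P/R/S/F, ROC-AUC, report assembly
  pipeline.py     balancing, two-stage dispatch, experiment driver
  cli.py          click command-line interface
```
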