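"""The two CNN classification stages operating on DCAE latent tensors.

Stage I is a binary gate — typical vs atypical WBC — with three
batch-normalised 3x3 convolutional layers (64/128/256 filters, ReLU, L2
weight decay, 20% dropout), max-pooling after the first two, a 50-unit dense
layer, and a single sigmoid output. Stage II classifies atypical latents
into the eight subtypes with four batch-normalised convolutional layers
(32/64/128/256), pooling after the third and fourth, a 50-unit dense layer
and an 8-way softmax. At the canonical 28x28x128 latent both stages flatten
7x7x256 = 12544 features.

Both stages train with SGD + momentum on cross-entropy; inference is
deterministic (dropout off, batch-norm running statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .nn.losses import sigmoid, softmax
from .taxonomy import ATYPICAL_CLASSES, Taxonomy, TaxonomyError, default_taxonomy
from .training import TrainingConfig


@dataclass(frozen=True)
class Stage1Spec:
    """Typical-vs-atypical CNN architecture."""

    input_shape: tuple[int, int, int] = (28, 28, 128)
    conv_filters: tuple[int, ...] = (64, 128, 256)
    kernel: int = 3
    pool_after: tuple[int, ...] = (0, 1)  # conv indices followed by 2x2 pooling
    dropout_rate: float = 0.2
    l2_coefficient: float = 1e-4
    dense_units: int = 50
    output_units: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def grid_chain(self) -> list[int]:
        """Spatial size after each conv stage (post-pool where pooled)."""
        s = self.input_shape[0]
        chain = []
        for i, _ in enumerate(self.conv_filters):
            if i in self.pool_after:
                s //= 2
            chain.append(s)
        return chain

    def flattened_size(self) -> int:
        s = self.grid_chain()[-1]
        return s * s * self.conv_filters[-1]


@dataclass(frozen=True)
class Stage2Spec(Stage1Spec):
    """Atypical-subtype CNN architecture (8-way softmax head)."""

    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    pool_after: tuple[int, ...] = (2, 3)
    output_units: int = 8


@dataclass
class ClassifierResults:
    """Per-epoch loss/accuracy curves from a classifier fit."""

    model: "_StageClassifier"
    history: dict[str, list[float]]
    config: TrainingConfig

    @property
    def final_loss(self) -> float | None:
        return self.history["loss"][-1] if self.history["loss"] else None

    def summary(self) -> str:
        lines = [f"{type(self.model).__name__} fit summary",
                 f"  epochs run: {len(self.history['loss'])} "
                 f"(batch {self.config.batch_size}, lr {self.config.learning_rate:g})"]
        for key in ("loss", "accuracy", "val_loss", "val_accuracy"):
            if key in self.history and self.history[key]:
                lines.append(f"  final {key}: {self.history[key][-1]:.4f}")
        return "\n".join(lines)


class _StageClassifier:
    """Shared build/fit/predict machinery for both stages."""

    kind = "classifier"

    def __init__(self, spec: Stage1Spec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[nn.layers.Layer] = []
        cin = spec.input_shape[2]
        for i, f in enumerate(spec.conv_filters):
            layers.append(nn.Conv2D(cin, f, spec.kernel, activation="relu", rng=rng))
            layers.append(nn.BatchNorm(f))
            if i in spec.pool_after:
                layers.append(nn.MaxPool2D(2))
            if spec.dropout_rate > 0:
                layers.append(nn.Dropout(spec.dropout_rate))
            cin = f
        layers.append(nn.Flatten())
        layers.append(nn.Dense(spec.flattened_size(), spec.dense_units,
                               activation="relu", rng=rng))
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate))
        # linear head: the loss works on logits; predict_* applies the squashing
        layers.append(nn.Dense(spec.dense_units, spec.output_units,
                               activation="linear", rng=rng))
        self.net = nn.Sequential(layers)
        # per-channel input standardisation, estimated from the training set
        c = spec.input_shape[2]
        self.input_mean = np.zeros(c, dtype=np.float32)
        self.input_std = np.ones(c, dtype=np.float32)

    def _check_latents(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32)
        if z.ndim == 3:
            z = z[None]
        if z.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"expected latents of shape {self.spec.input_shape}, got {z.shape[1:]}")
        return z

    def _standardize(self, z: np.ndarray) -> np.ndarray:
        return ((z - self.input_mean) / self.input_std).astype(np.float32)

    def _logits(self, latents, batch_size: int = 32) -> np.ndarray:
        return self.net.predict(self._standardize(self._check_latents(latents)),
                                batch_size)

    def _fit(self, x, y, loss_fn, accuracy_fn, config, validation) -> ClassifierResults:
        cfg = config or TrainingConfig()
        if cfg.epochs > 0:
            # per-channel standardisation conditions the optimisation; the
            # statistics are stored so inference applies the same transform
            self.input_mean = x.mean(axis=(0, 1, 2)).astype(np.float32)
            self.input_std = (x.std(axis=(0, 1, 2)) + 1e-6).astype(np.float32)
        x = self._standardize(x)
        if validation is not None:
            validation = (self._standardize(validation[0]), validation[1])
        history = nn.train_loop(
            self.net, x, y, loss_fn,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, momentum=cfg.momentum,
            weight_decay=cfg.weight_decay if cfg.weight_decay
            else self.spec.l2_coefficient,
            seed=cfg.seed, validation=validation, accuracy_fn=accuracy_fn,
            target_loss=cfg.target_loss,
        )
        if cfg.epochs > 0:
            # replace the EMA batch-norm statistics with the exact training-set
            # moments under the final weights (deterministic inference path)
            self.net.recalibrate_batchnorm(x, cfg.batch_size)
        return ClassifierResults(self, history, cfg)

    def save(self, path) -> Path:
        from .checkpoints import save_checkpoint
        state = dict(self.net.state_arrays())
        state["input/mean"] = self.input_mean
        state["input/std"] = self.input_std
        return save_checkpoint(path, self.kind, self.spec, state,
                               meta={"seed": self.seed})

    @classmethod
    def _load(cls, path, spec_cls):
        from .checkpoints import load_checkpoint
        kind, spec_d, state, meta = load_checkpoint(path)
        if kind != cls.kind:
            raise ValueError(f"checkpoint at {path} is a {kind!r}, not a {cls.kind}")
        for key in ("input_shape", "conv_filters", "pool_after"):
            spec_d[key] = tuple(spec_d[key])
        model = cls(spec_cls(**spec_d), seed=meta.get("seed", 0))
        model.input_mean = np.asarray(state.pop("input/mean"), dtype=np.float32)
        model.input_std = np.asarray(state.pop("input/std"), dtype=np.float32)
        model.net.load_state_arrays(state)
        return model


class Stage1Classifier(_StageClassifier):
    """Binary typical/atypical gate; emits P(atypical)."""

    kind = "stage1"

    def __init__(self, spec: Stage1Spec | None = None, seed: int = 0):
        super().__init__(spec or Stage1Spec(), seed)

    def fit(self, latents, labels, config: TrainingConfig | None = None,
            validation=None) -> ClassifierResults:
        """Train on latents with binary labels (1 = atypical)."""
        x = self._check_latents(latents)
        y = np.asarray(labels, dtype=np.float32).reshape(-1, 1)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")

        def acc(net, xa, ya):
            p = sigmoid(net.predict(xa, config.batch_size if config else 32))
            return float(np.mean((p >= 0.5) == (ya >= 0.5)))

        val = None
        if validation is not None:
            val = (self._check_latents(validation[0]),
                   np.asarray(validation[1], dtype=np.float32).reshape(-1, 1))
        return self._fit(x, y, nn.bce_with_logits, acc, config, val)

    def predict_proba(self, latents, batch_size: int = 32) -> np.ndarray:
        """P(atypical) in [0, 1] for each latent; deterministic."""
        return sigmoid(self._logits(latents, batch_size)).reshape(-1)

    @classmethod
    def load(cls, path) -> "Stage1Classifier":
        return cls._load(path, Stage1Spec)


class Stage2Classifier(_StageClassifier):
    """Eight-way atypical-subtype classifier; emits the probability vector pi."""

    kind = "stage2"

    def __init__(self, spec: Stage2Spec | None = None, seed: int = 0,
                 taxonomy: Taxonomy | None = None):
        super().__init__(spec or Stage2Spec(), seed)
        self.taxonomy = taxonomy or default_taxonomy()

    def _encode_labels(self, labels: Sequence[str | int]) -> np.ndarray:
        idx = []
        for lab in labels:
            if isinstance(lab, (int, np.integer)):
                if not 0 <= int(lab) < len(ATYPICAL_CLASSES):
                    raise TaxonomyError(f"atypical class index out of range: {lab}")
                idx.append(int(lab))
            else:
                idx.append(self.taxonomy.atypical_index(lab))
        return np.asarray(idx, dtype=np.int64)

    def fit(self, latents, labels, config: TrainingConfig | None = None,
            validation=None) -> ClassifierResults:
        """Train on atypical latents; ``labels`` are subtype names or indices."""
        x = self._check_latents(latents)
        y = self._encode_labels(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain at least two subtypes")

        def acc(net, xa, ya):
            p = net.predict(xa, config.batch_size if config else 32)
            return float(np.mean(p.argmax(axis=1) == ya))

        val = None
        if validation is not None:
            val = (self._check_latents(validation[0]),
                   self._encode_labels(validation[1]))
        return self._fit(x, y, nn.softmax_ce_with_logits, acc, config, val)

    def predict_proba(self, latents, batch_size: int = 32) -> np.ndarray:
        """(N, 8) probability vectors in canonical atypical class order."""
        return softmax(self._logits(latents, batch_size))

    def predict_subtype(self, latent) -> np.ndarray:
        """Probability vector pi for a single latent; sums to 1."""
        return self.predict_proba(latent)[0]

    def predict_labels(self, latents, batch_size: int = 32) -> list[str]:
        probs = self.predict_proba(latents, batch_size)
        return [argmax_class(p, self.taxonomy) for p in probs]

    @classmethod
    def load(cls, path) -> "Stage2Classifier":
        return cls._load(path, Stage2Spec)


def argmax_class(pi: np.ndarray, taxonomy: Taxonomy | None = None) -> str:
    """Label of the maximal probability; ties break to the lowest index."""
    pi = np.asarray(pi, dtype=np.float64).reshape(-1)
    if pi.shape[0] != len(ATYPICAL_CLASSES):
        raise ValueError(f"expected a vector of {len(ATYPICAL_CLASSES)} probabilities")
    taxonomy = taxonomy or default_taxonomy()
    return taxonomy.atypical_label(int(np.argmax(pi)))


def build_stage1(spec: Stage1Spec | None = None, seed: int = 0) -> Stage1Classifier:
    return Stage1Classifier(spec, seed)


def build_stage2(spec: Stage2Spec | None = None, seed: int = 0) -> Stage2Classifier:
    return Stage2Classifier(spec, seed)
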