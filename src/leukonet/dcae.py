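"""Deep convolutional autoencoder (DCAE).

The encoder compresses a square RGB cell image through three 3x3
convolutional layers of 32/64/128 filters (LeakyReLU), each followed by a
2x2 halving max-pool, into a latent tensor Z of shape (s, s, 128) with
``s = input_size / 8`` — 28x28x128 at the canonical 224x224 input. The
decoder mirrors the encoder with 128/64/32 filters and 2x nearest-neighbour
upsampling, closing with a 3-filter sigmoid convolution so reconstructions
live in [0, 1]. Training minimises per-pixel-channel mean squared error.

Besides reconstruction the model serves two roles:

* **feature extractor** — the latent tensor is the input representation of
  the downstream typical/atypical and subtype classifiers;
* **augmentation generator** — ``synthesize`` reconstructs geometrically
  transformed source images, emitting near-copy synthetic cells used to
  balance rare atypical classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .dataset import ImageSample, as_array
from .gt import GTPlan, flip, rotate
from .training import TrainingConfig


class SpecError(ValueError):
    """Architecture spec that cannot produce the declared latent grid."""


@dataclass(frozen=True)
class DCAESpec:
    """Mirror-symmetric encoder/decoder architecture description."""

    input_size: int = 224
    channels: int = 3
    encoder_filters: tuple[int, ...] = (32, 64, 128)
    decoder_filters: tuple[int, ...] = (128, 64, 32)
    kernel: int = 3
    leaky_alpha: float = 0.3

    def __post_init__(self) -> None:
        n = len(self.encoder_filters)
        if self.decoder_filters != tuple(reversed(self.encoder_filters)):
            raise SpecError("decoder filters must mirror the encoder")
        if self.input_size % (2 ** n) != 0:
            raise SpecError(
                f"input size {self.input_size} is not divisible by {2**n}: "
                "the pooling chain cannot reach an integer latent grid")

    @property
    def latent_size(self) -> int:
        return self.input_size // (2 ** len(self.encoder_filters))

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return (self.latent_size, self.latent_size, self.encoder_filters[-1])

    @property
    def encoder_grids(self) -> list[tuple[int, int, int]]:
        """Post-pool output grid of each encoder stage."""
        grids, s = [], self.input_size
        for f in self.encoder_filters:
            s //= 2
            grids.append((s, s, f))
        return grids


@dataclass
class DCAEResults:
    """Fit outcome: loss history and a handle back to the trained model."""

    model: "DCAE"
    history: dict[str, list[float]]
    config: TrainingConfig

    @property
    def loss_history(self) -> list[float]:
        return self.history["loss"]

    @property
    def final_loss(self) -> float | None:
        return self.history["loss"][-1] if self.history["loss"] else None

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "DCAE fit summary",
            f"  input: {spec.input_size}x{spec.input_size}x{spec.channels}"
            f"  latent: {'x'.join(map(str, spec.latent_shape))}",
            f"  epochs run: {len(self.loss_history)} (batch {self.config.batch_size}, "
            f"lr {self.config.learning_rate:g}, momentum {self.config.momentum})",
        ]
        if self.loss_history:
            lines.append(f"  training MSE: first {self.loss_history[0]:.6f}, "
                         f"final {self.final_loss:.6f}")
        if "val_loss" in self.history and self.history["val_loss"]:
            lines.append(f"  validation MSE: final {self.history['val_loss'][-1]:.6f}")
        return "\n".join(lines)


class DCAE:
    """Convolutional autoencoder model object.

    Construction is deterministic under ``seed``. ``fit`` trains with SGD +
    momentum and returns :class:`DCAEResults`.
    """

    def __init__(self, spec: DCAESpec | None = None, seed: int = 0):
        self.spec = spec or DCAESpec()
        self.seed = seed
        rng = np.random.default_rng(seed)
        a = self.spec.leaky_alpha
        k = self.spec.kernel

        enc_layers: list[nn.layers.Layer] = []
        cin = self.spec.channels
        for f in self.spec.encoder_filters:
            enc_layers.append(nn.Conv2D(cin, f, k, activation="leaky_relu",
                                        alpha=a, rng=rng))
            enc_layers.append(nn.MaxPool2D(2))
            cin = f
        self.encoder = nn.Sequential(enc_layers)

        dec_layers: list[nn.layers.Layer] = []
        for f in self.spec.decoder_filters:
            dec_layers.append(nn.Conv2D(cin, f, k, activation="leaky_relu",
                                        alpha=a, rng=rng))
            dec_layers.append(nn.Upsample2D(2))
            cin = f
        # output head squashes to [0, 1] so reconstructions are valid images
        dec_layers.append(nn.Conv2D(cin, self.spec.channels, k, activation="sigmoid",
                                    rng=rng))
        self.decoder = nn.Sequential(dec_layers)
        self._net = nn.Sequential(self.encoder.layers + self.decoder.layers)

    # -- shape plumbing ------------------------------------------------------

    def _check_images(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        s, c = self.spec.input_size, self.spec.channels
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (s, s, c):
            raise ValueError(f"expected images of shape ({s},{s},{c}), got {x.shape[1:]}")
        return x

    def _check_latents(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32)
        if z.ndim == 3:
            z = z[None]
        if z.shape[1:] != self.spec.latent_shape:
            raise ValueError(
                f"expected latents of shape {self.spec.latent_shape}, got {z.shape[1:]}")
        return z

    # -- core operations -----------------------------------------------------

    def encode(self, images, batch_size: int = 32) -> np.ndarray:
        """Map images (N,H,W,3) — or a list of samples — to latent tensors."""
        if isinstance(images, Sequence) and images and isinstance(images[0], ImageSample):
            images = as_array(images)
        x = self._check_images(images)
        return self.encoder.predict(x, batch_size)

    def decode(self, latents, batch_size: int = 32) -> np.ndarray:
        """Map latent tensors back to images in [0, 1]."""
        z = self._check_latents(latents)
        return np.clip(self.decoder.predict(z, batch_size), 0.0, 1.0)

    def reconstruct(self, images, batch_size: int = 32) -> np.ndarray:
        return self.decode(self.encode(images, batch_size), batch_size)

    def fit(self, images, config: TrainingConfig | None = None,
            validation=None) -> DCAEResults:
        """Train to reconstruct ``images``; returns results with history."""
        if isinstance(images, Sequence) and images and isinstance(images[0], ImageSample):
            images = as_array(images)
        x = self._check_images(images)
        if len(x) < 1:
            raise ValueError("need at least one training image")
        cfg = config or TrainingConfig()
        val = None
        if validation is not None:
            xv = self._check_images(validation if not (
                isinstance(validation, Sequence) and validation
                and isinstance(validation[0], ImageSample)) else as_array(validation))
            val = (xv, xv)
        history = nn.train_loop(
            self._net, x, x, nn.mse_loss,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, momentum=cfg.momentum,
            weight_decay=cfg.weight_decay, seed=cfg.seed,
            validation=val, target_loss=cfg.target_loss,
        )
        return DCAEResults(self, history, cfg)

    def reconstruction_mse(self, images, batch_size: int = 32) -> float:
        """Mean over images of per-pixel-channel squared reconstruction error."""
        if isinstance(images, Sequence) and images and isinstance(images[0], ImageSample):
            images = as_array(images)
        x = self._check_images(images)
        if len(x) < 1:
            raise ValueError("need at least one image")
        y = self.reconstruct(x, batch_size)
        return float(np.mean((x - y) ** 2))

    def synthesize(self, pool: Sequence[ImageSample], target_count: int,
                   gt_plan: GTPlan | None = None, seed: int = 0,
                   batch_size: int = 32) -> list[ImageSample]:
        """Generate ``target_count`` synthetic images from a source pool.

        Each output is the autoencoder reconstruction of a geometrically
        transformed source: a uniformly drawn pool image receives either a
        random rotation or a flip, then passes through encode -> decode.
        Labels are inherited from the sources.
        """
        if target_count < 1:
            raise ValueError("target_count must be >= 1")
        if not pool:
            raise ValueError("source pool is empty")
        plan = gt_plan or GTPlan()
        rng = np.random.default_rng(seed)
        lo, hi = plan.angle_domain
        sources, transformed = [], []
        for _ in range(target_count):
            src = pool[int(rng.integers(len(pool)))]
            if plan.include_flips and rng.random() < 0.2:
                g = flip(src, "horizontal" if rng.random() < 0.5 else "vertical")
            else:
                g = rotate(src, rng.uniform(lo, hi))
            sources.append(src)
            transformed.append(g)
        recon = self.reconstruct(as_array(transformed), batch_size)
        out = []
        for i, (src, g) in enumerate(zip(sources, transformed)):
            out.append(ImageSample(recon[i], label=src.label,
                                   source_id=f"{src.source_id}_syn{i:05d}"))
        return out

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> Path:
        from .checkpoints import save_checkpoint
        return save_checkpoint(path, "dcae", self.spec, self._net.state_arrays(),
                               meta={"seed": self.seed})

    @classmethod
    def load(cls, path) -> "DCAE":
        from .checkpoints import load_checkpoint
        kind, spec_d, state, meta = load_checkpoint(path)
        if kind != "dcae":
            raise ValueError(f"checkpoint at {path} is a {kind!r}, not a DCAE")
        spec_d["encoder_filters"] = tuple(spec_d["encoder_filters"])
        spec_d["decoder_filters"] = tuple(spec_d["decoder_filters"])
        model = cls(DCAESpec(**spec_d), seed=meta.get("seed", 0))
        model._net.load_state_arrays(state)
        return model


def build_dcae(spec: DCAESpec | None = None, seed: int = 0) -> DCAE:
    """Construct a DCAE with deterministic initial parameters."""
    return DCAE(spec, seed)
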