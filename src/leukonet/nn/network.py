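"""Sequential container and the shared minibatch training loop."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .layers import Layer, Param
from .optim import SGDMomentum


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite (divergence)."""


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    @property
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode forward in batches (dropout off, BN running stats)."""
        outs = [self.forward(x[i: i + batch_size], training=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.rng = rng

    def recalibrate_batchnorm(self, x: np.ndarray, batch_size: int = 32) -> None:
        """Set batch-norm running stats to the data's actual moments.

        Training leaves the running statistics as an exponential moving
        average over (noisy, small) minibatches, which can lag the final
        weights. This pass replaces them with the exact average of batch
        moments over ``x`` under the final weights — dropout disabled so the
        statistics match the inference path. No parameters change.
        """
        from .layers import BatchNorm, Dropout

        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        if not bns:
            return
        drops = [l for l in self.layers if isinstance(l, Dropout)]
        saved = [d.rate for d in drops]
        for d in drops:
            d.rate = 0.0
        for bn in bns:
            bn.start_calibration()
        try:
            for i in range(0, len(x), batch_size):
                self.forward(x[i: i + batch_size], training=True)
        finally:
            for bn in bns:
                bn.stop_calibration()
            for d, r in zip(drops, saved):
                d.rate = r

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All trainable and running-stat arrays, keyed for checkpointing."""
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i:02d}/param{j}_{p.name}"] = p.value
            for attr in ("running_mean", "running_var"):
                if hasattr(layer, attr):
                    state[f"layer{i:02d}/{attr}"] = getattr(layer, attr)
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p.value[...] = state[f"layer{i:02d}/param{j}_{p.name}"]
            for attr in ("running_mean", "running_var"):
                if hasattr(layer, attr):
                    setattr(layer, attr,
                            np.asarray(state[f"layer{i:02d}/{attr}"], dtype=np.float32))


def train_loop(
    net: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    loss_fn: Callable,
    *,
    epochs: int,
    batch_size: int,
    learning_rate: float,
    momentum: float = 0.8,
    weight_decay: float = 0.0,
    seed: int = 0,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    accuracy_fn: Callable | None = None,
    target_loss: float | None = None,
) -> dict[str, list[float]]:
    """Minibatch SGD training; returns a per-epoch history dict.

    History keys: ``loss`` (mean over batches), optional ``accuracy``,
    ``val_loss``/``val_accuracy`` when a validation pair is given. Training
    stops early once the epoch loss reaches ``target_loss``; the history then
    has fewer than ``epochs`` entries. A non-finite loss raises
    :class:`TrainingError` naming the epoch.
    """
    rng = np.random.default_rng(seed)
    net.set_dropout_rng(np.random.default_rng(rng.integers(2**31)))
    opt = SGDMomentum(net.params, learning_rate, momentum, weight_decay)
    history: dict[str, list[float]] = {"loss": []}
    if accuracy_fn is not None:
        history["accuracy"] = []
    if validation is not None:
        history["val_loss"] = []
        if accuracy_fn is not None:
            history["val_accuracy"] = []

    n = len(x)
    for epoch in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start: start + batch_size]
            out = net.forward(x[idx], training=True)
            loss, grad = loss_fn(out, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            net.backward(grad)
            opt.step()
            batch_losses.append(loss)
        history["loss"].append(float(np.mean(batch_losses)))
        if accuracy_fn is not None:
            history["accuracy"].append(accuracy_fn(net, x, y))
        if validation is not None:
            xv, yv = validation
            out = net.predict(xv, batch_size)
            vloss, _ = loss_fn(out, yv)
            history["val_loss"].append(float(vloss))
            if accuracy_fn is not None:
                history["val_accuracy"].append(accuracy_fn(net, xv, yv))
        if target_loss is not None and history["loss"][-1] <= target_loss:
            break
    return history
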