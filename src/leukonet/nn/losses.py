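"""Losses, each returning (scalar loss, gradient w.r.t. the network output)."""

from __future__ import annotations

import numpy as np


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over every element (pixel-channel scale-free)."""
    diff = pred - target
    with np.errstate(over="ignore"):  # divergence is reported via the loss value
        loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Binary cross-entropy on raw logits (numerically stable form).

    ``logits`` (N,) or (N,1); ``y`` binary targets of the same shape.
    """
    z = logits.reshape(-1)
    t = y.reshape(-1).astype(np.float32)
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    p = sigmoid(z)
    grad = ((p - t) / z.size).reshape(logits.shape)
    return loss, grad.astype(np.float32)


def softmax_ce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Categorical cross-entropy on raw logits; ``y`` holds class indices."""
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = z.shape[0]
    loss = float(-logp[np.arange(n), y].mean())
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(logits: np.ndarray) -> np.ndarray:
    # exp overflow for very negative logits saturates harmlessly to 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-logits))
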