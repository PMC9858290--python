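"""Stochastic gradient descent with classical momentum and L2 weight decay."""

from __future__ import annotations

import numpy as np

from .layers import Param


class SGDMomentum:
    """v <- mu*v - lr*(g + wd*w);  w <- w + v  (decay only where flagged)."""

    def __init__(self, params: list[Param], learning_rate: float,
                 momentum: float = 0.8, weight_decay: float = 0.0):
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        self.params = params
        self.lr = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v
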