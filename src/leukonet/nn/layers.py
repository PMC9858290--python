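"""Layers with explicit forward/backward passes.

All tensors are channels-last float32: images/feature stacks are
(N, H, W, C), dense activations are (N, D). Every layer caches what its
backward pass needs during a training forward pass only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-5


class Param:
    """A trainable array with its gradient accumulator.

    ``decay`` marks parameters subject to L2 weight decay (kernel weights
    yes; biases and batch-norm scales no).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# -- activations -------------------------------------------------------------

def _activate(z: np.ndarray, kind: str, alpha: float) -> np.ndarray:
    if kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "leaky_relu":
        return np.where(z > 0.0, z, alpha * z)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str, alpha: float) -> np.ndarray:
    if kind == "linear":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0.0).astype(z.dtype)
    if kind == "leaky_relu":
        g = np.full_like(z, alpha)
        g[z > 0.0] = 1.0
        return g
    if kind == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {kind!r}")


class Layer:
    params: tuple[Param, ...] = ()
    rng: np.random.Generator | None = None  # set by the trainer for dropout

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# -- convolution -------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padded im2col: (N,H,W,C) -> (N*H*W, k*k*C)."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    cols = cols.transpose(0, 1, 2, 4, 5, 3)  # N,H,W,k,k,C
    return np.ascontiguousarray(cols).reshape(n * h * w, k * k * c)


class Conv2D(Layer):
    """Same-padded square convolution with a fused elementwise activation."""

    def __init__(self, in_channels: int, filters: int, kernel: int = 3,
                 activation: str = "linear", alpha: float = 0.3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        k = kernel
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        fan_in, fan_out = k * k * in_channels, k * k * filters
        self.w = Param(glorot_uniform(rng, (k, k, in_channels, filters), fan_in, fan_out),
                       decay=True, name="conv_w")
        self.b = Param(np.zeros(filters, dtype=np.float32), name="conv_b")
        self.kernel = k
        self.in_channels = in_channels
        self.filters = filters
        self.activation = activation
        self.alpha = alpha
        self.params = (self.w, self.b)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"conv expects {self.in_channels} input channels, got {x.shape[-1]}")
        n, h, w, _ = x.shape
        k = self.kernel
        cols = _im2col(x, k)
        z = cols @ self.w.value.reshape(k * k * self.in_channels, self.filters)
        z += self.b.value
        z = z.reshape(n, h, w, self.filters)
        a = _activate(z, self.activation, self.alpha)
        if training:
            self._cache = (cols, z, a, x.shape)
        return a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, z, a, xshape = self._cache
        self._cache = None
        n, h, w, cin = xshape
        k = self.kernel
        dz = dy * _activate_grad(z, a, self.activation, self.alpha)
        dzf = dz.reshape(n * h * w, self.filters)
        self.w.grad[...] = (cols.T @ dzf).reshape(self.w.value.shape)
        self.b.grad[...] = dzf.sum(axis=0)
        # dx = dz convolved with the spatially flipped, channel-transposed kernel
        wt = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)  # k,k,Cout,Cin
        dcols = _im2col(dz, k)
        dx = dcols @ np.ascontiguousarray(wt).reshape(k * k * self.filters, cin)
        return dx.reshape(n, h, w, cin)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
           activation: str = "linear", alpha: float = 0.3) -> np.ndarray:
    """Functional same-padded convolution (one feature map per filter).

    ``x`` is (H, W, Cin) or (N, H, W, Cin); ``w`` is (k, k, Cin, Cout).
    Spatial dimensions are preserved. Raises on a channel-depth mismatch.
    """
    single = x.ndim == 3
    xb = x[None] if single else x
    k, k2, cin, cout = w.shape
    if k != k2:
        raise ValueError("kernel must be square")
    if xb.shape[-1] != cin:
        raise ValueError(f"kernel depth {cin} does not match input depth {xb.shape[-1]}")
    n, h, ww, _ = xb.shape
    z = _im2col(xb.astype(np.float32), k) @ w.reshape(k * k * cin, cout).astype(np.float32)
    if b is not None:
        z += np.asarray(b, dtype=np.float32)
    z = z.reshape(n, h, ww, cout)
    out = _activate(z, activation, alpha)
    return out[0] if single else out


# -- pooling / upsampling ----------------------------------------------------

class MaxPool2D(Layer):
    """2x2 max pooling with stride 2 (odd trailing row/column dropped)."""

    def __init__(self, pool: int = 2):
        self.pool = pool
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.pool
        n, h, w, c = x.shape
        h2, w2 = h // p, w // p
        xc = x[:, : h2 * p, : w2 * p, :]
        xr = xc.reshape(n, h2, p, w2, p, c).transpose(0, 1, 3, 5, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(n, h2, w2, c, p * p)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        self._cache = None
        p = self.pool
        n, h, w, c = xshape
        h2, w2 = h // p, w // p
        scat = np.zeros((n, h2, w2, c, p * p), dtype=dy.dtype)
        np.put_along_axis(scat, idx[..., None], dy[..., None], axis=-1)
        scat = scat.reshape(n, h2, w2, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(xshape, dtype=dy.dtype)
        dx[:, : h2 * p, : w2 * p, :] = scat.reshape(n, h2 * p, w2 * p, c)
        return dx


class Upsample2D(Layer):
    """Nearest-neighbour 2x upsampling (the decoder's inverse of pooling)."""

    def __init__(self, rate: int = 2):
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        r = self.rate
        return x.repeat(r, axis=1).repeat(r, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        r = self.rate
        n, h, w, c = dy.shape
        return dy.reshape(n, h // r, r, w // r, r, c).sum(axis=(2, 4))


# -- batch normalisation -----------------------------------------------------

class BatchNorm(Layer):
    """Per-channel batch normalisation (trailing axis), with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = _EPS):
        self.gamma = Param(np.ones(channels, dtype=np.float32), name="bn_gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), name="bn_beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = (self.gamma, self.beta)
        self._cache = None
        self._calibration_count: int | None = None

    def start_calibration(self) -> None:
        """Begin re-estimating running stats as exact averages of batch moments."""
        self._calibration_count = 0

    def stop_calibration(self) -> None:
        self._calibration_count = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self._calibration_count is not None:
                # cumulative moving average over calibration batches
                self._calibration_count += 1
                m = 1.0 - 1.0 / self._calibration_count
            else:
                m = self.momentum
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mean).astype(np.float32)
            self.running_var = (m * self.running_var
                                + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            m = x.size // x.shape[-1]
            self._cache = (xhat, inv_std, m, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m, axes = self._cache
        self._cache = None
        self.gamma.grad[...] = (dy * xhat).sum(axis=axes)
        self.beta.grad[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx.astype(np.float32)


def batch_normalize(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                    eps: float = _EPS) -> np.ndarray:
    """Functional training-mode batch normalisation over the trailing axis."""
    axes = tuple(range(x.ndim - 1))
    mean = x.mean(axis=axes)
    var = x.var(axis=axes)
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


# -- dropout / dense / flatten -----------------------------------------------

class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = self.rng or np.random.default_rng(0)
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, activation: str = "linear",
                 alpha: float = 0.3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(glorot_uniform(rng, (in_features, units), in_features, units),
                       decay=True, name="dense_w")
        self.b = Param(np.zeros(units, dtype=np.float32), name="dense_b")
        self.activation = activation
        self.alpha = alpha
        self.params = (self.w, self.b)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x @ self.w.value + self.b.value
        a = _activate(z, self.activation, self.alpha)
        if training:
            self._cache = (x, z, a)
        return a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, a = self._cache
        self._cache = None
        dz = dy * _activate_grad(z, a, self.activation, self.alpha)
        self.w.grad[...] = x.T @ dz
        self.b.grad[...] = dz.sum(axis=0)
        return dz @ self.w.value.T
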