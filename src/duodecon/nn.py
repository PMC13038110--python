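"""Minimal NumPy neural-network primitives with hand-written backpropagation.

Every layer exposes ``forward(x, train)`` and ``backward(gy)``; parameters and
their gradients live in ``params`` / ``grads`` dicts keyed by name.
Sequence-valued activations use the channels-last convention
``(batch, length, channels)``, which lets 1-D convolutions run as single
matrix products over stacked shifted views with no transposition copies;
dense layers use ``(batch, features)``.  All arithmetic runs in the dtype of
the parameters (float32 by default, float64 for gradient checking).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Layer",
    "Linear",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "MaxPool1d",
    "SiLU",
    "ReLU",
    "Softmax",
    "Adam",
    "FlatAdam",
    "collect_params",
    "collect_grads",
]


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params["W"] = _uniform_init(rng, (n_in, n_out), n_in, dtype)
        self.params["b"] = _uniform_init(rng, (n_out,), n_in, dtype)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy):
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


class Conv1d(Layer):
    """Same-padding, stride-1 1-D convolution on (B, L, C); odd kernel only.

    The kernel is stored as a 2-D ``(k * c_in, c_out)`` matrix (tap-major), so
    both the forward pass and both backward products are plain GEMMs over a
    patch matrix assembled from k shifted views of the zero-padded input.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same-padding convolution")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k
        self.params["W"] = _uniform_init(rng, (k * c_in, c_out), fan_in, dtype)
        self.params["b"] = _uniform_init(rng, (c_out,), fan_in, dtype)

    @staticmethod
    def _cols(x: np.ndarray, k: int) -> np.ndarray:
        # (B, L, C) -> (B*L, k*C): stack the k shifted windows channel-wise,
        # materialized in one pass from an overlapping strided view
        if k == 1:
            return x.reshape(-1, x.shape[2])
        b, l, c = x.shape
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        sb, sl, sc = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, shape=(b, l, k, c), strides=(sb, sl, sl, sc), writeable=False)
        return view.reshape(b * l, k * c)

    def forward(self, x, train=False):
        b, l, _ = x.shape
        self._cols_x = self._cols(x, self.k)
        y = self._cols_x @ self.params["W"] + self.params["b"]
        return y.reshape(b, l, self.c_out)

    def backward(self, gy):
        b, l, _ = gy.shape
        g2 = gy.reshape(b * l, self.c_out)
        self.grads["W"] = self._cols_x.T @ g2
        self.grads["b"] = g2.sum(axis=0)
        # dx = correlation of gy with the tap-reversed, channel-swapped kernel
        w3 = self.params["W"].reshape(self.k, self.c_in, self.c_out)
        w_rot = w3[::-1].transpose(0, 2, 1).reshape(self.k * self.c_out, self.c_in)
        dx = self._cols(gy, self.k) @ w_rot
        return dx.reshape(b, l, self.c_in)


class ConvTranspose1d(Layer):
    """Kernel-2, stride-2 transposed convolution on (B, L, C): doubles length."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 2
        self.params["W"] = _uniform_init(rng, (c_in, 2 * c_out), fan_in, dtype)
        self.params["b"] = _uniform_init(rng, (c_out,), fan_in, dtype)

    def forward(self, x, train=False):
        b, l, _ = x.shape
        self._x2 = x.reshape(b * l, self.c_in)
        y = self._x2 @ self.params["W"]  # (B*L, 2*c_out), tap-major
        return y.reshape(b, 2 * l, self.c_out) + self.params["b"]

    def backward(self, gy):
        b, l2, _ = gy.shape
        g2 = gy.reshape(b * (l2 // 2), 2 * self.c_out)
        self.grads["W"] = self._x2.T @ g2
        self.grads["b"] = gy.sum(axis=(0, 1))
        dx = g2 @ self.params["W"].T
        return dx.reshape(b, l2 // 2, self.c_in)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (B, L, C) or (B, C).

    Uses batch statistics during training and exponentially averaged running
    statistics at inference, so inference is deterministic per sample.
    """

    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def forward(self, x, train=False):
        x2 = x.reshape(-1, x.shape[-1])
        if train:
            mu = x2.mean(axis=0)
            xc = x2 - mu
            var = np.einsum("nc,nc->c", xc, xc) / xc.shape[0]
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.astype(np.float64)
            self.running_var = (1 - m) * self.running_var + m * var.astype(np.float64)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
            xc = x2 - mu
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xc *= inv_std
        xhat = xc
        self._train = train
        self._xhat, self._inv_std = xhat, inv_std
        y = xhat * self.params["gamma"] + self.params["beta"]
        return y.reshape(x.shape)

    def backward(self, gy):
        shape = gy.shape
        g2 = gy.reshape(-1, shape[-1])
        self.grads["gamma"] = (g2 * self._xhat).sum(axis=0)
        self.grads["beta"] = g2.sum(axis=0)
        scale = self.params["gamma"] * self._inv_std
        if not self._train:
            return (g2 * scale).reshape(shape)
        n = g2.shape[0]
        mean_gy = g2.mean(axis=0)
        mean_gy_xhat = (g2 * self._xhat).sum(axis=0) / n
        dx = scale * (g2 - mean_gy - self._xhat * mean_gy_xhat)
        return dx.reshape(shape)


class MaxPool1d(Layer):
    """Non-overlapping max pooling with window 2 on (B, L, C): halves length."""

    def forward(self, x, train=False):
        b, l, c = x.shape
        xr = x.reshape(b, l // 2, 2, c)
        self._idx = xr.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, gy):
        b, l, c = self._in_shape
        gx = np.zeros((b, l // 2, 2, c), dtype=gy.dtype)
        np.put_along_axis(gx, self._idx[:, :, None, :], gy[:, :, None, :], axis=2)
        return gx.reshape(b, l, c)


class SiLU(Layer):
    def forward(self, x, train=False):
        s = expit(x)
        self._x, self._s = x, s
        return x * s

    def backward(self, gy):
        s = self._s
        return gy * (s * (1.0 + self._x * (1.0 - s)))


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, gy):
        return gy * self._mask


class Softmax(Layer):
    """Softmax over the last axis with the full Jacobian in backward."""

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, gy):
        y = self._y
        return y * (gy - (gy * y).sum(axis=-1, keepdims=True))


class Adam:
    """Reference Adam over a flat {path: array} parameter mapping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class FlatAdam:
    """Adam over layer parameters rebased onto one contiguous buffer.

    Rebasing lets the moment updates run as a handful of vectorized passes
    over single large arrays instead of dozens of small ones.  The layers'
    ``params`` entries are replaced by views into the buffer, so in-place
    updates are visible to the layers immediately.
    """

    def __init__(self, named_layers: dict[str, Layer], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.index: dict[str, tuple[slice, tuple[int, ...]]] = {}
        total = 0
        entries = []
        for lname, layer in named_layers.items():
            for pname, arr in layer.params.items():
                key = f"{lname}.{pname}"
                sl = slice(total, total + arr.size)
                self.index[key] = (sl, arr.shape)
                entries.append((layer, pname, key, arr))
                total += arr.size
        dtype = entries[0][3].dtype if entries else np.float32
        self.flat = np.empty(total, dtype=dtype)
        for layer, pname, key, arr in entries:
            sl, shape = self.index[key]
            self.flat[sl] = arr.ravel()
            layer.params[pname] = self.flat[sl].reshape(shape)
        self.g = np.zeros_like(self.flat)
        self.m = np.zeros_like(self.flat)
        self.v = np.zeros_like(self.flat)
        self._tmp = np.empty_like(self.flat)

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for key, (sl, _) in self.index.items():
            np.copyto(self.g[sl], grads[key].reshape(-1))
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        g, m, v, tmp = self.g, self.m, self.v, self._tmp
        # m += (1-b1)(g-m); v += (1-b2)(g^2-v); flat -= lr*(m/b1t)/(sqrt(v/b2t)+eps)
        np.subtract(g, m, out=tmp)
        tmp *= (1.0 - self.b1)
        m += tmp
        np.multiply(g, g, out=tmp)
        tmp -= v
        tmp *= (1.0 - self.b2)
        v += tmp
        np.divide(v, b2t, out=tmp)
        np.sqrt(tmp, out=tmp)
        tmp += self.eps
        np.divide(m, tmp, out=tmp)
        tmp *= self.lr / b1t
        self.flat -= tmp


def collect_params(named_layers: dict[str, Layer]) -> dict[str, np.ndarray]:
    """Flatten layer parameters into a single {``layer.param``: array} dict."""
    flat: dict[str, np.ndarray] = {}
    for name, layer in named_layers.items():
        for pname, arr in layer.params.items():
            flat[f"{name}.{pname}"] = arr
    return flat


def collect_grads(named_layers: dict[str, Layer]) -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {}
    for name, layer in named_layers.items():
        for pname, arr in layer.grads.items():
            flat[f"{name}.{pname}"] = arr
    return flat
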