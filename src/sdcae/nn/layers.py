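"""Trainable layer objects with explicit forward/backward passes.

Thin stateful wrappers around :mod:`sdcae.nn.functional`: each layer caches
what its backward pass needs, accumulates parameter gradients into
``Param.grad``, and returns the gradient w.r.t. its input.  Weight
initialization is Glorot-uniform from a caller-supplied seeded generator,
so whole models are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .functional import ShapeError

__all__ = [
    "Param", "Layer", "Sequential",
    "Conv2DSame", "ReLU", "Sigmoid", "BatchNorm", "MaxPool", "Upsample",
    "Flatten", "Dense", "Dropout", "SqueezeWidth", "BiLSTM", "TimeAverage",
]


class Param:
    """One trainable tensor with its accumulated gradient."""

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:
        return f"Param({self.name}, shape={self.value.shape})"


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Conv2DSame(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 rng: np.random.Generator, name: str = "conv"):
        kh, kw = kernel
        fan_in, fan_out = kh * kw * c_in, kh * kw * c_out
        self.w = Param(f"{name}.w", glorot(rng, (kh, kw, c_in, c_out), fan_in, fan_out))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return F.conv2d_same(x, self.w.value, self.b.value)

    def backward(self, dy):
        dx, dw, db = F.conv2d_same_backward(self._x, self.w.value, dy)
        self.w.grad += dw
        self.b.grad += db
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._x = x
        return F.relu(x)

    def backward(self, dy):
        return F.drelu(self._x, dy)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = F.sigmoid(x)
        return self._y

    def backward(self, dy):
        return F.dsigmoid(self._y, dy)


class BatchNorm(Layer):
    def __init__(self, n_features: int, eps: float = 1e-3, momentum: float = 0.9,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(n_features))
        self.beta = Param(f"{name}.beta", np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        y, self._cache = F.batchnorm(
            x, self.gamma.value, self.beta.value,
            self.running_mean, self.running_var,
            eps=self.eps, momentum=self.momentum, train=train,
        )
        return y

    def backward(self, dy):
        dx, dgamma, dbeta = F.batchnorm_backward(dy, self._cache)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        return dx


class MaxPool(Layer):
    def __init__(self, window: tuple[int, int]):
        self.window = tuple(window)

    def forward(self, x, train=True):
        self._x = x
        self._y = F.maxpool(x, self.window)
        return self._y

    def backward(self, dy):
        return F.maxpool_backward(self._x, self._y, dy, self.window)


class Upsample(Layer):
    def __init__(self, factor: tuple[int, int]):
        self.factor = tuple(factor)

    def forward(self, x, train=True):
        return F.upsample_nearest(x, self.factor)

    def backward(self, dy):
        return F.upsample_nearest_backward(dy, self.factor)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.w = Param(f"{name}.w", glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(f"{name}.b", np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout, active in training mode only."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class SqueezeWidth(Layer):
    """(B, T, 1, C) -> (B, T, C): latent maps reshaped as a sequence."""

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[2] != 1:
            raise ShapeError(f"expected (B, T, 1, C) latent, got {x.shape}")
        self._shape = x.shape
        return x[:, :, 0, :]

    def backward(self, dy):
        return dy[:, :, None, :]


class _LSTMDirection:
    """One direction of an LSTM over a (B, T, F) sequence, with full BPTT."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator, name: str):
        shape = (units, units + n_in)
        fi, fo = units + n_in, units
        self.p = {
            f"W_{g}": Param(f"{name}.W_{g}", glorot(rng, shape, fi, fo))
            for g in ("f", "i", "o", "c")
        }
        for g in ("f", "i", "o", "c"):
            bias = np.zeros(units)
            if g == "f":
                bias += 1.0  # standard unit forget-gate bias
            self.p[f"b_{g}"] = Param(f"{name}.b_{g}", bias)
        self.units = units

    def params(self):
        return list(self.p.values())

    def _values(self):
        return {k: v.value for k, v in self.p.items()}

    def forward(self, x):
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._cache = []
        h_seq = np.empty((B, T, u))
        vals = self._values()
        for t in range(T):
            a = np.concatenate([h, x[:, t, :]], axis=1)
            f = F.sigmoid(a @ vals["W_f"].T + vals["b_f"])
            i = F.sigmoid(a @ vals["W_i"].T + vals["b_i"])
            o = F.sigmoid(a @ vals["W_o"].T + vals["b_o"])
            ct = np.tanh(a @ vals["W_c"].T + vals["b_c"])
            c_new = f * c + i * ct
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((a, f, i, o, ct, c, tanh_c))
            h, c = h_new, c_new
            h_seq[:, t, :] = h
        return h_seq

    def backward(self, dh_seq):
        B, T, _ = self._x.shape
        u = self.units
        vals = self._values()
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        grads = {k: np.zeros_like(v) for k, v in vals.items()}
        for t in range(T - 1, -1, -1):
            a, f, i, o, ct, c_prev, tanh_c = self._cache[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            df = dc * c_prev
            di = dc * ct
            dct = dc * i
            dc_next = dc * f
            dzf = df * f * (1 - f)
            dzi = di * i * (1 - i)
            dzo = do * o * (1 - o)
            dzc = dct * (1 - ct ** 2)
            da = dzf @ vals["W_f"] + dzi @ vals["W_i"] + dzo @ vals["W_o"] + dzc @ vals["W_c"]
            for g, dz in (("f", dzf), ("i", dzi), ("o", dzo), ("c", dzc)):
                grads[f"W_{g}"] += dz.T @ a
                grads[f"b_{g}"] += dz.sum(axis=0)
            dh_next = da[:, :u]
            dx[:, t, :] = da[:, u:]
        for k, g in grads.items():
            self.p[k].grad += g
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: per-step forward/backward outputs concatenated.

    Input (B, T, F) -> output (B, T, 2 * units); the first half of the
    feature axis is the forward pass, the second half the backward pass
    aligned to original time order.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator, name: str = "bilstm"):
        if units < 1:
            raise ShapeError("BiLSTM units must be >= 1")
        self.fwd = _LSTMDirection(n_in, units, rng, f"{name}.fwd")
        self.bwd = _LSTMDirection(n_in, units, rng, f"{name}.bwd")

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, x, train=True):
        if x.ndim != 3 or x.shape[1] < 1:
            raise ShapeError(f"BiLSTM expects a non-empty (B, T, F) sequence, got {x.shape}")
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy):
        u = self.fwd.units
        dxf = self.fwd.backward(dy[:, :, :u])
        dxb = self.bwd.backward(dy[:, ::-1, u:])[:, ::-1, :]
        return dxf + dxb


class TimeAverage(Layer):
    """(B, T, F) -> (B, F): mean over the time axis."""

    def forward(self, x, train=True):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._T, axis=1) / self._T
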