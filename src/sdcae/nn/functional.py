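"""Numerical primitives for the seizure-detection networks.

Everything operates on float64 NumPy arrays in NHWC layout
(batch, time, channel-width, feature-maps).  Each operation exposes a
forward function and, where trainable, a matching backward function that
returns exact gradients; correctness is established against brute-force
scalar-loop oracles in the test suite and by finite differences on whole
models.
"""

from __future__ import annotations

import numpy as np

from ..types import SdcaeError

__all__ = [
    "ShapeError",
    "relu", "drelu", "sigmoid", "dsigmoid",
    "conv2d_same", "conv2d_same_backward",
    "maxpool", "maxpool_backward",
    "upsample_nearest", "upsample_nearest_backward",
    "batchnorm", "batchnorm_backward",
    "lstm_cell_step",
]


class ShapeError(SdcaeError, ValueError):
    """Array dimensions inconsistent with the operation's contract."""


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, max{0, x} elementwise."""
    return np.maximum(0.0, x)


def drelu(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * (x > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function 1 / (1 + exp(-x)), numerically stable both tails."""
    out = np.empty_like(np.asarray(x, dtype=np.float64))
    x = np.asarray(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def dsigmoid(y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Backward through sigmoid given its *output* y."""
    return dy * y * (1.0 - y)


# ---------------------------------------------------------------------------
# same-padded 2-D convolution, stride 1
# ---------------------------------------------------------------------------

def _same_pads(k: int) -> tuple[int, int]:
    # stride-1 'same': total padding k-1, split with the extra unit after
    total = k - 1
    before = total // 2
    return before, total - before


def conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stride-1 'same' convolution (cross-correlation, as in deep learning).

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).
    Output spatial size equals input size for any kernel.
    """
    if x.ndim != 4 or w.ndim != 4 or x.shape[3] != w.shape[2]:
        raise ShapeError(f"conv2d_same: incompatible shapes {x.shape} and {w.shape}")
    kh, kw = w.shape[:2]
    (pt, pb), (pl, pr) = _same_pads(kh), _same_pads(kw)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    B, H, W, _ = x.shape
    out = np.broadcast_to(b, (B, H, W, w.shape[3])).copy()
    for di in range(kh):
        for dj in range(kw):
            out += np.tensordot(xp[:, di: di + H, dj: dj + W, :], w[di, dj], axes=([3], [0]))
    return out


def conv2d_same_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of conv2d_same w.r.t. upstream dy."""
    kh, kw = w.shape[:2]
    (pt, pb), (pl, pr) = _same_pads(kh), _same_pads(kw)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    B, H, W, _ = x.shape
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, di: di + H, dj: dj + W, :]
            dw[di, dj] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, di: di + H, dj: dj + W, :] += np.tensordot(dy, w[di, dj], axes=([3], [1]))
    db = dy.sum(axis=(0, 1, 2))
    dx = dxp[:, pt: pt + H, pl: pl + W, :]
    return dx, dw, db


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def maxpool(x: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Non-overlapping max pooling; spatial dims must divide the window."""
    ph, pw = window
    B, H, W, C = x.shape
    if H % ph or W % pw:
        raise ShapeError(f"maxpool: shape ({H},{W}) not divisible by window {window}")
    return x.reshape(B, H // ph, ph, W // pw, pw, C).max(axis=(2, 4))


def maxpool_backward(x: np.ndarray, y: np.ndarray, dy: np.ndarray,
                     window: tuple[int, int]) -> np.ndarray:
    """Route dy to the maxima; exact ties share the gradient equally."""
    ph, pw = window
    y_up = np.repeat(np.repeat(y, ph, axis=1), pw, axis=2)
    dy_up = np.repeat(np.repeat(dy, ph, axis=1), pw, axis=2)
    mask = (x == y_up).astype(x.dtype)
    B, H, W, C = x.shape
    counts = mask.reshape(B, H // ph, ph, W // pw, pw, C).sum(axis=(2, 4))
    counts_up = np.repeat(np.repeat(counts, ph, axis=1), pw, axis=2)
    return mask * dy_up / counts_up


def upsample_nearest(x: np.ndarray, factor: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling: repeat rows/cols by the given factors."""
    fh, fw = factor
    return np.repeat(np.repeat(x, fh, axis=1), fw, axis=2)


def upsample_nearest_backward(dy: np.ndarray, factor: tuple[int, int]) -> np.ndarray:
    fh, fw = factor
    B, H, W, C = dy.shape
    if H % fh or W % fw:
        raise ShapeError(f"upsample backward: dy shape ({H},{W}) not divisible by {factor}")
    return dy.reshape(B, H // fh, fh, W // fw, fw, C).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    eps: float = 1e-3,
    momentum: float = 0.9,
    train: bool = True,
):
    """Per-feature batch normalization: gamma * (x - mu)/sqrt(var + eps) + beta.

    Features are the last axis; statistics reduce over all other axes.
    In train mode the mini-batch statistics are used and the running
    estimates updated in place (exponential moving average); in inference
    mode the running estimates are used.  Returns ``(y, cache)`` where
    cache feeds :func:`batchnorm_backward`.
    """
    axes = tuple(range(x.ndim - 1))
    if train:
        m = int(np.prod([x.shape[a] for a in axes]))
        if m < 2:
            raise ShapeError("batchnorm train mode needs an effective batch of >= 2")
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        running_mean *= momentum
        running_mean += (1 - momentum) * mu
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    y = gamma * xhat + beta
    cache = (xhat, inv_std, gamma, train)
    return y, cache


def batchnorm_backward(dy: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dgamma, dbeta) through batchnorm."""
    xhat, inv_std, gamma, train = cache
    axes = tuple(range(dy.ndim - 1))
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dxhat = dy * gamma
    if not train:
        return dxhat * inv_std, dgamma, dbeta
    m = np.prod([dy.shape[a] for a in axes])
    dx = (inv_std / m) * (m * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# LSTM cell
# ---------------------------------------------------------------------------

def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step on the concatenated state-input vector [h_{t-1}, x_t].

    Gates: f = sigma(W_f.[h,x] + b_f), i and o analogous,
    candidate c~ = tanh(W_c.[h,x] + b_c); then
    c_t = f * c_{t-1} + i * c~ and h_t = o * tanh(c_t).
    Weight matrices have shape (units, units + input_dim).
    """
    a = np.concatenate([h_prev, x_t], axis=-1)
    units = h_prev.shape[-1]
    for key in ("W_f", "W_i", "W_o", "W_c"):
        if params[key].shape != (units, a.shape[-1]):
            raise ShapeError(
                f"{key} shape {params[key].shape} != ({units}, {a.shape[-1]})"
            )
    f = sigmoid(a @ params["W_f"].T + params["b_f"])
    i = sigmoid(a @ params["W_i"].T + params["b_i"])
    o = sigmoid(a @ params["W_o"].T + params["b_o"])
    c_tilde = np.tanh(a @ params["W_c"].T + params["b_c"])
    c_t = f * c_prev + i * c_tilde
    h_t = o * np.tanh(c_t)
    return h_t, c_t
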