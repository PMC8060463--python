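"""Brute-force scalar-loop oracles, independent of the package's vectorized
implementations.  Deliberately naive: plain Python loops and explicit
index arithmetic only."""

import math

import numpy as np


def conv2d_same_oracle(x, w, b):
    """Direct sliding-window summation with 'same' zero padding, stride 1."""
    B, H, W, Cin = x.shape
    kh, kw, _, Cout = w.shape
    pt = (kh - 1) // 2
    pl = (kw - 1) // 2
    out = np.zeros((B, H, W, Cout))
    for n in range(B):
        for i in range(H):
            for j in range(W):
                for co in range(Cout):
                    acc = b[co]
                    for di in range(kh):
                        for dj in range(kw):
                            ii, jj = i + di - pt, j + dj - pl
                            if 0 <= ii < H and 0 <= jj < W:
                                for ci in range(Cin):
                                    acc += x[n, ii, jj, ci] * w[di, dj, ci, co]
                    out[n, i, j, co] = acc
    return out


def maxpool_oracle(x, window):
    ph, pw = window
    B, H, W, C = x.shape
    out = np.empty((B, H // ph, W // pw, C))
    for n in range(B):
        for i in range(H // ph):
            for j in range(W // pw):
                for c in range(C):
                    vals = [x[n, i * ph + a, j * pw + b, c]
                            for a in range(ph) for b in range(pw)]
                    out[n, i, j, c] = max(vals)
    return out


def batchnorm_oracle(x, gamma, beta, eps):
    """Train-mode batch norm over all axes but the last, per feature."""
    out = np.empty_like(x)
    flat = x.reshape(-1, x.shape[-1])
    for c in range(x.shape[-1]):
        col = flat[:, c]
        mu = sum(col) / len(col)
        var = sum((v - mu) ** 2 for v in col) / len(col)
        out[..., c] = gamma[c] * (x[..., c] - mu) / math.sqrt(var + eps) + beta[c]
    return out


def _sig(v):
    return 1.0 / (1.0 + math.exp(-v))


def lstm_sequence_oracle(x_seq, params):
    """Element-by-element LSTM forward over a (T, F) sequence, one sample."""
    T, F = x_seq.shape
    u = params["b_f"].shape[0]
    h = [0.0] * u
    c = [0.0] * u
    h_seq = np.empty((T, u))
    for t in range(T):
        a = list(h) + list(x_seq[t])
        new_h = [0.0] * u
        new_c = [0.0] * u
        for k in range(u):
            zf = params["b_f"][k] + sum(params["W_f"][k][m] * a[m] for m in range(len(a)))
            zi = params["b_i"][k] + sum(params["W_i"][k][m] * a[m] for m in range(len(a)))
            zo = params["b_o"][k] + sum(params["W_o"][k][m] * a[m] for m in range(len(a)))
            zc = params["b_c"][k] + sum(params["W_c"][k][m] * a[m] for m in range(len(a)))
            f, i, o = _sig(zf), _sig(zi), _sig(zo)
            ct = math.tanh(zc)
            new_c[k] = f * c[k] + i * ct
            new_h[k] = o * math.tanh(new_c[k])
        h, c = new_h, new_c
        h_seq[t] = h
    return h_seq


def bce_oracle(y, p, eps=1e-7):
    total = 0.0
    for yi, pi in zip(y, p):
        pi = min(max(pi, eps), 1 - eps)
        total += yi * math.log(pi) + (1 - yi) * math.log(1 - pi)
    return -total / len(y)


def mse_oracle(x, x_hat):
    """Mean over segments of per-segment mean squared error, double loop."""
    N = x.shape[0]
    total = 0.0
    for n in range(N):
        seg = 0.0
        a, b = x[n].reshape(-1), x_hat[n].reshape(-1)
        for j in range(a.size):
            seg += (a[j] - b[j]) ** 2
        total += seg / a.size
    return total / N


def metrics_oracle(tp, tn, fp, fn):
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    prec = 100.0 * tp / (tp + fp)
    f1 = 2.0 * prec * sens / (prec + sens)
    return acc, sens, spec, prec, f1


def kruskal_oracle_h(groups):
    """Hand-ranked H with tie correction."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[k] = avg
        i = j
    rank_sums = [0.0] * len(groups)
    for idx, (_, gi) in enumerate(pooled):
        rank_sums[gi] += ranks[idx]
    h = 12.0 / (n * (n + 1)) * sum(
        rs ** 2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        ties += t ** 3 - t
        i = j
    correction = 1.0 - ties / (n ** 3 - n)
    return h / correction
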