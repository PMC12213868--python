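"""Independent nested-loop reference implementations used as test oracles.

Written deliberately as explicit Python loops over output positions so they
share no code path with the vectorised layers they check.
"""

from __future__ import annotations

import math

import numpy as np


def loop_conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 convolution, NHWC, weight (k, k, cin, cout)."""
    n, h, w, cin = x.shape
    k = weight.shape[0]
    p = k // 2
    cout = weight.shape[3]
    out = np.zeros((n, h, w, cout))
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for f in range(cout):
                    acc = bias[f]
                    for di in range(k):
                        for dj in range(k):
                            ii, jj = i + di - p, j + dj - p
                            if 0 <= ii < h and 0 <= jj < w:
                                for c in range(cin):
                                    acc += x[b, ii, jj, c] * weight[di, dj, c, f]
                    out[b, i, j, f] = acc
    return out


def loop_depthwise(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded depthwise convolution, weight (k, k, c)."""
    n, h, w, c = x.shape
    k = weight.shape[0]
    p = k // 2
    out = np.zeros_like(x, dtype=np.float64)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for ch in range(c):
                    acc = bias[ch]
                    for di in range(k):
                        for dj in range(k):
                            ii, jj = i + di - p, j + dj - p
                            if 0 <= ii < h and 0 <= jj < w:
                                acc += x[b, ii, jj, ch] * weight[di, dj, ch]
                    out[b, i, j, ch] = acc
    return out


def loop_maxpool2x2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    out = np.zeros((n, h // 2, w // 2, c))
    for b in range(n):
        for i in range(h // 2):
            for j in range(w // 2):
                for ch in range(c):
                    out[b, i, j, ch] = max(
                        x[b, 2 * i, 2 * j, ch],
                        x[b, 2 * i, 2 * j + 1, ch],
                        x[b, 2 * i + 1, 2 * j, ch],
                        x[b, 2 * i + 1, 2 * j + 1, ch],
                    )
    return out


def loop_layernorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Per-position normalisation across channels."""
    n, h, w, c = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                row = [x[b, i, j, ch] for ch in range(c)]
                mu = sum(row) / c
                var = sum((v - mu) ** 2 for v in row) / c
                for ch in range(c):
                    out[b, i, j, ch] = gamma[ch] * (row[ch] - mu) / math.sqrt(var + eps) + beta[ch]
    return out


def loop_batchnorm_train(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Training-mode batch normalisation over (batch, height, width)."""
    n, h, w, c = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    cnt = n * h * w
    for ch in range(c):
        vals = [x[b, i, j, ch] for b in range(n) for i in range(h) for j in range(w)]
        mu = sum(vals) / cnt
        var = sum((v - mu) ** 2 for v in vals) / cnt
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    out[b, i, j, ch] = gamma[ch] * (x[b, i, j, ch] - mu) / math.sqrt(var + eps) + beta[ch]
    return out


def loop_gelu(x: np.ndarray) -> np.ndarray:
    flat = np.zeros(x.size)
    for idx, v in enumerate(x.ravel()):
        flat[idx] = v * 0.5 * (1.0 + math.erf(v / math.sqrt(2.0)))
    return flat.reshape(x.shape)


def loop_se(x, w_reduce, b_reduce, w_expand, b_expand):
    """Squeeze-and-excitation: per-channel mean, two affine maps, sigmoid gate."""
    n, h, w, c = x.shape
    r = w_reduce.shape[1]
    out = np.zeros_like(x, dtype=np.float64)
    for b in range(n):
        pooled = [sum(x[b, i, j, ch] for i in range(h) for j in range(w)) / (h * w) for ch in range(c)]
        hidden = []
        for u in range(r):
            acc = b_reduce[u]
            for ch in range(c):
                acc += pooled[ch] * w_reduce[ch, u]
            hidden.append(max(acc, 0.0))
        gates = []
        for ch in range(c):
            acc = b_expand[ch]
            for u in range(r):
                acc += hidden[u] * w_expand[u, ch]
            gates.append(1.0 / (1.0 + math.exp(-acc)))
        for i in range(h):
            for j in range(w):
                for ch in range(c):
                    out[b, i, j, ch] = x[b, i, j, ch] * gates[ch]
    return out


def loop_attention_head(tokens: np.ndarray, wq: np.ndarray, wk: np.ndarray, wv: np.ndarray) -> np.ndarray:
    """One attention head: scores, scaled softmax rows, weighted value sum.

    ``tokens`` is (t, d); projections are (d, dh).
    """
    t, d = tokens.shape
    dh = wq.shape[1]
    q = [[sum(tokens[i][c] * wq[c][u] for c in range(d)) for u in range(dh)] for i in range(t)]
    k = [[sum(tokens[i][c] * wk[c][u] for c in range(d)) for u in range(dh)] for i in range(t)]
    v = [[sum(tokens[i][c] * wv[c][u] for c in range(d)) for u in range(dh)] for i in range(t)]
    out = np.zeros((t, dh))
    for i in range(t):
        scores = [sum(q[i][u] * k[j][u] for u in range(dh)) / math.sqrt(dh) for j in range(t)]
        mx = max(scores)
        exps = [math.exp(s - mx) for s in scores]
        total = sum(exps)
        attn = [e / total for e in exps]
        for u in range(dh):
            out[i, u] = sum(attn[j] * v[j][u] for j in range(t))
    return out


def loop_confusion(p_true: np.ndarray, q_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = tn = fp = fn = 0
    for a, b in zip(p_true.ravel(), q_pred.ravel()):
        if a == 1 and b == 1:
            tp += 1
        elif a == 0 and b == 0:
            tn += 1
        elif a == 0 and b == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def loop_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise positive-negative comparison statistic, ties count one half."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
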