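"""Stateless tensor functions."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Gaussian Error Linear Unit, exact form ``x * Phi(x)``.

    Uses the Gaussian CDF rather than the tanh approximation.
    """
    return (x * ndtr(x)).astype(x.dtype, copy=False)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """Derivative of the exact GeLU: ``Phi(x) + x * phi(x)``."""
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * np.square(x))
    return (ndtr(x) + x * pdf).astype(x.dtype, copy=False)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax along ``axis`` with max-subtraction for stability."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def extract_patches(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding ``k x k`` windows of a same-padded NHWC tensor.

    Returns a view-backed array of shape ``(n, h, w, c, k, k)`` where entry
    ``[n, i, j]`` holds the receptive field of output pixel ``(i, j)``.
    """
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    return np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
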