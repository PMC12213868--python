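"""Scaled dot-product multi-head self-attention over token sequences."""

from __future__ import annotations

import numpy as np

from ..exceptions import ConfigurationError
from .functional import softmax
from .layers import Layer, Parameter, glorot_uniform


class MultiHeadSelfAttention(Layer):
    """Multi-head self-attention on ``(batch, tokens, d_model)`` sequences.

    Each head linearly projects the tokens to queries, keys and values of
    width ``d_model / heads``, scores query-key similarity scaled by
    ``1 / sqrt(d_head)``, normalises each row with softmax and aggregates the
    values. Head outputs are concatenated back to ``d_model``. The projections
    are bias-free; the output 1x1 projection and residual belong to the
    calling block.

    Attributes
    ----------
    last_attention
        Row-stochastic attention weights ``(batch, heads, tokens, tokens)``
        from the most recent forward pass.
    """

    def __init__(self, d_model: int, heads: int, rng, dtype=np.float32, name="mha"):
        if d_model % heads != 0:
            raise ConfigurationError(f"d_model={d_model} is not divisible by heads={heads}")
        self.d_model = d_model
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Parameter(f"{name}.wq", glorot_uniform(rng, (d_model, d_model), d_model, d_model, dtype))
        self.wk = Parameter(f"{name}.wk", glorot_uniform(rng, (d_model, d_model), d_model, d_model, dtype))
        self.wv = Parameter(f"{name}.wv", glorot_uniform(rng, (d_model, d_model), d_model, d_model, dtype))
        self.last_attention: np.ndarray | None = None
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        return x.reshape(n, t, self.heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x, training=True):
        q = self._split(x @ self.wq.value)
        k = self._split(x @ self.wk.value)
        v = self._split(x @ self.wv.value)
        scale = 1.0 / np.sqrt(self.d_head)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax(scores, axis=-1)
        out = self._merge(attn @ v)
        self.last_attention = attn
        self._cache = (x, q, k, v, attn, scale)
        return out.astype(x.dtype, copy=False)

    def backward(self, dout):
        x, q, k, v, attn, scale = self._cache
        do = self._split(dout)
        dattn = do @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ do
        # softmax backward per row
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqf, dkf, dvf = (self._merge(a) for a in (dq, dk, dv))
        xf = x.reshape(-1, self.d_model)
        self.wq.grad += xf.T @ dqf.reshape(-1, self.d_model)
        self.wk.grad += xf.T @ dkf.reshape(-1, self.d_model)
        self.wv.grad += xf.T @ dvf.reshape(-1, self.d_model)
        return dqf @ self.wq.value.T + dkf @ self.wk.value.T + dvf @ self.wv.value.T
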