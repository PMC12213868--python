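"""Trainable layers with explicit forward/backward passes.

Conventions:

* activations are NHWC (``Dense`` accepts any leading shape);
* spatial convolutions use same-padding, stride 1;
* weights are Glorot-uniform initialised from a caller-supplied
  ``numpy.random.Generator`` so a single seed fixes every parameter;
* ``backward`` accumulates into ``Parameter.grad`` and returns the input
  gradient, enabling arbitrary DAG wiring by the blocks above.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ShapeError
from .functional import extract_patches, gelu_grad, sigmoid, gelu as _gelu


class Parameter:
    """A named trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base class: parameter bookkeeping plus the forward/backward contract."""

    def params(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.forward(x, training=training)


class Conv2d(Layer):
    """``k x k`` convolution, stride 1, same padding, NHWC."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, dtype=np.float32, name="conv"):
        k = int(kernel_size)
        fan_in = k * k * in_channels
        fan_out = k * k * out_channels
        self.k = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(
            f"{name}.weight", glorot_uniform(rng, (k, k, in_channels, out_channels), fan_in, fan_out, dtype)
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels, dtype=dtype))
        self._x = None

    def forward(self, x, training=True):
        if x.shape[-1] != self.in_channels:
            raise ShapeError(
                f"conv expects {self.in_channels} input channels, got tensor of shape {x.shape} "
                f"against kernel {self.weight.value.shape}"
            )
        self._x = x
        win = extract_patches(x, self.k)
        out = np.tensordot(win, self.weight.value, axes=([3, 4, 5], [2, 0, 1]))
        out += self.bias.value
        return out.astype(x.dtype, copy=False)

    def backward(self, dout):
        x = self._x
        n, h, w, _ = x.shape
        k, p = self.k, self.k // 2
        win = extract_patches(x, k)
        dw = np.tensordot(win, dout, axes=([0, 1, 2], [0, 1, 2]))  # (c, k, k, f)
        self.weight.grad += dw.transpose(1, 2, 0, 3)
        self.bias.grad += dout.sum(axis=(0, 1, 2))
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_channels), dtype=dout.dtype)
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dout @ wv[i, j].T
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class DepthwiseConv2d(Layer):
    """Per-channel ``k x k`` convolution (spatial mixing, no channel mixing)."""

    def __init__(self, channels, kernel_size, rng, dtype=np.float32, name="dwconv"):
        k = int(kernel_size)
        self.k = k
        self.channels = channels
        self.weight = Parameter(f"{name}.weight", glorot_uniform(rng, (k, k, channels), k * k, k * k, dtype))
        self.bias = Parameter(f"{name}.bias", np.zeros(channels, dtype=dtype))
        self._x = None

    def forward(self, x, training=True):
        if x.shape[-1] != self.channels:
            raise ShapeError(
                f"depthwise conv expects {self.channels} channels, got shape {x.shape} "
                f"against kernel {self.weight.value.shape}"
            )
        self._x = x
        win = extract_patches(x, self.k)
        out = np.einsum("nhwcij,ijc->nhwc", win, self.weight.value, optimize=True)
        out += self.bias.value
        return out.astype(x.dtype, copy=False)

    def backward(self, dout):
        x = self._x
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        win = extract_patches(x, k)
        self.weight.grad += np.einsum("nhwcij,nhwc->ijc", win, dout, optimize=True)
        self.bias.grad += dout.sum(axis=(0, 1, 2))
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dout * wv[i, j]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ConvTranspose2d2x2(Layer):
    """2x2 transposed convolution with stride 2: doubles height and width."""

    def __init__(self, in_channels, out_channels, rng, dtype=np.float32, name="convT"):
        fan_in, fan_out = 4 * in_channels, 4 * out_channels
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(
            f"{name}.weight", glorot_uniform(rng, (2, 2, in_channels, out_channels), fan_in, fan_out, dtype)
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels, dtype=dtype))
        self._x = None

    def forward(self, x, training=True):
        if x.shape[-1] != self.in_channels:
            raise ShapeError(f"transposed conv expects {self.in_channels} channels, got shape {x.shape}")
        self._x = x
        n, h, w, _ = x.shape
        t = np.tensordot(x, self.weight.value, axes=([3], [2]))  # (n, h, w, 2, 2, f)
        out = t.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, self.out_channels)
        out = out + self.bias.value
        return out.astype(x.dtype, copy=False)

    def backward(self, dout):
        x = self._x
        n, h, w, _ = x.shape
        f = self.out_channels
        dt = dout.reshape(n, h, 2, w, 2, f).transpose(0, 1, 3, 2, 4, 5)  # (n, h, w, 2, 2, f)
        dw = np.tensordot(x, dt, axes=([0, 1, 2], [0, 1, 2]))  # (c, 2, 2, f)
        self.weight.grad += dw.transpose(1, 2, 0, 3)
        self.bias.grad += dout.sum(axis=(0, 1, 2))
        return np.tensordot(dt, self.weight.value, axes=([3, 4, 5], [0, 1, 3]))


class BatchNorm2d(Layer):
    """Batch normalisation over (batch, height, width) per channel.

    Training mode uses batch statistics and updates exponential running
    moments (momentum 0.99); inference mode uses the running moments.
    """

    def __init__(self, channels, momentum=0.99, eps=1e-3, dtype=np.float32, name="bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, training=True):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1.0 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var + (1.0 - m) * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivstd
        self._cache = (xhat, ivstd, training, x.shape[0] * x.shape[1] * x.shape[2])
        return (self.gamma.value * xhat + self.beta.value).astype(x.dtype, copy=False)

    def backward(self, dout):
        xhat, ivstd, training, n = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma.value
        if not training:
            return dxhat * ivstd
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (ivstd / n) * (n * dxhat - s1 - xhat * s2)


class ChannelLayerNorm(Layer):
    """Layer normalisation across channels at each spatial position (eps 1e-6)."""

    def __init__(self, channels, eps=1e-6, dtype=np.float32, name="ln"):
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self._cache = None

    def forward(self, x, training=True):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivstd
        self._cache = (xhat, ivstd, x.shape[-1])
        return (self.gamma.value * xhat + self.beta.value).astype(x.dtype, copy=False)

    def backward(self, dout):
        xhat, ivstd, c = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
        self.beta.grad += dout.sum(axis=tuple(range(dout.ndim - 1)))
        dxhat = dout * self.gamma.value
        s1 = dxhat.sum(axis=-1, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=-1, keepdims=True)
        return (ivstd / c) * (c * dxhat - s1 - xhat * s2)


class Dense(Layer):
    """Affine map on the trailing axis."""

    def __init__(self, in_features, out_features, rng, dtype=np.float32, bias=True, name="dense"):
        self.in_features = in_features
        self.weight = Parameter(
            f"{name}.weight", glorot_uniform(rng, (in_features, out_features), in_features, out_features, dtype)
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features, dtype=dtype)) if bias else None
        self._x = None

    def forward(self, x, training=True):
        self._x = x
        out = x @ self.weight.value
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, dout):
        x2 = self._x.reshape(-1, self.in_features)
        d2 = dout.reshape(-1, dout.shape[-1])
        self.weight.grad += x2.T @ d2
        if self.bias is not None:
            self.bias.grad += d2.sum(axis=0)
        return dout @ self.weight.value.T


class GeLU(Layer):
    def __init__(self):
        self._x = None

    def forward(self, x, training=True):
        self._x = x
        return _gelu(x)

    def backward(self, dout):
        return dout * gelu_grad(self._x)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype, copy=False)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Sigmoid(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x, training=True):
        self._out = sigmoid(x)
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2. Rejects odd spatial sizes (no silent padding)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, training=True):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ShapeError(f"max pool requires even height/width, got {(h, w)}")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (n, h, w, c) = self._cache
        g = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
        np.put_along_axis(g, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return g.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)
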