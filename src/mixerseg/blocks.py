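"""Architectural building blocks of the hybrid mixer segmentation network.

The network is a five-stage U-shaped encoder-decoder for grayscale ultrasound
images. The pieces implemented here:

* ``CBGBlock`` — 3x3 convolution + batch norm + exact GeLU; the basic
  edge-extracting unit used throughout.
* ``SEBlock`` — squeeze-and-excitation channel recalibration: global average
  pool to one scalar per channel, a bottlenecked pair of dense maps
  (ReLU then sigmoid), and a broadcast multiply back onto the feature map.
* ``ECMBlock`` — enhanced ConvMixer: depthwise 3x3 spatial mixing, GeLU,
  batch norm, pointwise 1x1 channel mixing, GeLU, batch norm, SE
  recalibration, and a residual add of the block input.
* ``EncoderBlock`` — CBG (optionally followed by ECM) producing the
  full-resolution skip tensor, then 2x2 max pooling for the downsampled path.
* ``CEMHABlock`` — convolution-enhanced multi-head attention bottleneck: a
  CBG reduces the deepest encoder output to ``d_model`` channels, the spatial
  grid is flattened to tokens, multi-head self-attention mixes them, a 1x1
  projection maps back and a residual adds the pre-attention features.
* ``ECNBlock`` — enhanced ConvNeXt: depthwise 7x7, channel layer norm,
  1x1 back to the input width, residual add, 1x1 expansion by 4, GeLU,
  1x1 contraction, SE recalibration.
* ``DecoderBlock`` — 2x2 transposed convolution (doubling resolution,
  mapping to the skip width) + BN + GeLU, centre-crop of the skip,
  concatenation, refinement (ECN or CBG), and an optional residual add of
  the cropped skip.

All blocks operate on NHWC float tensors and are seeded deterministically via
the ``numpy.random.Generator`` passed at construction.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError, ShapeError
from .nn import (
    BatchNorm2d,
    ChannelLayerNorm,
    Conv2d,
    ConvTranspose2d2x2,
    Dense,
    DepthwiseConv2d,
    GeLU,
    Layer,
    MaxPool2x2,
    MultiHeadSelfAttention,
    ReLU,
    Sigmoid,
)


def center_crop(x: np.ndarray, height: int, width: int) -> np.ndarray:
    """Crop the central ``height x width`` window of an NHWC tensor.

    The crop is the identity when sizes already match; it cannot enlarge.
    The top-left offset is ``floor((size - target) / 2)`` per axis.
    """
    n, h, w, c = x.shape
    if h < height or w < width:
        raise ShapeError(f"cannot crop {(h, w)} up to {(height, width)}")
    i = (h - height) // 2
    j = (w - width) // 2
    return x[:, i : i + height, j : j + width, :]


class CBGBlock(Layer):
    """3x3 convolution -> batch norm -> GeLU (same padding, channels -> f)."""

    def __init__(self, in_channels, out_channels, rng, kernel_size=3, dtype=np.float32, name="cbg"):
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng, dtype, name=f"{name}.conv")
        self.bn = BatchNorm2d(out_channels, dtype=dtype, name=f"{name}.bn")
        self.act = GeLU()

    def forward(self, x, training=True):
        return self.act(self.bn(self.conv(x, training), training), training)

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(self.act.backward(dout)))


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Pools each channel to its spatial mean, maps ``c -> c/r`` (ReLU) then
    back ``c/r -> c`` (sigmoid) and rescales the input channels by the
    resulting gates, which lie strictly in (0, 1).
    """

    def __init__(self, channels, rng, reduction=8, dtype=np.float32, name="se"):
        reduced = channels // reduction
        if reduced < 1:
            raise ConfigurationError(
                f"SE reduction {reduction} leaves no units for {channels} channels (c/r < 1)"
            )
        self.channels = channels
        self.reduce = Dense(channels, reduced, rng, dtype, name=f"{name}.reduce")
        self.relu = ReLU()
        self.expand = Dense(reduced, channels, rng, dtype, name=f"{name}.expand")
        self.sig = Sigmoid()
        self._cache = None

    def forward(self, x, training=True):
        pooled = x.mean(axis=(1, 2))
        gate = self.sig(self.expand(self.relu(self.reduce(pooled, training), training), training), training)
        self._cache = (x, gate)
        return x * gate[:, None, None, :]

    def backward(self, dout):
        x, gate = self._cache
        hw = x.shape[1] * x.shape[2]
        dgate = (dout * x).sum(axis=(1, 2))
        dpooled = self.reduce.backward(self.relu.backward(self.expand.backward(self.sig.backward(dgate))))
        return dout * gate[:, None, None, :] + dpooled[:, None, None, :] / hw

    @property
    def last_gates(self) -> np.ndarray:
        """Channel gates from the most recent forward pass, shape (n, c)."""
        return self._cache[1]


class ECMBlock(Layer):
    """Enhanced ConvMixer module: depthwise/pointwise mixing + SE + residual."""

    def __init__(self, channels, rng, se_reduction=8, dtype=np.float32, name="ecm"):
        self.dw = DepthwiseConv2d(channels, 3, rng, dtype, name=f"{name}.dw")
        self.act1 = GeLU()
        self.bn1 = BatchNorm2d(channels, dtype=dtype, name=f"{name}.bn1")
        self.pw = Conv2d(channels, channels, 1, rng, dtype, name=f"{name}.pw")
        self.act2 = GeLU()
        self.bn2 = BatchNorm2d(channels, dtype=dtype, name=f"{name}.bn2")
        self.se = SEBlock(channels, rng, se_reduction, dtype, name=f"{name}.se")

    def forward(self, x, training=True):
        t = self.bn1(self.act1(self.dw(x, training), training), training)
        t = self.bn2(self.act2(self.pw(t, training), training), training)
        recal = self.se(t, training)
        if recal.shape != x.shape:
            raise ShapeError(f"residual mismatch: {recal.shape} vs input {x.shape}")
        return recal + x

    def backward(self, dout):
        d = self.se.backward(dout)
        d = self.bn2.backward(d)
        d = self.pw.backward(self.act2.backward(d))
        d = self.bn1.backward(d)
        d = self.dw.backward(self.act1.backward(d))
        return d + dout


class EncoderBlock(Layer):
    """One encoder stage: CBG (+ optional ECM) producing the skip, then 2x2 max pool."""

    def __init__(self, in_channels, filters, rng, use_ecm=True, se_reduction=8, dtype=np.float32, name="enc"):
        self.cbg = CBGBlock(in_channels, filters, rng, dtype=dtype, name=f"{name}.cbg")
        self.ecm = ECMBlock(filters, rng, se_reduction, dtype, name=f"{name}.ecm") if use_ecm else None
        self.pool = MaxPool2x2()

    def forward(self, x, training=True):
        skip = self.cbg(x, training)
        if self.ecm is not None:
            skip = self.ecm(skip, training)
        down = self.pool(skip, training)
        return skip, down

    def backward(self, dskip, ddown):
        """Combine the decoder-side skip gradient with the deeper-path gradient."""
        d = dskip + self.pool.backward(ddown)
        if self.ecm is not None:
            d = self.ecm.backward(d)
        return self.cbg.backward(d)


class CEMHABlock(Layer):
    """Convolution-enhanced multi-head attention bottleneck.

    ``F = CBG(x)`` reduces the deepest encoder output to ``d_model`` channels;
    the spatial grid is flattened to ``h * w`` tokens with channels as the
    embedding; multi-head self-attention (default four heads) mixes the
    tokens; a 1x1 convolution projects the concatenated heads back to
    ``d_model`` and the result is added to ``F``.
    """

    def __init__(self, in_channels, d_model, heads, rng, dtype=np.float32, name="cemha"):
        self.d_model = d_model
        self.cbg = CBGBlock(in_channels, d_model, rng, dtype=dtype, name=f"{name}.cbg")
        self.mha = MultiHeadSelfAttention(d_model, heads, rng, dtype, name=f"{name}.mha")
        self.proj = Conv2d(d_model, d_model, 1, rng, dtype, name=f"{name}.proj")
        self._shape = None

    def forward(self, x, training=True):
        f = self.cbg(x, training)
        n, h, w, d = f.shape
        self._shape = (n, h, w, d)
        tokens = f.reshape(n, h * w, d)
        attended = self.mha(tokens, training).reshape(n, h, w, d)
        return self.proj(attended, training) + f

    def backward(self, dout):
        n, h, w, d = self._shape
        da = self.proj.backward(dout)
        dtok = self.mha.backward(da.reshape(n, h * w, d))
        df = dtok.reshape(n, h, w, d) + dout
        return self.cbg.backward(df)

    @property
    def last_attention(self) -> np.ndarray:
        """Attention weights (n, heads, tokens, tokens) of the last forward pass."""
        return self.mha.last_attention


class ECNBlock(Layer):
    """Enhanced ConvNeXt module.

    Depthwise 7x7 -> channel layer norm -> 1x1 back to ``c`` -> residual add
    of the input -> 1x1 expansion to ``4c`` -> GeLU -> 1x1 contraction ->
    squeeze-and-excitation. ``out_channels`` (default ``c``) sets the width
    of the final contraction, letting decoder stages fuse a concatenated
    tensor down to the skip width.
    """

    def __init__(self, channels, rng, out_channels=None, se_reduction=8, dtype=np.float32, name="ecn"):
        out_channels = channels if out_channels is None else out_channels
        self.out_channels = out_channels
        self.dw = DepthwiseConv2d(channels, 7, rng, dtype, name=f"{name}.dw")
        self.ln = ChannelLayerNorm(channels, dtype=dtype, name=f"{name}.ln")
        self.pw_in = Conv2d(channels, channels, 1, rng, dtype, name=f"{name}.pw_in")
        self.pw_expand = Conv2d(channels, 4 * channels, 1, rng, dtype, name=f"{name}.pw_expand")
        self.act = GeLU()
        self.pw_out = Conv2d(4 * channels, out_channels, 1, rng, dtype, name=f"{name}.pw_out")
        self.se = SEBlock(out_channels, rng, se_reduction, dtype, name=f"{name}.se")

    def forward(self, x, training=True):
        t = self.pw_in(self.ln(self.dw(x, training), training), training)
        r = t + x
        e = self.act(self.pw_expand(r, training), training)
        return self.se(self.pw_out(e, training), training)

    def backward(self, dout):
        d = self.pw_out.backward(self.se.backward(dout))
        dr = self.pw_expand.backward(self.act.backward(d))
        dt = self.pw_in.backward(dr)
        return self.dw.backward(self.ln.backward(dt)) + dr


class DecoderBlock(Layer):
    """One decoder stage.

    The deeper-stage tensor is upsampled by a 2x2 stride-2 transposed
    convolution to the skip's channel width (halving channels in the generic
    stage), batch-normalised and GeLU-activated; the encoder skip is
    centre-cropped to the upsampled size (identity when shapes match, as with
    same-padded power-of-two inputs) and concatenated along channels; the
    concatenation is refined by an ECN (or, in the ablated variants, a CBG)
    down to the skip width, and the cropped skip is optionally added back as
    a residual.
    """

    def __init__(
        self,
        in_channels,
        skip_channels,
        rng,
        use_ecn=True,
        residual=True,
        se_reduction=8,
        dtype=np.float32,
        name="dec",
    ):
        self.skip_channels = skip_channels
        self.up = ConvTranspose2d2x2(in_channels, skip_channels, rng, dtype, name=f"{name}.up")
        self.bn = BatchNorm2d(skip_channels, dtype=dtype, name=f"{name}.bn")
        self.act = GeLU()
        if use_ecn:
            self.refine: Layer = ECNBlock(
                2 * skip_channels, rng, out_channels=skip_channels, se_reduction=se_reduction,
                dtype=dtype, name=f"{name}.ecn",
            )
        else:
            self.refine = CBGBlock(2 * skip_channels, skip_channels, rng, dtype=dtype, name=f"{name}.cbg")
        self.residual = residual
        self._cache = None

    def forward(self, x, skip, training=True):
        u = self.act(self.bn(self.up(x, training), training), training)
        n, h, w, _ = u.shape
        cropped = center_crop(skip, h, w)
        cat = np.concatenate([u, cropped], axis=-1)
        y = self.refine(cat, training)
        if self.residual:
            y = y + cropped
        self._cache = (skip.shape, h, w)
        return y

    def backward(self, dout):
        skip_shape, h, w = self._cache
        dcat = self.refine.backward(dout)
        du = dcat[..., : self.skip_channels]
        dcrop = dcat[..., self.skip_channels :].copy()
        if self.residual:
            dcrop += dout
        dskip = np.zeros(skip_shape, dtype=dout.dtype)
        i = (skip_shape[1] - h) // 2
        j = (skip_shape[2] - w) // 2
        dskip[:, i : i + h, j : j + w, :] = dcrop
        dx = self.up.backward(self.bn.backward(self.act.backward(du)))
        return dx, dskip
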