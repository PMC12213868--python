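"""Full segmentation network: encoder stages, bottleneck, decoder stages, head.

``build_model`` assembles one of four variants:

* ``model1`` — plain CBG encoder/decoder stages and a two-layer convolutional
  bottleneck (the ablation base model);
* ``model2`` — adds enhanced ConvMixer modules to every encoder stage;
* ``model3`` — additionally refines every decoder stage with an enhanced
  ConvNeXt module;
* ``hma_net`` — the full network: ``model3`` plus the convolution-enhanced
  multi-head attention bottleneck.

The forward pass maps ``(n, h, w, in_channels)`` images to per-pixel lesion
probabilities ``(n, h, w, 1)`` strictly inside (0, 1).
"""

from __future__ import annotations

import json

import numpy as np

from .blocks import CBGBlock, CEMHABlock, DecoderBlock, EncoderBlock
from .config import ModelConfig
from .exceptions import ConfigurationError, ShapeError
from .nn import Conv2d, Layer, Sigmoid
from .nn.functional import sigmoid

_PROB_EPS = 1e-7  # keeps outputs strictly inside (0, 1) even in float32


class SegmentationModel(Layer):
    """Encoder-bottleneck-decoder network built from a :class:`ModelConfig`."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dtype = cfg.np_dtype
        widths = cfg.effective_widths
        d_model = cfg.effective_d_model
        use_ecm = cfg.variant in ("model2", "model3", "hma_net")
        use_ecn = cfg.variant in ("model3", "hma_net")
        use_attention = cfg.variant == "hma_net"

        self.encoders = []
        in_ch = cfg.in_channels
        for i, w in enumerate(widths):
            self.encoders.append(
                EncoderBlock(in_ch, w, rng, use_ecm=use_ecm, se_reduction=cfg.se_reduction,
                             dtype=dtype, name=f"enc{i + 1}")
            )
            in_ch = w

        if use_attention:
            self.bottleneck = CEMHABlock(widths[-1], d_model, cfg.heads, rng, dtype, name="bottleneck")
            self._conv_bottleneck = None
        else:
            # two 3x3 conv + BN + GeLU layers, narrowed so the decoder sees
            # the same channel count (d_model) as the attention bottleneck
            self._conv_bottleneck = [
                CBGBlock(widths[-1], max(1, d_model // 2), rng, dtype=dtype, name="bottleneck.cbg1"),
                CBGBlock(max(1, d_model // 2), d_model, rng, dtype=dtype, name="bottleneck.cbg2"),
            ]
            self.bottleneck = None

        self.decoders = []
        in_ch = d_model
        for i, w in enumerate(reversed(widths)):
            self.decoders.append(
                DecoderBlock(in_ch, w, rng, use_ecn=use_ecn,
                             residual=cfg.decoder_residual and use_ecn,
                             se_reduction=cfg.se_reduction, dtype=dtype, name=f"dec{5 - i}")
            )
            in_ch = w

        self.head = Conv2d(widths[0], 1, 1, rng, dtype, name="head")
        self.head_act = Sigmoid()

    # -- introspection ---------------------------------------------------
    def iter_layers(self):
        """Yield every layer object in the network, depth first."""

        def walk(obj):
            if isinstance(obj, Layer):
                yield obj
                for v in obj.__dict__.values():
                    yield from walk(v)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    yield from walk(item)

        for enc in self.encoders:
            yield from walk(enc)
        yield from walk(self.bottleneck if self.bottleneck is not None else self._conv_bottleneck)
        for dec in self.decoders:
            yield from walk(dec)
        yield from walk(self.head)

    def params(self):
        out = []
        for enc in self.encoders:
            out.extend(enc.params())
        if self.bottleneck is not None:
            out.extend(self.bottleneck.params())
        else:
            for b in self._conv_bottleneck:
                out.extend(b.params())
        for dec in self.decoders:
            out.extend(dec.params())
        out.extend(self.head.params())
        return out

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    @property
    def bottleneck_grid(self) -> tuple[int, int]:
        """Token grid of the bottleneck for the configured input size."""
        s = self.cfg.input_size // 32
        return (s, s)

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ShapeError(f"expected NHWC input, got shape {x.shape}")
        n, h, w, c = x.shape
        if n < 1:
            raise ShapeError("batch of size 0 is rejected")
        if c != self.cfg.in_channels:
            raise ShapeError(f"expected {self.cfg.in_channels} channels, got {c}")
        if h % 32 or w % 32:
            raise ShapeError(f"spatial size {(h, w)} must be divisible by 32")

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._check_input(x)
        skips = []
        t = x.astype(self.cfg.np_dtype, copy=False)
        for enc in self.encoders:
            skip, t = enc(t, training)
            skips.append(skip)
        if self.bottleneck is not None:
            t = self.bottleneck(t, training)
        else:
            for b in self._conv_bottleneck:
                t = b(t, training)
        for dec, skip in zip(self.decoders, reversed(skips)):
            t = dec.forward(t, skip, training)
        logits = self.head(t, training)
        p = self.head_act(logits, training)
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        d = self.head.backward(self.head_act.backward(dprob))
        dskips = []
        for dec in reversed(self.decoders):
            d, dskip = dec.backward(d)
            dskips.append(dskip)
        if self.bottleneck is not None:
            d = self.bottleneck.backward(d)
        else:
            for b in reversed(self._conv_bottleneck):
                d = b.backward(d)
        for enc, dskip in zip(reversed(self.encoders), reversed(dskips)):
            d = enc.backward(dskip, d)
        return d

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write all weights, BN running statistics and the config to one archive."""
        arrays = {"config_json": np.array(self.cfg.to_json())}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i:04d}"] = p.value
        from .nn import BatchNorm2d

        bn_idx = 0
        for layer in self.iter_layers():
            if isinstance(layer, BatchNorm2d):
                arrays[f"bn_{bn_idx:04d}_mean"] = layer.running_mean
                arrays[f"bn_{bn_idx:04d}_var"] = layer.running_var
                bn_idx += 1
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig.from_json(str(data["config_json"]))
            model = cls(cfg)
            for i, p in enumerate(model.params()):
                value = data[f"param_{i:04d}"]
                if value.shape != p.value.shape:
                    raise ConfigurationError(
                        f"checkpoint parameter {i} has shape {value.shape}, expected {p.value.shape}"
                    )
                p.value[...] = value
            from .nn import BatchNorm2d

            bn_idx = 0
            for layer in model.iter_layers():
                if isinstance(layer, BatchNorm2d):
                    layer.running_mean = data[f"bn_{bn_idx:04d}_mean"]
                    layer.running_var = data[f"bn_{bn_idx:04d}_var"]
                    bn_idx += 1
        return model


def build_model(cfg: ModelConfig) -> SegmentationModel:
    """Construct a seeded, deterministically initialised network variant."""
    return SegmentationModel(cfg)


def predict_masks(model: SegmentationModel, images: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold predicted probabilities into binary masks (strict ``>``).

    ``threshold=0.0`` therefore yields all ones and ``threshold=1.0`` all
    zeros, since probabilities are strictly inside (0, 1).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must lie in [0, 1], got {threshold}")
    expected = model.cfg.input_size
    if images.shape[1] % 32 or images.shape[2] % 32:
        raise ShapeError(
            f"image size {images.shape[1:3]} incompatible; configured input size is {expected}"
        )
    probs = model.forward(images, training=False)
    return (probs > threshold).astype(np.uint8)
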