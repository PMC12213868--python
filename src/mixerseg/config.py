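"""Model and training configuration with YAML/JSON round-tripping."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .exceptions import ConfigurationError

VARIANTS = ("model1", "model2", "model3", "hma_net")


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    Parameters
    ----------
    input_size
        Side length of the (square) network input in pixels; must be
        divisible by 32 so five 2x2 poolings leave an integral grid.
        Non-square inputs are accepted at the forward pass as long as both
        sides are divisible by 32.
    stage_widths
        Channel widths of the five encoder stages before ``width_mult``.
    width_mult
        Global channel multiplier for desk-scale experiments.
    d_model
        Bottleneck embedding width of the attention module; defaults to half
        the deepest stage width. Must be divisible by ``heads``.
    variant
        ``model1`` (plain conv encoder/decoder, conv bottleneck), ``model2``
        (+ enhanced ConvMixer encoder), ``model3`` (+ enhanced ConvNeXt
        decoder), ``hma_net`` (+ attention bottleneck; the full network).
    """

    input_size: int = 128
    in_channels: int = 1
    stage_widths: Sequence[int] = (32, 64, 128, 256, 512)
    width_mult: float = 1.0
    se_reduction: int = 8
    heads: int = 4
    d_model: Optional[int] = None
    decoder_residual: bool = True
    variant: str = "hma_net"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; valid names are {', '.join(VARIANTS)}"
            )
        if self.input_size % 32 != 0:
            raise ConfigurationError(f"input_size must be divisible by 32, got {self.input_size}")
        if len(tuple(self.stage_widths)) != 5:
            raise ConfigurationError("stage_widths must list exactly five encoder widths")
        if self.effective_d_model % self.heads != 0:
            raise ConfigurationError(
                f"d_model={self.effective_d_model} is not divisible by heads={self.heads}"
            )

    @property
    def effective_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(w * self.width_mult)) for w in self.stage_widths)

    @property
    def effective_d_model(self) -> int:
        if self.d_model is not None:
            return self.d_model
        return max(self.heads, self.effective_widths[-1] // 2)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "stage_widths" in d:
            d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, constant learning rate)."""

    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    shuffle_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)
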