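"""Strided 1D convolutional encoder: raw 20-channel EEG -> BENDR vectors.

Six sequential blocks of (1D convolution, GroupNorm, GELU).  Receptive
fields are (3, 2, 2, 2, 2, 2) and each stride equals its receptive field, so
receptive fields never overlap and the stack downsamples by their product,
96: at 256 Hz input the output vectors arrive at ~2.67 Hz, one vector per
375 ms of signal.  Convolutions are valid (no padding); trailing samples
that do not fill a block are dropped.

Because kernel == stride, each convolution is a reshape into non-overlapping
patches followed by a dense projection, which is how it is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor

__all__ = ["EncoderConfig", "ConvEncoder", "output_length", "downsample_factor"]


@dataclass(frozen=True)
class EncoderConfig:
    in_channels: int = 20
    filters: int = 512
    receptive_fields: tuple[int, ...] = (3, 2, 2, 2, 2, 2)
    norm_groups: int = 16

    def __post_init__(self):
        if any(k < 1 for k in self.receptive_fields):
            raise ValueError("receptive fields must be >= 1")
        if self.filters % self.norm_groups:
            raise ValueError("filters must divide evenly into norm groups")

    @property
    def strides(self) -> tuple[int, ...]:
        # strides match the receptive fields (non-overlapping patches)
        return self.receptive_fields


def downsample_factor(cfg: EncoderConfig) -> int:
    """Product of strides: input samples per output vector."""
    return int(np.prod(cfg.strides))


def output_length(n_samples: int, cfg: EncoderConfig) -> int:
    """Composed valid-convolution length: successive floor(T / k)."""
    length = int(n_samples)
    for k in cfg.strides:
        length //= k
    return length


def effective_hz(input_hz: float, cfg: EncoderConfig) -> Fraction:
    """Exact rational output rate (256 Hz -> 8/3 Hz for the default stack)."""
    return Fraction(input_hz).limit_denominator() / downsample_factor(cfg)


class _ConvBlock(Module):
    """Patch convolution (kernel == stride) + GroupNorm + GELU."""

    def __init__(self, c_in: int, c_out: int, kernel: int, groups: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        # Kaiming fan-in init over the flattened patch
        w = rng.normal(0.0, np.sqrt(2.0 / (c_in * kernel)),
                       size=(c_in * kernel, c_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out))
        self.norm = nn.GroupNorm(groups, c_out)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, t = x.shape
        k = self.kernel
        length = t // k
        if length == 0:
            raise ValueError(f"input length {t} shorter than kernel {k}")
        x = x[:, :, :length * k]
        # (B, C, L, k) -> (B, L, C, k) -> (B, L, C*k)
        patches = x.reshape(b, c, length, k).transpose(0, 2, 1, 3) \
                   .reshape(b, length, c * k)
        y = patches @ self.weight + self.bias     # (B, L, F)
        y = y.transpose(0, 2, 1)                  # (B, F, L)
        return self.norm(y).gelu()


class ConvEncoder(Module):
    """The full six-block stack; maps (B, 20, T) to BENDR (B, L, filters)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        blocks = []
        c_in = cfg.in_channels
        for k in cfg.receptive_fields:
            blocks.append(_ConvBlock(c_in, cfg.filters, k, cfg.norm_groups, rng))
            c_in = cfg.filters
        self.blocks = blocks

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[2] < downsample_factor(self.cfg):
            raise ValueError(
                f"input length {x.shape[2]} shorter than the encoder span "
                f"{downsample_factor(self.cfg)}")
        for block in self.blocks:
            x = block(x)
        return x.transpose(0, 2, 1)  # (B, L, filters)

    def encode(self, data: np.ndarray) -> np.ndarray:
        """Plain-array forward (no gradient tape)."""
        return self(Tensor(np.asarray(data, dtype=np.float64))).data
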