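"""Transformer contextualizer: (masked) BENDR -> contextual outputs.

A standard bidirectional transformer encoder with every internal
normalization layer removed, made trainable by T-Fixup weight scaling.
Position is represented by an additive grouped convolution (receptive
field 25, 16 groups, GELU on the branch) rather than a positional table,
so the same weights accept any sequence length.

Input BENDR (dimension ``d_bendr``) is up-projected to the model dimension,
contextualized, and down-projected back to BENDR space so the contrastive
loss compares commensurable vectors.  A fixed start token (a vector of -5,
outside the harmonized signal range) is prepended; its output position is
reserved for downstream classification and never masked.

During pre-training each layer is skipped independently with the LayerDrop
probability and dropout is active; both are off in evaluation mode and
during fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor

__all__ = [
    "ContextualizerConfig",
    "ContextualOutput",
    "Contextualizer",
    "apply_mask",
    "prepend_start_token",
]


@dataclass(frozen=True)
class ContextualizerConfig:
    d_bendr: int = 512
    layers: int = 8
    heads: int = 8
    d_model: int = 1536
    d_ff: int = 3076
    layerdrop_p: float = 0.01
    dropout_p: float = 0.15
    position_rf: int = 25
    position_groups: int = 16
    start_token_value: float = -5.0
    tfixup_scale: float = 0.67  # multiplies layers**-0.25

    def __post_init__(self):
        if self.d_model % self.heads:
            raise ValueError("d_model must divide evenly into heads")
        if not (0.0 <= self.layerdrop_p <= 1.0 and 0.0 <= self.dropout_p < 1.0):
            raise ValueError("probabilities out of range")
        if self.d_model % self.position_groups:
            raise ValueError("d_model must divide evenly into position groups")


@dataclass
class ContextualOutput:
    """Transformer outputs split at the start token."""

    start_out: np.ndarray | Tensor     # (B, d_bendr) classification position
    sequence_out: np.ndarray | Tensor  # (B, L, d_bendr), the c_t


def apply_mask(b: np.ndarray, mask_bool: np.ndarray,
               mask_vector: np.ndarray | Tensor) -> Tensor:
    """Replace masked BENDR positions with the learned mask vector (pure).

    ``b`` is (B, L, D) or (L, D); ``mask_bool`` a matching boolean (B, L) or
    (L,).  The original array is untouched — the unmasked BENDR stays
    available as the loss target.
    """
    b = np.asarray(b)
    mask_bool = np.asarray(mask_bool, dtype=bool)
    if mask_bool.shape != b.shape[:-1]:
        raise ValueError("mask shape must match sequence positions")
    m = mask_vector if isinstance(mask_vector, Tensor) else Tensor(mask_vector)
    if m.shape != (b.shape[-1],):
        raise ValueError("mask vector dimension must match BENDR dimension")
    keep = Tensor((~mask_bool)[..., None].astype(np.float64))
    fill = Tensor(mask_bool[..., None].astype(np.float64))
    return Tensor(b) * keep + m * fill


def prepend_start_token(b: Tensor | np.ndarray,
                        value: float = -5.0) -> Tensor:
    """Prepend a constant start-token vector; positions shift by one."""
    if not isinstance(b, Tensor):
        b = Tensor(b)
    if b.ndim == 2:
        b = b.reshape(1, *b.shape)
    batch, _, d = b.shape
    token = Tensor(np.full((batch, 1, d), float(value)))
    return nn.concatenate([token, b], axis=1)


class _GroupedConvPosition(Module):
    """Additive grouped same-length convolutional position encoder."""

    def __init__(self, d_model: int, rf: int, groups: int,
                 rng: np.random.Generator):
        self.rf = rf
        self.groups = groups
        c_per = d_model // groups
        fan_in = c_per * rf
        bound = np.sqrt(6.0 / (fan_in + c_per))
        # (groups, c_in_per_group * rf, c_out_per_group)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(groups, fan_in, c_per)))
        self.bias = Parameter(np.zeros(d_model))

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, L, D) -> conv over L with same-length zero padding
        b, length, d = x.shape
        g = self.groups
        c_per = d // g
        rf = self.rf
        pad_l = (rf - 1) // 2
        pad_r = rf - 1 - pad_l
        xt = x.transpose(0, 2, 1)  # (B, D, L)
        zeros_l = Tensor(np.zeros((b, d, pad_l)))
        zeros_r = Tensor(np.zeros((b, d, pad_r)))
        xp = nn.concatenate([zeros_l, xt, zeros_r], axis=2)  # (B, D, L+rf-1)
        idx = np.arange(length)[:, None] + np.arange(rf)[None, :]  # (L, rf)
        win = xp[:, :, idx]                       # (B, D, L, rf)
        win = win.reshape(b, g, c_per, length, rf) \
                 .transpose(0, 1, 3, 2, 4) \
                 .reshape(b, g, length, c_per * rf)
        y = win @ self.weight                     # (B, g, L, c_per)
        y = y.transpose(0, 2, 1, 3).reshape(b, length, d) + self.bias
        branch = y.gelu()
        return x + branch


class _SelfAttention(Module):
    def __init__(self, cfg: ContextualizerConfig, rng: np.random.Generator):
        self.heads = cfg.heads
        d = cfg.d_model
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.drop = nn.Dropout(cfg.dropout_p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        b, length, d = x.shape
        h = self.heads
        dh = d // h

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, length, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        attn = self.drop(attn, rng)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, length, d)
        return self.wo(ctx)


class _TransformerLayer(Module):
    """Pre-activation-free residual layer: no normalization anywhere."""

    def __init__(self, cfg: ContextualizerConfig, rng: np.random.Generator):
        self.attn = _SelfAttention(cfg, rng)
        self.ff1 = nn.Linear(cfg.d_model, cfg.d_ff, rng)
        self.ff2 = nn.Linear(cfg.d_ff, cfg.d_model, rng)
        self.drop = nn.Dropout(cfg.dropout_p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        x = x + self.drop(self.attn(x, rng), rng)
        x = x + self.drop(self.ff2(self.ff1(x).gelu()), rng)
        return x


class Contextualizer(Module):
    """Up-project, position-encode, transformer stack, down-project."""

    def __init__(self, cfg: ContextualizerConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_proj = nn.Linear(cfg.d_bendr, cfg.d_model, rng)
        self.pos_conv = _GroupedConvPosition(
            cfg.d_model, cfg.position_rf, cfg.position_groups, rng)
        self.layers = [_TransformerLayer(cfg, rng) for _ in range(cfg.layers)]
        self.out_proj = nn.Linear(cfg.d_model, cfg.d_bendr, rng)
        self.mask_vector = Parameter(rng.normal(0.0, 1.0, size=cfg.d_bendr))
        self._tfixup()

    def _tfixup(self) -> None:
        """T-Fixup: scale value-projection and feed-forward weights by
        0.67 * N^(-1/4) after Xavier init (no normalization layers exist)."""
        scale = self.cfg.tfixup_scale * self.cfg.layers**-0.25
        for layer in self.layers:
            for p in (layer.attn.wv.weight, layer.attn.wo.weight,
                      layer.ff1.weight, layer.ff2.weight):
                p.data *= scale

    def __call__(self, q: Tensor | np.ndarray,
                 rng: np.random.Generator | None = None) -> ContextualOutput:
        """Contextualize a masked BENDR sequence (start token included).

        ``rng`` enables train mode (LayerDrop + dropout); ``None`` is
        deterministic evaluation mode with every layer active.
        """
        if not isinstance(q, Tensor):
            q = Tensor(np.asarray(q, dtype=np.float64))
        if q.ndim == 2:
            q = q.reshape(1, *q.shape)
        x = self.in_proj(q)
        x = self.pos_conv(x)
        for layer in self.layers:
            if rng is not None and rng.random() < self.cfg.layerdrop_p:
                continue
            x = layer(x, rng)
        y = self.out_proj(x)
        if not np.all(np.isfinite(y.data)):
            raise FloatingPointError("contextualizer produced non-finite output")
        return ContextualOutput(start_out=y[:, 0, :], sequence_out=y[:, 1:, :])
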