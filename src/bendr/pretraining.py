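"""Masked-span contrastive pre-training (wav2vec 2.0-style, unquantized).

A span mask is sampled over BENDR positions (each position starts a span of
10 with probability 0.065; overlaps merge), masked positions are replaced by
a single learned mask vector, and the transformer must produce an output
``c_t`` at each masked position that is more cosine-similar (temperature
0.1) to the true un-masked BENDR ``b_t`` than to 20 distractors drawn
uniformly from the same sequence.  The mean squared BENDR activation is
added to the loss (weight 1) to keep encoder activations bounded.
Optimization is Adam with decoupled weight decay 0.01 under a cosine
learning-rate schedule with linear warm-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .contextualizer import (Contextualizer, ContextualizerConfig, apply_mask,
                             prepend_start_token)
from .encoder import ConvEncoder, EncoderConfig
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "PretrainConfig",
    "MaskPlan",
    "sample_mask_plan",
    "sample_negatives",
    "cosine_similarity",
    "contrastive_loss",
    "activation_penalty",
    "lr_schedule",
    "BendrModel",
    "pretrain_step",
    "pretrain",
]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class PretrainConfig:
    p_mask: float = 0.065
    span: int = 10
    n_negatives: int = 20
    kappa: float = 0.1
    act_penalty_weight: float = 1.0
    weight_decay: float = 0.01
    warmup_frac: float = 0.05
    total_steps: int = 10000
    peak_lr: float = 1e-4
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_mask <= 1.0:
            raise ValueError("p_mask must be a probability")
        if self.span < 1 or self.n_negatives < 1 or self.kappa <= 0:
            raise ValueError("invalid pre-training configuration")


@dataclass
class MaskPlan:
    """Span starts + span length; ``mask_bool[i]`` iff i is inside a span."""

    starts: list[int]
    span: int
    mask_bool: np.ndarray

    @property
    def n_masked(self) -> int:
        return int(self.mask_bool.sum())


def sample_mask_plan(L: int, cfg: PretrainConfig,
                     rng: np.random.Generator) -> MaskPlan:
    """Each position starts a span with probability p_mask; overlap allowed,
    spans truncated at the sequence end."""
    starts = np.flatnonzero(rng.random(L) < cfg.p_mask)
    mask = np.zeros(L, dtype=bool)
    for s in starts:
        mask[s:s + cfg.span] = True
    return MaskPlan(starts=starts.tolist(), span=cfg.span, mask_bool=mask)


def sample_negatives(L: int, t: int, n_negatives: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Indices of distractors: uniform with replacement over {0..L-1} \\ {t}."""
    if L < 2:
        raise ValueError("cannot sample negatives from a length-1 sequence")
    idx = rng.integers(0, L - 1, size=n_negatives)
    idx[idx >= t] += 1  # skip the target position
    return idx


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """cossim(x, y) = x'y / (|x||y|); zero vectors are undefined."""
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(x, y) / (nx * ny))


def _cosine_rows(c: Tensor, cands: Tensor, eps: float = 1e-12) -> Tensor:
    """Batched cosine similarities: c (N, D) against cands (N, K, D) -> (N, K)."""
    num = (c.reshape(c.shape[0], 1, c.shape[1]) * cands).sum(axis=2)
    cn = ((c**2).sum(axis=1) + eps).sqrt()
    kn = ((cands**2).sum(axis=2) + eps).sqrt()
    return num / (cn.reshape(-1, 1) * kn)


def contrastive_loss(c_t: np.ndarray | Tensor,
                     candidates: np.ndarray | Tensor,
                     kappa: float = 0.1,
                     target_index: int = 0) -> Tensor:
    """-log softmax (over candidates) of cossim(c_t, .)/kappa at the target.

    ``c_t``: (D,) or (N, D); ``candidates``: (K, D) or (N, K, D) with the true
    ``b_t`` at ``target_index``.  Returns the mean over the N masked positions.
    """
    c = c_t if isinstance(c_t, Tensor) else Tensor(c_t)
    cands = candidates if isinstance(candidates, Tensor) else Tensor(candidates)
    if c.ndim == 1:
        c = c.reshape(1, -1)
        cands = cands.reshape(1, *cands.shape)
    if np.any(np.linalg.norm(cands.data, axis=-1) == 0.0) or \
            np.any(np.linalg.norm(c.data, axis=-1) == 0.0):
        raise ValueError("contrastive loss undefined for zero vectors")
    sims = _cosine_rows(c, cands) * (1.0 / kappa)   # (N, K)
    loss = sims.logsumexp(axis=-1) - sims[:, target_index]
    return loss.mean()


def activation_penalty(b: np.ndarray | Tensor) -> Tensor:
    """Mean squared BENDR activation over all positions and features."""
    t = b if isinstance(b, Tensor) else Tensor(b)
    return (t**2).mean()


def lr_schedule(step: int, cfg: PretrainConfig) -> float:
    """Linear warm-up to peak, then half-cosine decay to zero."""
    warmup = max(1, int(round(cfg.warmup_frac * cfg.total_steps)))
    if step < warmup:
        return cfg.peak_lr * step / warmup
    frac = (step - warmup) / max(1, cfg.total_steps - warmup)
    return cfg.peak_lr * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))


# =============================================================================
# Model container and training step
# =============================================================================


class BendrModel(nn.Module):
    """Encoder + contextualizer with a shared checkpoint layout."""

    def __init__(self, enc_cfg: EncoderConfig, ctx_cfg: ContextualizerConfig,
                 rng: np.random.Generator):
        if ctx_cfg.d_bendr != enc_cfg.filters:
            raise ValueError("contextualizer d_bendr must equal encoder filters")
        self.encoder = ConvEncoder(enc_cfg, rng)
        self.contextualizer = Contextualizer(ctx_cfg, rng)

    # -- checkpointing --------------------------------------------------------
    def save(self, path, extra_trees: dict[str, dict[str, np.ndarray]] | None = None,
             optimizer: nn.Adam | None = None, meta: dict | None = None) -> None:
        arrays: dict[str, np.ndarray] = {}
        for k, v in self.encoder.state_dict().items():
            arrays[f"encoder/{k}"] = v
        for k, v in self.contextualizer.state_dict().items():
            arrays[f"contextualizer/{k}"] = v
        for tree, state in (extra_trees or {}).items():
            for k, v in state.items():
                arrays[f"{tree}/{k}"] = v
        if optimizer is not None:
            for k, v in optimizer.state_dict().items():
                arrays[f"optimizer/{k}"] = v
        meta = dict(meta or {})
        meta["schema"] = CHECKPOINT_SCHEMA
        nn.save_arrays(path, arrays, meta)

    @staticmethod
    def load_trees(path) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
        arrays, meta = nn.load_arrays(path)
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(
                f"incompatible checkpoint schema {meta.get('schema')!r}; "
                f"expected {CHECKPOINT_SCHEMA}")
        trees: dict[str, dict[str, np.ndarray]] = {}
        for key, arr in arrays.items():
            tree, _, name = key.partition("/")
            trees.setdefault(tree, {})[name] = arr
        return trees, meta


@dataclass
class StepResult:
    contrastive: float
    penalty: float
    total: float
    accuracy: float
    n_masked: int


def _forward_contrastive(model: BendrModel, batch: np.ndarray,
                         cfg: PretrainConfig, rng: np.random.Generator,
                         plans: list[MaskPlan] | None = None,
                         train: bool = True) -> tuple[Tensor, Tensor, float, int]:
    """Shared forward pass: returns (contrastive loss, penalty, accuracy, n)."""
    x = Tensor(np.asarray(batch, dtype=np.float64))
    b = model.encoder(x)                       # (B, L, D), the unmasked targets
    B, L, D = b.shape
    if plans is None:
        plans = []
        for _ in range(B):
            plan = sample_mask_plan(L, cfg, rng)
            if plan.n_masked == 0:             # resample once, then give up
                plan = sample_mask_plan(L, cfg, rng)
            plans.append(plan)
    mask_bool = np.stack([p.mask_bool for p in plans])
    if mask_bool.sum() == 0:
        raise RuntimeError("empty mask plan after resampling; skip this step")
    q = apply_mask(b.data, mask_bool, model.contextualizer.mask_vector)
    q = prepend_start_token(q, model.contextualizer.cfg.start_token_value)
    out = model.contextualizer(q, rng if train else None)
    c_seq = out.sequence_out                   # (B, L, D), aligned with b

    # gather masked positions and their candidate sets
    rows, cols = np.nonzero(mask_bool)
    n_masked = rows.size
    cand_rows = np.empty((n_masked, cfg.n_negatives + 1), dtype=np.intp)
    for i, (bi, t) in enumerate(zip(rows, cols)):
        cand_rows[i, 0] = t
        cand_rows[i, 1:] = sample_negatives(L, int(t), cfg.n_negatives, rng)
    c_masked = c_seq[rows, cols, :]            # (n, D)
    cands = b[rows[:, None], cand_rows, :]     # (n, K, D)
    loss_c = contrastive_loss(c_masked, cands, cfg.kappa, target_index=0)
    penalty = activation_penalty(b) * cfg.act_penalty_weight

    sims = _cosine_rows(Tensor(c_masked.data), Tensor(cands.data)).data
    correct = np.all(sims[:, :1] > sims[:, 1:], axis=1)  # ties are incorrect
    accuracy = float(correct.mean()) if n_masked else 0.0
    return loss_c, penalty, accuracy, n_masked


def pretrain_step(model: BendrModel, optimizer: nn.Adam, batch: np.ndarray,
                  cfg: PretrainConfig, rng: np.random.Generator,
                  step: int) -> StepResult:
    """One optimization step: encode, mask, contextualize, contrast, update."""
    loss_c, penalty, accuracy, n_masked = _forward_contrastive(
        model, batch, cfg, rng, train=True)
    total = loss_c + penalty
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite pre-training loss; halting")
    optimizer.zero_grad()
    total.backward()
    optimizer.step(lr=lr_schedule(step, cfg))
    return StepResult(contrastive=float(loss_c.data), penalty=float(penalty.data),
                      total=float(total.data), accuracy=accuracy,
                      n_masked=n_masked)


def pretrain(model: BendrModel, windows: np.ndarray, cfg: PretrainConfig,
             metrics_path=None, checkpoint_path=None,
             checkpoint_every: int = 0, start_step: int = 0,
             optimizer: nn.Adam | None = None) -> list[StepResult]:
    """Run the pre-training loop over an array of harmonized windows.

    ``windows``: (N, 20, T).  Batches are drawn with replacement under the
    config seed.  Metrics are appended as delimited text, one row per step.
    """
    rng = np.random.default_rng(cfg.seed + start_step)
    if optimizer is None:
        optimizer = nn.Adam(model.parameters(), lr=cfg.peak_lr,
                            weight_decay=cfg.weight_decay)
    history: list[StepResult] = []
    log_f = open(metrics_path, "a") if metrics_path else None
    if log_f and start_step == 0:
        log_f.write("step\tcontrastive\tpenalty\ttotal\taccuracy\tlr\n")
    try:
        for step in range(start_step, cfg.total_steps):
            take = rng.integers(0, windows.shape[0], size=cfg.batch_size)
            try:
                res = pretrain_step(model, optimizer, windows[take], cfg, rng,
                                    step)
            except RuntimeError:
                logger.warning("step %d: empty mask plan, skipped", step)
                continue
            history.append(res)
            if log_f:
                log_f.write(f"{step}\t{res.contrastive:.6f}\t{res.penalty:.6f}"
                            f"\t{res.total:.6f}\t{res.accuracy:.4f}"
                            f"\t{lr_schedule(step, cfg):.3e}\n")
            if checkpoint_path and checkpoint_every and \
                    (step + 1) % checkpoint_every == 0:
                model.save(checkpoint_path, optimizer=optimizer,
                           meta={"step": step + 1})
        if checkpoint_path:
            model.save(checkpoint_path, optimizer=optimizer,
                       meta={"step": cfg.total_steps, "final": True})
    finally:
        if log_f:
            log_f.close()
    return history
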