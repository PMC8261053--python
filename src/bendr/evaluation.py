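"""Contrastive-generalization evaluation and the six fine-tuning variants.

Evaluation of the pre-trained model on unseen data masks half the span
budget expected during training, with spans evenly spaced through the
sequence (N_m = floor(0.5 * N_S * p_mask) spans of 10, spaced floor(N_S/N_m)
apart, starting at position 0), and measures the fraction of masked
positions where the transformer output is strictly closest (cosine) to the
true BENDR among 20 distractors.

Downstream, six transfer configurations are supported, crossing pre-trained
vs random initialization, full transformer vs pooled-BENDR linear head, and
frozen vs trainable encoder.  Fine-tuning applies span masking with the
(frozen) pre-trained mask vector along time and contiguous feature dropout
along the BENDR dimension, balances classes per epoch by undersampling with
replacement, and reports chance-normalized metrics with bootstrap
confidence intervals over subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, balanced_accuracy_score,
                             roc_auc_score)

from . import nn
from .contextualizer import (Contextualizer, ContextualizerConfig, apply_mask,
                             prepend_start_token)
from .encoder import ConvEncoder, EncoderConfig
from .nn import Tensor
from .pretraining import (BendrModel, PretrainConfig, _cosine_rows,
                          lr_schedule, sample_negatives)

logger = logging.getLogger(__name__)

__all__ = [
    "EvalMaskPlan",
    "evenly_spaced_mask_plan",
    "contrastive_accuracy",
    "length_sweep",
    "pooled_linear_head",
    "DownstreamRegConfig",
    "downstream_regularize",
    "FineTuneSpec",
    "FineTuneModel",
    "build_finetune_model",
    "FinetuneConfig",
    "undersample_epoch",
    "metric",
    "normalize_metric",
    "run_finetune",
]


class UndefinedMetricError(ValueError):
    """Metric undefined (e.g., single-class test fold)."""


# =============================================================================
# Contrastive-generalization evaluation
# =============================================================================


@dataclass
class EvalMaskPlan:
    """Evenly spaced, non-overlapping evaluation spans."""

    n_seq: int
    n_m: int
    spacing: int
    span: int
    starts: list[int]
    mask_bool: np.ndarray


def evenly_spaced_mask_plan(L: int, p_mask: float = 0.065,
                            span: int = 10) -> EvalMaskPlan:
    """Half the training mask budget, evenly spaced from position 0."""
    n_m = max(1, int(np.floor(0.5 * L * p_mask)))
    spacing = L // n_m
    if spacing < span:
        raise ValueError(
            f"sequence of {L} steps too short for {n_m} non-overlapping "
            f"spans of {span} (spacing {spacing})")
    starts = [k * spacing for k in range(n_m)]
    mask = np.zeros(L, dtype=bool)
    for s in starts:
        mask[s:s + span] = True
    return EvalMaskPlan(n_seq=L, n_m=n_m, spacing=spacing, span=span,
                        starts=starts, mask_bool=mask)


def contrastive_accuracy(model: BendrModel, windows: np.ndarray,
                         cfg: PretrainConfig,
                         rng: np.random.Generator) -> float:
    """Fraction of masked positions whose transformer output is strictly
    closest to the true BENDR among the distractors (ties count as errors)."""
    correct = 0
    total = 0
    for window in windows:
        b = model.encoder.encode(window[None])[0]       # (L, D)
        L = b.shape[0]
        plan = evenly_spaced_mask_plan(L, cfg.p_mask, cfg.span)
        q = apply_mask(b, plan.mask_bool,
                       model.contextualizer.mask_vector.data)
        q = prepend_start_token(q, model.contextualizer.cfg.start_token_value)
        out = model.contextualizer(q, rng=None)         # eval mode
        c_seq = out.sequence_out.data[0]                # (L, D)
        for t in np.flatnonzero(plan.mask_bool):
            negs = sample_negatives(L, int(t), cfg.n_negatives, rng)
            cands = np.concatenate([b[None, t], b[negs]], axis=0)  # (K+1, D)
            sims = _cosine_rows(Tensor(c_seq[None, t]),
                                Tensor(cands[None])).data[0]
            correct += int(np.all(sims[0] > sims[1:]))
            total += 1
    return correct / total if total else 0.0


def length_sweep(model: BendrModel,
                 windows_by_subject: dict[str, np.ndarray],
                 lengths_s: tuple[float, ...],
                 cfg: PretrainConfig, rng_seed: int = 0,
                 sfreq: float = 256.0) -> pd.DataFrame:
    """Per-subject contrastive accuracy at several evaluation lengths.

    Each window is cropped to the leading ``length_s`` seconds before
    evaluation; returns a (subject, length_s, accuracy) table.
    """
    rows = []
    for subject, windows in sorted(windows_by_subject.items()):
        for length_s in lengths_s:
            n = int(round(length_s * sfreq))
            cropped = windows[:, :, :n]
            rng = np.random.default_rng(rng_seed)
            acc = contrastive_accuracy(model, cropped, cfg, rng)
            rows.append({"subject": subject, "length_s": length_s,
                         "accuracy": acc})
    return pd.DataFrame(rows)


# =============================================================================
# Downstream heads and regularization
# =============================================================================


def pooled_linear_head(b: Tensor | np.ndarray) -> Tensor:
    """Split BENDR into 4 contiguous near-equal parts, mean each, concatenate.

    (B, L, D) -> (B, 4*D); part lengths differ by at most one.
    """
    if not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=np.float64))
    if b.ndim == 2:
        b = b.reshape(1, *b.shape)
    L = b.shape[1]
    if L < 4:
        raise ValueError(f"pooled head needs at least 4 BENDR steps, got {L}")
    bounds = np.linspace(0, L, 5).round().astype(int)
    parts = [b[:, lo:hi, :].mean(axis=1) for lo, hi in zip(bounds, bounds[1:])]
    return nn.concatenate(parts, axis=1)


@dataclass(frozen=True)
class DownstreamRegConfig:
    span_frac: float = 0.10     # time-span length as a fraction of L
    span_start_p: float = 0.01  # per-position start probability
    feat_frac: float = 0.10     # contiguous feature-span fraction (51 of 512)
    feat_start_p: float = 0.005


def downstream_regularize(b: Tensor | np.ndarray, mask_vector: np.ndarray,
                          cfg: DownstreamRegConfig,
                          rng: np.random.Generator) -> Tensor:
    """Training-time BENDR regularization: time-span masking with the frozen
    pre-trained mask vector, and contiguous feature dropout to zero."""
    t = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float64))
    if t.ndim == 2:
        t = t.reshape(1, *t.shape)
    B, L, D = t.shape
    span_t = max(1, int(round(cfg.span_frac * L)))
    span_f = int(np.floor(cfg.feat_frac * D))
    time_mask = np.zeros((B, L), dtype=bool)
    for s in np.argwhere(rng.random((B, L)) < cfg.span_start_p):
        time_mask[s[0], s[1]:s[1] + span_t] = True
    feat_keep = np.ones((B, D))
    if span_f:
        for s in np.argwhere(rng.random((B, D)) < cfg.feat_start_p):
            feat_keep[s[0], s[1]:s[1] + span_f] = 0.0
    mv = np.asarray(mask_vector, dtype=np.float64)
    out = t * Tensor((~time_mask)[..., None].astype(float)) \
        + Tensor(time_mask[..., None].astype(float)) * Tensor(mv)
    return out * Tensor(feat_keep[:, None, :])


# =============================================================================
# Fine-tuning variants
# =============================================================================


@dataclass(frozen=True)
class FineTuneSpec:
    """One of the six transfer configurations."""

    variant: int
    load_encoder: str           # 'pretrained' | 'random'
    load_contextualizer: str    # 'pretrained' | 'random' | 'absent'
    frozen: frozenset = frozenset()
    head: str = "start-token"   # 'start-token' | 'pooled'

    @staticmethod
    def for_variant(variant: int) -> "FineTuneSpec":
        table = {
            1: ("pretrained", "pretrained", frozenset(), "start-token"),
            2: ("pretrained", "absent", frozenset(), "pooled"),
            3: ("random", "absent", frozenset(), "pooled"),
            4: ("pretrained", "pretrained", frozenset({"encoder"}), "start-token"),
            5: ("random", "random", frozenset(), "start-token"),
            6: ("pretrained", "absent", frozenset({"encoder"}), "pooled"),
        }
        if variant not in table:
            raise ValueError(f"variant must be 1-6, got {variant}")
        enc, ctx, frozen, head = table[variant]
        return FineTuneSpec(variant=variant, load_encoder=enc,
                            load_contextualizer=ctx, frozen=frozen, head=head)


class FineTuneModel(nn.Module):
    """Assembled downstream classifier for one FineTuneSpec."""

    def __init__(self, spec: FineTuneSpec, enc_cfg: EncoderConfig,
                 ctx_cfg: ContextualizerConfig, n_classes: int,
                 rng: np.random.Generator,
                 reg_cfg: DownstreamRegConfig = DownstreamRegConfig()):
        self.spec = spec
        self.reg_cfg = reg_cfg
        self.n_classes = n_classes
        self.encoder = ConvEncoder(enc_cfg, rng)
        self.contextualizer = (Contextualizer(ctx_cfg, rng)
                               if spec.load_contextualizer != "absent" else None)
        d = enc_cfg.filters
        d_head = d if spec.head == "start-token" else 4 * d
        self.head = nn.Linear(d_head, n_classes, rng)
        # frozen mask vector used for downstream span masking (zeros when
        # training from scratch, overwritten by checkpoint loading)
        self._reg_mask_vector = np.zeros(d)

    def trainable_parameters(self) -> dict[str, nn.Parameter]:
        params = {}
        for name, p in self.parameters().items():
            tree = name.split(".", 1)[0]
            if tree not in self.spec.frozen:
                params[name] = p
        return params

    def __call__(self, batch: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a batch (B, 20, T); ``rng`` enables train-mode
        regularization."""
        b = self.encoder(Tensor(np.asarray(batch, dtype=np.float64)))
        if rng is not None:
            b = downstream_regularize(b, self._reg_mask_vector, self.reg_cfg,
                                      rng)
        if self.spec.head == "start-token":
            q = prepend_start_token(b, self.contextualizer.cfg.start_token_value)
            # LayerDrop/dropout are pre-training-only: always eval-mode here
            out = self.contextualizer(q, rng=None)
            feats = out.start_out
        else:
            feats = pooled_linear_head(b)
        return self.head(feats)


def build_finetune_model(variant: int, enc_cfg: EncoderConfig,
                         ctx_cfg: ContextualizerConfig, n_classes: int,
                         checkpoint_path=None, seed: int = 0,
                         reg_cfg: DownstreamRegConfig = DownstreamRegConfig()
                         ) -> FineTuneModel:
    """Assemble a downstream model for one of the six variants.

    Variants 1, 2, 4, 6 require a pre-trained checkpoint; 3 and 5 forbid one.
    """
    spec = FineTuneSpec.for_variant(variant)
    needs_ckpt = "pretrained" in (spec.load_encoder, spec.load_contextualizer)
    if needs_ckpt and checkpoint_path is None:
        raise ValueError(f"variant {variant} requires a pre-trained checkpoint")
    if not needs_ckpt and checkpoint_path is not None:
        raise ValueError(f"variant {variant} trains from scratch; "
                         "a checkpoint must not be supplied")
    rng = np.random.default_rng(seed)
    model = FineTuneModel(spec, enc_cfg, ctx_cfg, n_classes, rng, reg_cfg)
    if needs_ckpt:
        trees, _ = BendrModel.load_trees(checkpoint_path)
        if spec.load_encoder == "pretrained":
            model.encoder.load_state_dict(trees["encoder"])
        if spec.load_contextualizer == "pretrained":
            model.contextualizer.load_state_dict(trees["contextualizer"])
        model._reg_mask_vector = np.asarray(
            trees["contextualizer"]["mask_vector"], dtype=np.float64)
    return model


# =============================================================================
# Balancing, metrics
# =============================================================================


def undersample_epoch(labels: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-epoch balanced index multiset: the minority class contributes all
    its points; every other class contributes n_min uniform draws with
    replacement."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("undersampling needs at least two nonempty classes")
    n_min = counts.min()
    picked = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if count == n_min:
            picked.append(idx)
        else:
            picked.append(rng.choice(idx, size=n_min, replace=True))
    out = np.concatenate(picked)
    rng.shuffle(out)
    return out


def metric(y_true: np.ndarray, y_pred: np.ndarray, kind: str,
           scores: np.ndarray | None = None) -> float:
    """BAC (mean per-class recall), accuracy, or binary AUROC in [0, 1]."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2 and kind in ("BAC", "AUROC"):
        raise UndefinedMetricError(f"{kind} undefined on a single-class fold")
    if kind == "BAC":
        return float(balanced_accuracy_score(y_true, y_pred))
    if kind == "accuracy":
        return float(accuracy_score(y_true, y_pred))
    if kind == "AUROC":
        if scores is None:
            raise ValueError("AUROC requires class-1 scores")
        return float(roc_auc_score(y_true, scores))
    raise ValueError(f"unknown metric kind {kind!r}")


def normalize_metric(value: float, chance_level: float) -> float:
    """Affine rescale: chance -> 0, perfect -> 1 (below-chance is negative)."""
    if chance_level >= 1.0:
        raise ValueError("chance level must be < 1")
    return (value - chance_level) / (1.0 - chance_level)


def bootstrap_ci(values: np.ndarray, rng: np.random.Generator,
                 n_boot: int = 1000, level: float = 0.95
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean."""
    values = np.asarray(values, dtype=float)
    means = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)), float(np.quantile(means, 1.0 - lo)))


# =============================================================================
# Fine-tuning loop
# =============================================================================


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 20
    batch_size: int = 16
    peak_lr: float = 5e-5
    weight_decay: float = 0.01
    warmup_frac: float = 0.10
    n_bootstrap: int = 1000
    metric_kind: str = "BAC"
    seed: int = 0


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n = logits.shape[0]
    lse = logits.logsumexp(axis=-1)
    picked = logits[np.arange(n), np.asarray(labels)]
    return (lse - picked).mean()


def finetune(model: FineTuneModel, X: np.ndarray, y: np.ndarray,
             cfg: FinetuneConfig) -> list[float]:
    """Train one fold; returns per-epoch mean training losses."""
    rng = np.random.default_rng(cfg.seed)
    params = model.trainable_parameters()
    opt = nn.Adam(params, lr=cfg.peak_lr, weight_decay=cfg.weight_decay)
    n_per_epoch = len(np.unique(y)) * np.bincount(np.asarray(y)).min()
    steps_per_epoch = max(1, int(np.ceil(n_per_epoch / cfg.batch_size)))
    sched = PretrainConfig(total_steps=cfg.epochs * steps_per_epoch,
                           peak_lr=cfg.peak_lr, warmup_frac=cfg.warmup_frac)
    step = 0
    losses = []
    for _ in range(cfg.epochs):
        order = undersample_epoch(y, rng)
        epoch_losses = []
        for k in range(0, len(order), cfg.batch_size):
            take = order[k:k + cfg.batch_size]
            logits = model(X[take], rng=rng)
            loss = _cross_entropy(logits, y[take])
            for p in params.values():
                p.grad = None
            loss.backward()
            opt.step(lr=lr_schedule(step, sched))
            step += 1
            epoch_losses.append(float(loss.data))
        losses.append(float(np.mean(epoch_losses)))
    return losses


def predict(model: FineTuneModel, X: np.ndarray,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode class predictions and softmax probabilities."""
    probs = []
    for k in range(0, len(X), batch_size):
        logits = model(X[k:k + batch_size], rng=None)
        probs.append(logits.softmax(axis=-1).data)
    probs = np.concatenate(probs, axis=0)
    return probs.argmax(axis=1), probs


def make_subject_folds(subjects: np.ndarray, n_folds: int) -> list[np.ndarray]:
    """Partition unique subjects into n_folds contiguous groups (sessions of
    a subject always travel together)."""
    uniq = np.unique(subjects)
    return [arr for arr in np.array_split(uniq, n_folds) if arr.size]


def run_finetune(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                 variant: int, enc_cfg: EncoderConfig,
                 ctx_cfg: ContextualizerConfig, cfg: FinetuneConfig,
                 checkpoint_path=None, n_folds: int = 2,
                 reg_cfg: DownstreamRegConfig = DownstreamRegConfig()
                 ) -> tuple[pd.DataFrame, dict]:
    """Leave-subjects-out fine-tuning for one variant.

    Returns (per-subject metric table, summary with mean/CI), where the table
    has columns (variant, fold, subject, metric, value, normalized).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    classes = np.unique(y)
    n_classes = len(classes)
    chance = 0.5 if cfg.metric_kind == "AUROC" else 1.0 / n_classes
    y_idx = np.searchsorted(classes, y)
    folds = make_subject_folds(subjects, n_folds)
    rows = []
    for fold_i, test_subjects in enumerate(folds):
        test_mask = np.isin(subjects, test_subjects)
        model = build_finetune_model(
            variant, enc_cfg, ctx_cfg, n_classes,
            checkpoint_path=checkpoint_path, seed=cfg.seed + fold_i,
            reg_cfg=reg_cfg)
        finetune(model, X[~test_mask], y_idx[~test_mask], cfg)
        for subject in test_subjects:
            sm = subjects == subject
            yp, probs = predict(model, X[sm])
            try:
                value = metric(y_idx[sm], yp, cfg.metric_kind,
                               scores=probs[:, 1] if n_classes == 2 else None)
            except UndefinedMetricError:
                logger.info("fold %d subject %s: single-class test set, "
                            "skipped", fold_i, subject)
                continue
            rows.append({"variant": variant, "fold": fold_i,
                         "subject": subject, "metric": cfg.metric_kind,
                         "value": value,
                         "normalized": normalize_metric(value, chance)})
    table = pd.DataFrame(rows)
    rng = np.random.default_rng(cfg.seed)
    values = table["value"].to_numpy() if len(table) else np.array([np.nan])
    ci = bootstrap_ci(values, rng, n_boot=cfg.n_bootstrap)
    summary = {"variant": variant, "metric": cfg.metric_kind,
               "mean": float(np.mean(values)), "ci_low": ci[0],
               "ci_high": ci[1], "chance": chance, "n_subjects": len(table)}
    return table, summary
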