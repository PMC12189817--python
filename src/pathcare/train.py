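"""Losses, two-stage optimization, early stopping, reproducibility.

Training is two-stage by default, in the spirit of pretrained language
models supplying contextual features to a downstream task:

* **Stage 1** (``pretrain_future``) optimizes only the auxiliary branch on
  the self-supervised next-visit loss ``L_future``; the checkpoint with
  the lowest validation ``L_future`` is kept.
* **Stage 2** (``train_target``) freezes the auxiliary branch and
  optimizes everything else on ``L_total = L_task + α·L_decorrelation``,
  with early stopping on validation AUPRC.

A ``joint`` stage trains everything at once on
``L_task + α·L_decorrelation + L_future`` for comparison.

Optimization uses Adam with decoupled weight decay, a linear-warmup +
cosine-decay learning-rate schedule, and global-norm gradient clipping.
All randomness derives from the configs, so identical configs give
identical logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .autograd import Tensor, zero_grads
from .data import Batch, Cohort, batch_cohort
from .model import (ModelConfig, ModelParams, concat, decorrelation_loss,
                    forward)

logger = logging.getLogger(__name__)

STAGES = ("pretrain_future", "train_target", "joint")
_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10           # epochs without val improvement
    lr: float = 0.001
    warmup_epochs: int = 5
    schedule: str = "warmup_cosine"
    alpha: float = 0.1
    weight_decay: float = 0.01
    clip_norm: float = 5.0
    seed: int = 42
    stage: str = "train_target"
    task: str = "mortality"

    def __post_init__(self):
        if min(self.batch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("batch_size, max_epochs, patience must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.lr <= 0 or self.alpha < 0 or self.weight_decay < 0:
            raise ValueError("lr > 0, alpha >= 0, weight_decay >= 0 required")
        if self.schedule != "warmup_cosine":
            raise ValueError("only the warmup_cosine schedule is supported")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")


@dataclass
class TrainLog:
    """Per-epoch training record; serializes to a delimited text table."""

    entries: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1

    def append(self, **kwargs) -> None:
        for k, v in kwargs.items():
            if k != "epoch" and not np.isfinite(v):
                raise TrainingDivergedError(f"non-finite {k} at epoch "
                                            f"{kwargs.get('epoch')}")
        if self.entries and kwargs["epoch"] <= self.entries[-1]["epoch"]:
            raise ValueError("epoch index must increase")
        self.entries.append(dict(kwargs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def column(self, name: str) -> np.ndarray:
        return np.array([e[name] for e in self.entries])


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def future_loss(r_hat_seq: List[Tensor], r_seq: np.ndarray,
                lengths: np.ndarray) -> Tensor:
    """Self-supervised next-visit loss.

    Per patient: (1/T) Σ_{t=1}^{T-1} MSE(r̂_{t+1}, r_{t+1}), MSE averaged
    over the Nr features.  The prefactor is 1/T (not 1/(T-1)).  Patients
    with a single visit contribute no supervised pair and are excluded;
    padding never contributes.  Batch value = mean over included patients.
    """
    lengths = np.asarray(lengths)
    included = lengths >= 2
    if not included.any():
        raise ValueError("future loss needs at least one patient with T >= 2")
    B = len(lengths)
    acc: Optional[Tensor] = None
    T = r_seq.shape[1]
    for t in range(T - 1):
        valid = (lengths >= t + 2).astype(np.float64)
        if not valid.any():
            break
        diff = r_hat_seq[t] - r_seq[:, t + 1, :]
        per_patient = (diff ** 2).mean(axis=1) * valid
        acc = per_patient if acc is None else acc + per_patient
    per_patient_loss = acc * (included / np.maximum(lengths, 1))
    return per_patient_loss.sum() / float(included.sum())


def task_loss(y_hat: Tensor, y: np.ndarray) -> Tensor:
    """Binary cross-entropy over the batch; ŷ clamped to [ε, 1-ε]."""
    y = np.asarray(y, dtype=np.float64)
    n_clamped = int(((y_hat.data <= _EPS) | (y_hat.data >= 1 - _EPS)).sum())
    if n_clamped:
        logger.warning("clamped %d predicted probabilities to [%g, %g]",
                       n_clamped, _EPS, 1 - _EPS)
    p = y_hat.clip(_EPS, 1.0 - _EPS)
    ll = p.log() * y + (1.0 - p).log() * (1.0 - y)
    return -ll.mean()


def total_loss(L_task, L_decorrelation, alpha: float):
    """L_total = L_task + α·L_decorrelation."""
    return L_task + alpha * L_decorrelation


def lr_at(step: float, config: TrainConfig) -> float:
    """Learning rate at a (fractional) epoch index.

    Linear ramp 0 → lr over the warmup epochs, then half-cosine decay to
    0 at ``max_epochs``.
    """
    w, m, lr = config.warmup_epochs, config.max_epochs, config.lr
    if step <= w:
        return lr * step / w
    frac = (step - w) / (m - w)
    return lr * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay and global-norm gradient clipping."""

    def __init__(self, params: List[Tuple[str, Tensor]],
                 weight_decay: float = 0.01, clip_norm: float = 5.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in params}
        self.v = {n: np.zeros_like(p.data) for n, p in params}

    def step(self, lr: float) -> None:
        grads = {n: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for n, p in self.params}
        gnorm = np.sqrt(sum((g ** 2).sum() for g in grads.values()))
        scale = min(1.0, self.clip_norm / (gnorm + 1e-12))
        self.t += 1
        for n, p in self.params:
            g = grads[n] * scale
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * g
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * g * g
            mhat = self.m[n] / (1 - self.b1 ** self.t)
            vhat = self.v[n] / (1 - self.b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.weight_decay * p.data)


# ---------------------------------------------------------------------------
# epoch helpers
# ---------------------------------------------------------------------------

def _epoch_batches(cohort: Cohort, split: str, config: TrainConfig,
                   epoch: int) -> List[Batch]:
    # deterministic reshuffle each epoch, derived from the config seed
    return list(batch_cohort(cohort, split, config.batch_size,
                             shuffle_seed=(config.seed * 1000003 + epoch)
                             % (2 ** 31)))


def eval_future_loss(params: ModelParams, cohort: Cohort, split: str,
                     config: TrainConfig) -> float:
    """Mean next-visit loss of the current parameters on one split."""
    from .model import encode_future, predict_next_visit
    vals = []
    for batch in batch_cohort(cohort, split, config.batch_size):
        hf = encode_future(params, batch)
        r_hat = [predict_next_visit(params, h) for h in hf]
        vals.append(future_loss(r_hat, batch.values, batch.lengths).data)
    return float(np.mean(vals))


def predict_scores(params: ModelParams, cohort: Cohort, split: str,
                   batch_size: int = 256,
                   variant: Optional[str] = None
                   ) -> Tuple[np.ndarray, List[str]]:
    """Predicted outcome probabilities for one split (cohort order)."""
    scores, ids = [], []
    for batch in batch_cohort(cohort, split, batch_size):
        diag = forward(params, batch, variant=variant)
        scores.append(diag.y_hat.data)
        ids.extend(diag.patient_ids)
    return np.concatenate(scores), ids


def _split_labels(cohort: Cohort, split: str, task: str) -> np.ndarray:
    return np.array([p.labels[task] for p in cohort.patients_in(split)])


def _decorrelation_term(diag, joint: bool) -> Tensor:
    """Decorrelation penalty: separately on g_future and g_task batches
    (summed), or jointly on their concatenation when configured."""
    if diag.g_future is None:
        return decorrelation_loss(diag.g_task)
    if joint:
        return decorrelation_loss(concat([diag.g_future, diag.g_task],
                                         axis=1))
    return (decorrelation_loss(diag.g_future)
            + decorrelation_loss(diag.g_task))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def pretrain_future(cohort: Cohort, model_config: ModelConfig,
                    train_config: TrainConfig
                    ) -> Tuple[ModelParams, TrainLog]:
    """Stage 1: optimize the auxiliary branch on L_future only.

    Trains on the train split; keeps the checkpoint with the lowest
    validation L_future; stops after ``patience`` epochs without
    improvement.
    """
    from .model import encode_future, predict_next_visit
    params = ModelParams(model_config)
    opt = AdamW(params.group(*ModelParams.FUTURE_GROUP),
                train_config.weight_decay, train_config.clip_norm)
    log = TrainLog()
    best = np.inf
    best_state = params.state_dict()
    stall = 0
    for epoch in range(train_config.max_epochs):
        lr = lr_at(epoch + 1, train_config)
        ep_losses = []
        for batch in _epoch_batches(cohort, "train", train_config, epoch):
            hf = encode_future(params, batch)
            r_hat = [predict_next_visit(params, h) for h in hf]
            loss = future_loss(r_hat, batch.values, batch.lengths)
            zero_grads([t for _, t in opt.params])
            loss.backward()
            opt.step(lr)
            ep_losses.append(float(loss.data))
        val = eval_future_loss(params, cohort, "val", train_config)
        log.append(epoch=epoch, lr=lr, L_future=float(np.mean(ep_losses)),
                   L_task=0.0, L_decorrelation=0.0, L_total=0.0,
                   val_metric=val)
        if val < best - 1e-12:
            best, best_state, stall = val, params.state_dict(), 0
            log.best_epoch = epoch
        else:
            stall += 1
            if stall >= train_config.patience:
                break
    params.load_state_dict(best_state)
    return params, log


def train_target(cohort: Cohort, future_params: Optional[ModelParams],
                 model_config: ModelConfig, train_config: TrainConfig
                 ) -> Tuple[ModelParams, TrainLog]:
    """Stage 2 (or joint): optimize the target objective.

    Two-stage (default): the future branch is copied from
    ``future_params`` and frozen; only the task encoder, projections,
    gate and head train on L_task + α·L_decorrelation.  ``stage="joint"``
    trains every parameter on L_task + α·L_decorrelation + L_future.
    Early stopping and checkpoint selection use validation AUPRC.
    """
    joint = train_config.stage == "joint"
    params = ModelParams(model_config)
    if future_params is not None:
        state = params.state_dict()
        donor = future_params.state_dict()
        for name in state:
            if name.startswith(ModelParams.FUTURE_GROUP):
                state[name] = donor[name]
        params.load_state_dict(state)
    needs_future = model_config.variant != "context_minus"
    if needs_future and future_params is None and not joint:
        raise ValueError("two-stage training needs pretrained future params")

    groups = (ModelParams.FUTURE_GROUP + ModelParams.TARGET_GROUP
              if joint else ModelParams.TARGET_GROUP)
    opt = AdamW(params.group(*groups), train_config.weight_decay,
                train_config.clip_norm)
    task = train_config.task
    alpha = train_config.alpha
    log = TrainLog()
    best = -np.inf
    best_state = params.state_dict()
    stall = 0
    val_labels = _split_labels(cohort, "val", task)
    for epoch in range(train_config.max_epochs):
        lr = lr_at(epoch + 1, train_config)
        ep = {"L_task": [], "L_decorrelation": [], "L_total": [],
              "L_future": []}
        for batch in _epoch_batches(cohort, "train", train_config, epoch):
            diag = forward(params, batch)
            L_t = task_loss(diag.y_hat, batch.labels[task])
            L_d = _decorrelation_term(diag, model_config.joint_decorrelation)
            loss = total_loss(L_t, L_d, alpha)
            L_f = 0.0
            if joint and diag.r_hat_seq is not None:
                Lf = future_loss(diag.r_hat_seq, batch.values, batch.lengths)
                loss = loss + Lf
                L_f = float(Lf.data)
            zero_grads([t for _, t in opt.params])
            loss.backward()
            opt.step(lr)
            ep["L_task"].append(float(L_t.data))
            ep["L_decorrelation"].append(float(L_d.data))
            ep["L_total"].append(float(L_t.data) + alpha * float(L_d.data))
            ep["L_future"].append(L_f)
        scores, _ = predict_scores(params, cohort, "val",
                                   train_config.batch_size)
        val_auprc = _metrics.auprc(val_labels, scores)
        log.append(epoch=epoch, lr=lr,
                   L_future=float(np.mean(ep["L_future"])),
                   L_task=float(np.mean(ep["L_task"])),
                   L_decorrelation=float(np.mean(ep["L_decorrelation"])),
                   L_total=float(np.mean(ep["L_total"])),
                   val_metric=val_auprc)
        if val_auprc > best + 1e-12:
            best, best_state, stall = val_auprc, params.state_dict(), 0
            log.best_epoch = epoch
        else:
            stall += 1
            if stall >= train_config.patience:
                break
    params.load_state_dict(best_state)
    return params, log


def fit(cohort: Cohort, model_config: ModelConfig,
        train_config: TrainConfig
        ) -> Tuple[ModelParams, Dict[str, TrainLog]]:
    """End-to-end training for any variant.

    Runs stage 1 then stage 2 for variants with a future branch (or a
    single joint stage when requested); ``context_minus`` skips
    pretraining entirely.
    """
    logs: Dict[str, TrainLog] = {}
    if model_config.variant == "context_minus":
        params, logs["target"] = train_target(cohort, None, model_config,
                                              train_config)
        return params, logs
    if train_config.stage == "joint":
        params, logs["target"] = train_target(cohort, None, model_config,
                                              train_config)
        return params, logs
    stage1 = TrainConfig(**{**train_config.__dict__,
                            "stage": "pretrain_future"})
    future_params, logs["future"] = pretrain_future(cohort, model_config,
                                                    stage1)
    params, logs["target"] = train_target(cohort, future_params,
                                          model_config, train_config)
    return params, logs
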