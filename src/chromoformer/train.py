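"""Training loop, losses, optimizer schedule, metrics and cross-validation.

The published protocol: 10 epochs of AdamW (decoupled weight decay) starting
at lr 3e-5 with a 13% multiplicative decay per epoch (so the rate roughly
halves every five epochs), batch size 64, cross-entropy for classification
and MSE for the regression variants, and the *last* epoch's weights as the
final model (no early stopping). Evaluation is under chromosome-disjoint
k-fold cross-validation so no chromosome contributes to both training and
validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    r2_score,
    roc_auc_score,
)

from .autodiff import Parameter, Tensor
from .io_features import Dataset, InputError, TrainingExample
from .model import Chromoformer, ChromoformerDiff, ForwardOutput, ModelConfig

__all__ = [
    "TrainConfig",
    "AdamW",
    "cross_entropy",
    "mse_loss",
    "collate",
    "train",
    "evaluate",
    "run_cv",
    "EvalReport",
    "CvResult",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    lr0: float = 3e-5
    lr_decay: float = 0.87  # multiplicative per-epoch step (a 13% decrease)
    batch_size: int = 64
    weight_decay: float = 0.01
    grad_clip: float | None = None
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise InputError("epochs must be >= 1")
        if not (0.0 < self.lr_decay < 1.0):
            raise InputError("lr_decay must be in (0, 1)")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for 0-based epoch index: lr0 * decay**epoch."""
        return self.lr0 * self.lr_decay**epoch


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            p.data = p.data - self.lr * (update + self.weight_decay * p.data)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    m = logits.data.max(axis=-1, keepdims=True)  # constant shift for stability
    z = logits - m
    log_norm = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - log_norm
    picked = logp[np.arange(len(labels)), np.asarray(labels, dtype=np.int64)]
    return -picked.mean()


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.reshape(pred.shape[0]) - np.asarray(target, dtype=np.float64)
    return (diff * diff).mean()


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

def collate(examples: Sequence[TrainingExample], resolutions: Sequence[int]) -> dict:
    """Stack per-gene arrays into one batch dict consumed by the model."""
    return {
        "promoters": {r: np.stack([e.promoters[r] for e in examples]) for r in resolutions},
        "pcres": {r: np.stack([e.pcres[r] for e in examples]) for r in resolutions},
        "f": np.stack([e.f for e in examples]),
        "pad_mask": np.stack([e.pad_mask for e in examples]),
        "labels": np.array([e.label for e in examples]),
        "gene_ids": [e.gene_id for e in examples],
    }


def _batches(n: int, batch_size: int, order: np.ndarray):
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _loss_for(model, batch, task: str) -> Tensor:
    out: ForwardOutput = model(batch)
    if task == "clf":
        return cross_entropy(out.prediction, batch["labels"].astype(int))
    return mse_loss(out.prediction, batch["labels"])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    model: Chromoformer,
    train_set: Sequence[TrainingExample],
    config: TrainConfig,
    val_set: Sequence[TrainingExample] | None = None,
    task: str | None = None,
) -> list[dict]:
    """Run exactly ``config.epochs`` epochs and keep the last epoch's weights.

    The learning rate at 0-based epoch ``e`` is ``lr0 * lr_decay**e``.
    Returns the per-epoch history (lr, mean train loss, mean val loss).
    """
    task = task or model.config.task
    resolutions = model.config.resolutions
    opt = AdamW(model.parameters(), lr=config.lr0, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = []
    n = len(train_set)
    for epoch in range(config.epochs):
        opt.lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for bi, idx in enumerate(_batches(n, config.batch_size, order)):
            batch = collate([train_set[i] for i in idx], resolutions)
            model.zero_grad()
            loss = _loss_for(model, batch, task)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi} (lr={opt.lr:.3g})"
                )
            loss.backward()
            if config.grad_clip is not None:
                _clip_gradients(model.parameters(), config.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if val_set:
            record["val_loss"] = _mean_loss(model, val_set, config.batch_size, resolutions, task)
        history.append(record)
    return history


def _clip_gradients(params, max_norm: float):
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _mean_loss(model, examples, batch_size, resolutions, task) -> float:
    losses, weights = [], []
    for idx in _batches(len(examples), batch_size, np.arange(len(examples))):
        batch = collate([examples[i] for i in idx], resolutions)
        losses.append(float(_loss_for(model, batch, task).data))
        weights.append(len(idx))
    return float(np.average(losses, weights=weights))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    task: str
    metrics: dict
    predictions: pd.DataFrame  # gene_id, label, score (P(label=1) or predicted value)


def predict(
    model: Chromoformer,
    examples: Sequence[TrainingExample],
    batch_size: int = 64,
    collect_embeddings: bool = False,
) -> pd.DataFrame:
    """Per-gene predictions (and optionally the promoter / regulatory
    multi-resolution embedding vectors used for PCRI)."""
    resolutions = model.config.resolutions
    rows = []
    for idx in _batches(len(examples), batch_size, np.arange(len(examples))):
        batch = collate([examples[i] for i in idx], resolutions)
        out = model(batch)
        pred = out.prediction.data
        if model.config.task == "clf":
            z = pred - pred.max(axis=-1, keepdims=True)
            p = np.exp(z)
            score = (p / p.sum(axis=-1, keepdims=True))[:, 1]
        else:
            score = pred[:, 0]
        for j, gid in enumerate(batch["gene_ids"]):
            row = {"gene_id": gid, "label": batch["labels"][j], "score": float(score[j])}
            if collect_embeddings:
                row["promoter_vector"] = out.bundle["promoter_vector"][j].copy()
                row["regulatory_vector"] = out.bundle["regulatory_vector"][j].copy()
            rows.append(row)
    return pd.DataFrame(rows)


def evaluate(model: Chromoformer, val_set: Sequence[TrainingExample], task: str | None = None) -> EvalReport:
    """Validation metrics: ROC-AUC / accuracy / average precision for
    classification; Pearson r / R^2 / MSE for the regression variants."""
    task = task or model.config.task
    preds = predict(model, val_set)
    y, s = preds["label"].to_numpy(), preds["score"].to_numpy()
    metrics: dict = {}
    if task == "clf":
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn("single-class validation labels: ROC-AUC undefined")
            metrics["roc_auc"] = None
            metrics["average_precision"] = None
        else:
            metrics["roc_auc"] = float(roc_auc_score(y, s))
            metrics["average_precision"] = float(average_precision_score(y, s))
        metrics["accuracy"] = float(accuracy_score(y, (s > 0.5).astype(int)))
    else:
        metrics["mse"] = float(np.mean((s - y) ** 2))
        if np.std(y) > 0 and np.std(s) > 0:
            metrics["pearson_r"] = float(stats.pearsonr(y, s)[0])
        else:
            warnings.warn("constant labels or predictions: Pearson r undefined")
            metrics["pearson_r"] = None
        metrics["r2"] = float(r2_score(y, s))
    return EvalReport(task=task, metrics=metrics, predictions=preds)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    reports: list[EvalReport]
    oof_predictions: pd.DataFrame  # fold, gene_id, label, score (+ embeddings)
    models: list[Chromoformer] = field(default_factory=list)
    histories: list[list[dict]] = field(default_factory=list)

    def aggregate(self, metric: str) -> float:
        vals = [r.metrics[metric] for r in self.reports if r.metrics.get(metric) is not None]
        return float(np.mean(vals))


def run_cv(
    dataset: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    collect_embeddings: bool = True,
    keep_models: bool = True,
) -> CvResult:
    """Train one model per fold, validate on the held-out chromosomes, and
    collect per-gene out-of-fold predictions (with the embedding vectors the
    interpretation layer consumes, each gene scored by its own fold's model)."""
    reports, frames, models, histories = [], [], [], []
    for fold in range(dataset.folds.k):
        train_set, val_set = dataset.fold_split(fold)
        model = Chromoformer(
            _with_seed(model_config, model_config.seed + fold)
        )
        hist = train(model, train_set, train_config, task=dataset.task)
        report = evaluate(model, val_set, task=dataset.task)
        preds = predict(model, val_set, collect_embeddings=collect_embeddings)
        preds.insert(0, "fold", fold)
        reports.append(report)
        frames.append(preds)
        histories.append(hist)
        if keep_models:
            models.append(model)
    oof = pd.concat(frames, ignore_index=True)
    return CvResult(reports=reports, oof_predictions=oof, models=models, histories=histories)


def _with_seed(cfg: ModelConfig, seed: int) -> ModelConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Differential (Siamese) training
# ---------------------------------------------------------------------------

@dataclass
class DiffExample:
    """One gene featurized in two cell types, with fold-change target."""

    example_a: TrainingExample
    example_b: TrainingExample
    log2fc: float
    log2_expr_a: float
    log2_expr_b: float


def train_diff(
    model: ChromoformerDiff,
    train_set: Sequence[DiffExample],
    config: TrainConfig,
) -> list[dict]:
    """Train the Siamese variant: MSE on the fold-change plus the two
    auxiliary absolute-expression MSEs, equally weighted."""
    resolutions = model.config.resolutions
    opt = AdamW(model.parameters(), lr=config.lr0, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = []
    n = len(train_set)
    for epoch in range(config.epochs):
        opt.lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for bi, idx in enumerate(_batches(n, config.batch_size, order)):
            items = [train_set[i] for i in idx]
            batch_a = collate([d.example_a for d in items], resolutions)
            batch_b = collate([d.example_b for d in items], resolutions)
            model.zero_grad()
            fc, aux_a, aux_b = model(batch_a, batch_b)
            loss = (
                mse_loss(fc, np.array([d.log2fc for d in items]))
                + mse_loss(aux_a, np.array([d.log2_expr_a for d in items]))
                + mse_loss(aux_b, np.array([d.log2_expr_b for d in items]))
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi} (lr={opt.lr:.3g})"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))})
    return history
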