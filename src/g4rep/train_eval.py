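"""Training loop and binary-classification evaluation.

Training minimises binary cross-entropy with the Adam optimiser; progress is
monitored on a validation split with early stopping on validation loss, and
the parameters at the best validation loss are returned.  Evaluation reports
the confusion matrix at a decision threshold plus accuracy, precision,
recall, F1 and a rank-based AUROC (the probability that a random positive
outscores a random negative, ties counted half).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import autodiff as ad
from .autodiff import Tensor
from .encode import EncodedSequence, iter_batches, make_batch
from .models import BindingPrediction, ModelConfig, forward_scores, init_params

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 1400  # top of the one-hot training range; 400 for embeddings
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.early_stop_patience < 0:
            raise ValueError("early_stop_patience must be >= 0")


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    auroc: float | None
    threshold: float = 0.5

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def bce_loss(scores, labels) -> float:
    """Mean binary cross-entropy, with probabilities clamped away from 0/1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    p = np.clip(scores, _EPS, 1.0 - _EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def _bce_tensor(scores: Tensor, labels: np.ndarray) -> Tensor:
    y = np.asarray(labels, dtype=float)
    p = ad.clip(scores, _EPS, 1.0 - _EPS)
    one_minus_p = ad.sub(Tensor(1.0), p)
    nll = ad.add(
        ad.mul(Tensor(y), ad.log(p)),
        ad.mul(Tensor(1.0 - y), ad.log(one_minus_p)),
    )
    return ad.mul(ad.tmean(nll), Tensor(-1.0))


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _epoch_loss(cfg: ModelConfig, params: dict[str, Tensor],
                items: list[EncodedSequence], batch_size: int) -> float:
    total, n = 0.0, 0
    for batch in iter_batches(items, batch_size):
        scores = forward_scores(cfg, params, batch).data
        total += bce_loss(scores, batch.labels) * len(batch)
        n += len(batch)
    return total / n


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_items: list[EncodedSequence],
    val_items: list[EncodedSequence],
    params: dict[str, Tensor] | None = None,
) -> tuple[dict[str, Tensor], list[dict]]:
    """Train a classifier; returns (best parameters, per-epoch history).

    "Best" means lowest validation loss.  Early stopping fires after
    ``early_stop_patience`` consecutive epochs without improvement; a
    non-finite loss aborts with a diagnostic.
    """
    if params is None:
        params = init_params(model_cfg)
    opt = Adam(params, train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)

    best_loss = np.inf
    best_params = {k: Tensor(v.data.copy()) for k, v in params.items()}
    since_improve = 0
    history: list[dict] = []

    for epoch in range(1, train_cfg.max_epochs + 1):
        epoch_seed = int(rng.integers(0, 2**31 - 1))
        running, n_seen = 0.0, 0
        for batch in iter_batches(
            train_items, train_cfg.batch_size, shuffle=True, seed=epoch_seed
        ):
            scores = forward_scores(model_cfg, params, batch)
            loss = _bce_tensor(scores, batch.labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}"
                )
            loss.backward()
            opt.step()
            running += float(loss.data) * len(batch)
            n_seen += len(batch)

        val_loss = _epoch_loss(model_cfg, params, val_items, train_cfg.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": running / n_seen, "val_loss": val_loss}
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: Tensor(v.data.copy()) for k, v in params.items()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > train_cfg.early_stop_patience:
                logger.info("early stop at epoch %d (best val loss %.4f)", epoch, best_loss)
                break
    return best_params, history


def predict(
    model_cfg: ModelConfig,
    params: dict[str, Tensor],
    items: list[EncodedSequence],
    batch_size: int = 16,
) -> list[BindingPrediction]:
    preds: list[BindingPrediction] = []
    for batch in iter_batches(items, batch_size):
        scores = forward_scores(model_cfg, params, batch).data
        preds.extend(
            BindingPrediction(sid, float(s)) for sid, s in zip(batch.seq_ids, scores)
        )
    return preds


def auroc_rank(scores, labels) -> float | None:
    """Rank-based AUROC (Mann-Whitney): P(random positive > random negative),
    ties counted half.  ``None`` (with a warning) when only one class present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUROC undefined: only one class present")
        return None
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics_from_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    calls = (scores >= threshold).astype(int)
    tp = int(((calls == 1) & (labels == 1)).sum())
    tn = int(((calls == 0) & (labels == 0)).sum())
    fp = int(((calls == 1) & (labels == 0)).sum())
    fn = int(((calls == 0) & (labels == 1)).sum())
    total = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision and recall and (precision + recall) > 0
        else None
    )
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        precision=precision, recall=recall, f1=f1,
        auroc=auroc_rank(scores, labels),
        threshold=threshold,
    )


def evaluate(
    params: dict[str, Tensor],
    model_cfg: ModelConfig,
    items: list[EncodedSequence],
    threshold: float = 0.5,
    batch_size: int = 16,
) -> MetricsReport:
    if any(e.label is None for e in items):
        raise ValueError("evaluate requires labelled inputs")
    preds = predict(model_cfg, params, items, batch_size)
    scores = np.array([p.score_B for p in preds])
    labels = np.array([e.label for e in items])
    return metrics_from_scores(scores, labels, threshold)


def write_history_csv(history: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for row in history:
            fh.write(f"{row['epoch']},{row['train_loss']:.6f},{row['val_loss']:.6f}\n")
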