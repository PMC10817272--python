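"""Dataset splitting, training with early stopping, and evaluation.

Splits are patient-level 8:1:1 (train/validation/test) with a seeded
shuffle. Training minimises binary cross-entropy with Adam and stops when
validation AUROC has not improved for `patience` consecutive epochs,
returning the best-validation checkpoint. Metrics follow the usual
reporting: AUROC on validation and test, precision/recall/F1 on test at a
0.5 threshold, aggregated over repeated runs as per-repeat values plus mean
and sample (n-1) standard deviation.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from ._nn import Adam, Tensor
from .encoding import EncodedSample
from .models import make_batch

__all__ = ["SplitSpec", "split", "train", "evaluate", "repeat_runs",
           "metrics_table"]

METRIC_NAMES = ["validation_auroc", "test_auroc", "test_precision",
                "test_recall", "test_f1"]


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0


def split(samples: Sequence, spec: SplitSpec | None = None,
          ) -> tuple[list, list, list]:
    """Seeded 8:1:1 partition: floor(0.8 n) / floor(0.1 n) / remainder."""
    spec = spec or SplitSpec()
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples to split 8:1:1")
    total = sum(spec.ratios)
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(n * spec.ratios[0] / total)
    n_val = int(n * spec.ratios[1] / total)
    items = [samples[i] for i in order]
    return (items[:n_train], items[n_train : n_train + n_val],
            items[n_train + n_val :])


def _bce(p: Tensor, y: np.ndarray, eps: float = 1e-9) -> Tensor:
    pc = p * (1.0 - 2.0 * eps) + eps
    loss = -(y * pc.log() + (1.0 - y) * (1.0 - pc).log())
    return loss.mean()


def train(model, train_set: Sequence[EncodedSample],
          val_set: Sequence[EncodedSample], *, patience: int = 3,
          max_epochs: int = 30, lr: float = 3e-3, batch_size: int = 128,
          seed: int = 0) -> tuple[object, pd.DataFrame]:
    """Early-stopped Adam training; returns (best model, epoch history)."""
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    opt = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed)
    y_train = np.array([s.y for s in train_set], dtype=float)

    best_auc, best_state, since_best = -np.inf, model.get_state(), 0
    history = []
    for epoch in range(max_epochs):
        order = rng.permutation(len(train_set))
        losses = []
        model.train(True)
        for k in range(0, len(order), batch_size):
            sel = order[k : k + batch_size]
            batch = make_batch([train_set[i] for i in sel])
            p = model.forward_batch(batch, training=True)
            loss = _bce(p, y_train[sel])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        val_auc = roc_auc_score([s.y for s in val_set],
                                model.predict_proba(val_set))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auroc": float(val_auc)})
        if val_auc > best_auc:
            best_auc, best_state, since_best = val_auc, model.get_state(), 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.set_state(best_state)
    model.eval()
    return model, pd.DataFrame(history)


def evaluate(scores_or_model, test_set: Sequence[EncodedSample],
             threshold: float = 0.5,
             val_set: Sequence[EncodedSample] | None = None) -> dict[str, float]:
    """AUROC (rank statistic, ties at 0.5) and thresholded precision/recall/F1.

    Accepts either a fitted model with `predict_proba` or a precomputed
    score vector. Raises when the test set has a single class.
    """
    y = np.array([s.y for s in test_set])
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: test set has a single class")
    if hasattr(scores_or_model, "predict_proba"):
        scores = np.asarray(scores_or_model.predict_proba(test_set))
    else:
        scores = np.asarray(scores_or_model)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, (scores >= threshold).astype(int), average="binary",
        zero_division=0.0)
    out = {"test_auroc": float(roc_auc_score(y, scores)),
           "test_precision": float(prec), "test_recall": float(rec),
           "test_f1": float(f1)}
    if val_set is not None and hasattr(scores_or_model, "predict_proba"):
        out["validation_auroc"] = float(roc_auc_score(
            [s.y for s in val_set], scores_or_model.predict_proba(val_set)))
    return out


def repeat_runs(pipeline: Callable[[int], dict[str, float]], k: int = 5,
                seeds: Sequence[int] | None = None) -> pd.DataFrame:
    """Run `pipeline(seed)` k times; rows = metrics, columns = repeats,
    Average and sample std — the usual repeated-metrics table layout."""
    if k < 2:
        raise ValueError("need k >= 2 repeats")
    seeds = list(seeds) if seeds is not None else list(range(k))
    if len(seeds) != k:
        raise ValueError("len(seeds) must equal k")
    rows = [pipeline(s) for s in seeds]
    return metrics_table(rows)


def metrics_table(rows: Sequence[dict[str, float]]) -> pd.DataFrame:
    """Per-repeat metric rows -> table with per-repeat columns, mean, sd."""
    names = [m for m in METRIC_NAMES if m in rows[0]] or sorted(rows[0])
    table = pd.DataFrame(
        {str(i + 1): [rows[i].get(m, np.nan) for m in names]
         for i in range(len(rows))}, index=names)
    table["Average"] = table.mean(axis=1)
    table["std.s"] = table.iloc[:, : len(rows)].std(axis=1, ddof=1)
    table.index.name = "metric"
    return table
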