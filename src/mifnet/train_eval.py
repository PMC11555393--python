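"""Training and evaluation of an assembled network on labelled patch sets.

Training follows the published regime: Xavier initialization, softmax
cross-entropy, mini-batches of 32, a constant learning rate of 0.001 and a
choice of ADAM / SGDM / RMSPROP.  Evaluation reports the confusion matrix,
the five standard metrics (accuracy, F1, precision, sensitivity,
specificity, in percent) and a per-sample (predicted label, confidence)
table.  The positive class is the malignant/nodule label (1), so
sensitivity is the nodule true-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import Network, make_optimizer


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class MetricsReport:
    """Confusion counts plus derived metrics (percent scale).

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    acc: Optional[float]
    f1: Optional[float]
    prec: Optional[float]
    sens: Optional[float]
    spec: Optional[float]
    predictions: List[Tuple[int, float]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def summary(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.2f}%"
        return (f"n={self.total}  TP={self.tp} FP={self.fp} "
                f"TN={self.tn} FN={self.fn}\n"
                f"Acc={fmt(self.acc)}  F1={fmt(self.f1)}  "
                f"Prec={fmt(self.prec)}  Sens={fmt(self.sens)}  "
                f"Spec={fmt(self.spec)}")

    def to_dict(self) -> Dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "acc": self.acc, "f1": self.f1, "prec": self.prec,
                "sens": self.sens, "spec": self.spec}


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int
                           ) -> MetricsReport:
    """Derive the five classification metrics from confusion counts.

    acc = (TP+TN)/N, prec = TP/(TP+FP), sens = TP/(TP+FN),
    spec = TN/(TN+FP), F1 = 2*prec*sens/(prec+sens); all in percent.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    acc = ratio(tp + tn, total)
    prec = ratio(tp, tp + fp)
    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, f1=f1,
                         prec=prec, sens=sens, spec=spec)


def _check_dataset(images: np.ndarray, labels: np.ndarray) -> None:
    if len(images) == 0:
        raise ValueError("empty dataset")
    bad = set(np.unique(labels)) - {0, 1}
    if bad:
        raise ValueError(f"labels must be binary (0/1), found {sorted(bad)}")


def train(network: Network, images: np.ndarray, labels: np.ndarray,
          config: TrainConfig) -> Dict[str, List[float]]:
    """Mini-batch training; returns per-epoch loss and error history.

    The batch order is drawn from ``config.seed``, so identical seeds, data
    and initialization reproduce identical histories bit for bit.
    """
    _check_dataset(images, labels)
    labels = np.asarray(labels, dtype=np.int64)
    optimizer = make_optimizer(config.optimizer, network.parameters(),
                               config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(images)
    history = {"loss": [], "error": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, wrong = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            network.zero_grad()
            loss, probs = network.loss_and_backward(images[idx], labels[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch + 1)
            optimizer.step()
            losses.append(loss * len(idx))
            wrong += int(np.sum(probs.argmax(axis=1) != labels[idx]))
        history["loss"].append(sum(losses) / n)
        history["error"].append(wrong / n)
    # freeze batch-norm statistics on the final weights before inference
    network.finalize_batchnorm(images)
    return history


def predict(network: Network, images: np.ndarray, batch_size: int = 64
            ) -> np.ndarray:
    """Per-class probabilities in inference mode (dropout off, BN running)."""
    chunks = [network.forward(images[i:i + batch_size], train=False)
              for i in range(0, len(images), batch_size)]
    return np.concatenate(chunks, axis=0)


def evaluate(network: Network, images: np.ndarray, labels: np.ndarray
             ) -> MetricsReport:
    """Confusion matrix, the five metrics, and per-sample predictions.

    Prediction is the argmax class; an exact probability tie goes to the
    positive class.
    """
    _check_dataset(images, labels)
    labels = np.asarray(labels, dtype=np.int64)
    probs = predict(network, images)
    pred = np.where(probs[:, 1] >= probs[:, 0], 1, 0)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    report = metrics_from_confusion(tp, fp, tn, fn)
    report.predictions = [(int(p), float(probs[i, p]))
                          for i, p in enumerate(pred)]
    return report
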