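"""Diagnostic evaluation metrics.

Implements the ratio metrics (accuracy, sensitivity, specificity, F1),
the rank-statistic AUC-ROC, mean squared error, discrete Kullback-Leibler
divergence and the Dice similarity coefficient.  Degenerate denominators
raise :class:`UndefinedMetricError` rather than silently returning 0, and
an absolute-continuity violation in the KL divergence signals ``inf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "ScoredLabels",
    "DiscreteDistributionPair",
    "UndefinedMetricError",
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f1",
    "auc_roc",
    "mse",
    "kl_divergence",
    "dice",
    "write_report",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero for the given inputs."""


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(bool)
        p = np.asarray(y_pred).astype(bool)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred must have equal length")
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )


@dataclass
class ScoredLabels:
    scores: np.ndarray
    truths: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.truths = np.asarray(self.truths).astype(int)
        if self.scores.shape != self.truths.shape:
            raise ValueError("scores and truths must have equal length")
        if not np.isin(self.truths, (0, 1)).all():
            raise ValueError("truths must be binary")


@dataclass
class DiscreteDistributionPair:
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.p.shape != self.q.shape:
            raise ValueError("p and q must share a support")
        for name, v in (("p", self.p), ("q", self.q)):
            if (v < 0).any():
                raise ValueError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")


def accuracy(cm: ConfusionMatrix) -> float:
    """Correct predictions over all predictions."""
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined for an empty matrix")
    return (cm.tp + cm.tn) / cm.total


def sensitivity(cm: ConfusionMatrix) -> float:
    """True-positive rate TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined without positives")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """True-negative rate TN / (TN + FP)."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined without negatives")
    return cm.tn / (cm.tn + cm.fp)


def precision(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("precision undefined without predicted positives")
    return cm.tp / (cm.tp + cm.fp)


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall."""
    p = precision(cm)
    r = sensitivity(cm)
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined when precision + recall = 0")
    return 2 * p * r / (p + r)


def auc_roc(data: ScoredLabels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(score+ > score-) + 0.5 P(tie); exact under ties, identical to
    trapezoidal integration of the empirical ROC curve.
    """
    pos = data.truths == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(data.scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def mse(y, y_hat) -> float:
    """Mean squared error (1/n) sum (y_i - yhat_i)^2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise UndefinedMetricError("MSE undefined for empty vectors")
    return float(np.mean((y - y_hat) ** 2))


def kl_divergence(pair: DiscreteDistributionPair) -> float:
    """Discrete KL divergence sum_x P(x) log[P(x)/Q(x)] (natural log).

    Terms with ``p = 0`` contribute zero; any support point with ``p > 0``
    but ``q = 0`` makes the divergence infinite.
    """
    p, q = pair.p, pair.q
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def dice(x_mask, y_mask) -> float:
    """Dice similarity 2|x n y| / (|x| + |y|) between binary masks."""
    x = np.asarray(x_mask).astype(bool)
    y = np.asarray(y_mask).astype(bool)
    if x.shape != y.shape:
        raise ValueError("mask shapes differ")
    denom = int(x.sum()) + int(y.sum())
    if denom == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks")
    return 2.0 * int(np.sum(x & y)) / denom


def write_report(metrics: dict, csv_path, json_path=None, cm: ConfusionMatrix | None = None) -> None:
    """Write an evaluation report as (metric, value) CSV plus JSON."""
    import json as _json

    import pandas as pd

    rows = dict(metrics)
    if cm is not None:
        rows.update({"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn})
    frame = pd.DataFrame({"metric": list(rows), "value": list(rows.values())})
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            _json.dump({k: (v if isinstance(v, (int, str)) else float(v)) for k, v in rows.items()}, fh, indent=2)
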