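"""Detector evaluation: per-class recall/precision, UAR and F1."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "evaluate"]


@dataclass
class EvalReport:
    tp: int
    fn: int
    fp: int
    tn: int
    recall_pos: float
    recall_neg: float
    uar: float  # unweighted average recall
    precision_pos: float
    precision_neg: float
    precision: float  # unweighted average precision
    f1: float  # harmonic mean of (unweighted) precision and recall
    f1_pos: float

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 as the harmonic mean of a precision and a recall value."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(predictions, labels, threshold: float | None = None) -> EvalReport:
    """Score binary predictions (or confidences, with ``threshold``) against labels.

    Recall and precision are reported per class and in an unweighted average
    over the positive and negative class; F1 is the harmonic mean of the two
    unweighted averages (the per-positive-class F1 is also reported).
    """
    preds = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if preds.size == 0 or y.size == 0:
        raise ValueError("empty predictions or labels")
    if preds.shape != y.shape:
        raise ValueError("predictions and labels must align")
    if threshold is not None:
        preds = (preds >= threshold).astype(np.int64)
    else:
        preds = preds.astype(np.int64)

    tp = int(np.sum((preds == 1) & (y == 1)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))

    recall_pos = _safe_div(tp, tp + fn)
    recall_neg = _safe_div(tn, tn + fp)
    uar = 0.5 * (recall_pos + recall_neg)
    precision_pos = _safe_div(tp, tp + fp)
    precision_neg = _safe_div(tn, tn + fn)
    uap = 0.5 * (precision_pos + precision_neg)
    return EvalReport(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        recall_pos=recall_pos,
        recall_neg=recall_neg,
        uar=uar,
        precision_pos=precision_pos,
        precision_neg=precision_neg,
        precision=uap,
        f1=harmonic_f1(uap, uar),
        f1_pos=harmonic_f1(precision_pos, recall_pos),
    )
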