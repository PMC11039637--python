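"""Confusion-count bookkeeping and evaluation formulas.

All rate metrics are returned on the percentage scale used throughout the
segmentation/classification literature (accuracy 80.0 means 80%).  Jaccard
and Dice are returned as proportions in ``[0, 1]``.

The published formulation this package follows contains evident typos in its
printed equations (an accuracy denominator missing FP; precision and
sensitivity duplicating the specificity formula; a Matthews-correlation
numerator of ``TP*TN - TP*FN``).  The standard textbook definitions are the
default; every affected function accepts ``as_printed=True`` to reproduce the
literal printed arithmetic for audit purposes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionCounts", "confusion", "accuracy", "specificity", "sensitivity",
    "precision", "f1", "mcc", "jaccard", "dice", "roc_auc", "metric_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isin(arr, (0, 1, True, False))):
        raise ValidationError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def confusion(pred: np.ndarray, true: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over pixels (masks) or samples (label vectors)."""
    p = _binary(pred, "pred")
    t = _binary(true, "true")
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs true {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def accuracy(c: ConfusionCounts, as_printed: bool = False) -> float:
    den = (c.tp + c.tn + c.fn) if as_printed else c.total
    if den == 0:
        raise UndefinedMetricError("accuracy undefined: zero total")
    return 100.0 * (c.tp + c.tn) / den


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: TN+FP is zero")
    return 100.0 * c.tn / (c.tn + c.fp)


def sensitivity(c: ConfusionCounts, as_printed: bool = False) -> float:
    if as_printed:
        return specificity(c)
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: TP+FN is zero")
    return 100.0 * c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts, as_printed: bool = False) -> float:
    if as_printed:
        return specificity(c)
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: TP+FP is zero")
    return 100.0 * c.tp / (c.tp + c.fp)


def f1(c: ConfusionCounts) -> float:
    p = precision(c)
    s = sensitivity(c)
    if p + s == 0:
        raise UndefinedMetricError("f1 undefined: precision + sensitivity is zero")
    return 2.0 * p * s / (p + s)


def mcc(c: ConfusionCounts, as_printed: bool = False) -> float:
    """Matthews correlation x 100; zero marginals return 0 with a warning."""
    marg = [(c.tp + c.fp), (c.tp + c.fn), (c.tn + c.fp), (c.tn + c.fn)]
    if any(m == 0 for m in marg):
        warnings.warn("MCC marginal is zero; returning 0 by convention", stacklevel=2)
        return 0.0
    num = c.tp * c.tn - (c.tp * c.fn if as_printed else c.fp * c.fn)
    den = np.sqrt(np.prod([float(m) for m in marg]))
    return 100.0 * num / den


def jaccard(pred: np.ndarray, true: np.ndarray, eps: float = 0.0) -> float:
    """Smoothed Jaccard ``(eps + |I|) / (eps + |P| + |T| - |I|)``."""
    p = _binary(pred, "pred")
    t = _binary(true, "true")
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs true {t.shape}")
    inter = float(np.sum(p & t))
    den = eps + p.sum() + t.sum() - inter
    if den == 0:
        return 1.0  # both masks empty, eps = 0: identical sets
    return (eps + inter) / den


def dice(pred: np.ndarray, true: np.ndarray, eps: float = 0.0) -> float:
    """Smoothed Dice ``(2|I| + eps) / (|P| + |T| + eps)``."""
    p = _binary(pred, "pred")
    t = _binary(true, "true")
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs true {t.shape}")
    inter = float(np.sum(p & t))
    den = float(p.sum() + t.sum()) + eps
    if den == 0:
        return 1.0
    return (2.0 * inter + eps) / den


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney) for the pipeline's own probability outputs."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _binary(labels, "labels").ravel()
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: one class is empty")
    order = scores.argsort(kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, scores.size + 1)
    # midranks for ties
    sorted_scores = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def metric_report(rows: list[dict]) -> pd.DataFrame:
    """Per-image table plus a mean/std summary row."""
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    numeric = df.select_dtypes("number")
    summary = numeric.mean().to_dict()
    std = numeric.std(ddof=0).add_suffix("_std").to_dict()
    mean_row = {"image": "mean", **summary}
    std_row = {"image": "std", **{k.removesuffix("_std"): v for k, v in std.items()}}
    return pd.concat([df, pd.DataFrame([mean_row, std_row])], ignore_index=True)
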