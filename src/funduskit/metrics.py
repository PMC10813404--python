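"""Classification and segmentation performance metrics.

Six metrics are computed from confusion counts: accuracy, precision,
recall, F1, Dice and the Jaccard coefficient.  Two Dice conventions are
supported: the default ``dice`` here is ``2TP / (2TP + FN)`` (no FP term),
with the conventional overlap coefficient ``2TP / (2TP + FP + FN)``
available via ``standard_dice=True``; both are reported side by side in
:func:`metric_suite`.

Multiclass results are tallied one-vs-rest per class plus a pooled
(micro) tally whose counts are the per-class sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Hashable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metric_suite",
    "macro_metrics",
    "mask_overlap",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tally of a classifier's decisions for one class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    y_pred: Sequence[Hashable],
    y_true: Sequence[Hashable],
    classes: Sequence[Hashable],
) -> Dict[Hashable, ConfusionCounts]:
    """One-vs-rest confusion counts per class, plus a pooled ``"micro"`` entry.

    Parameters
    ----------
    y_pred, y_true
        Equal-length label sequences.
    classes
        The admissible label set; a label outside it raises ``ValueError``.
    """
    y_pred = list(y_pred)
    y_true = list(y_true)
    if len(y_pred) != len(y_true):
        raise ValueError("prediction and truth lists differ in length")
    class_set = set(classes)
    for lab in list(y_pred) + list(y_true):
        if lab not in class_set:
            raise ValueError(f"label {lab!r} outside the class set")
    out: Dict[Hashable, ConfusionCounts] = {}
    totals = np.zeros(4, dtype=int)
    for c in classes:
        tp = sum(1 for p, t in zip(y_pred, y_true) if p == c and t == c)
        fp = sum(1 for p, t in zip(y_pred, y_true) if p == c and t != c)
        fn = sum(1 for p, t in zip(y_pred, y_true) if p != c and t == c)
        tn = len(y_true) - tp - fp - fn
        out[c] = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        totals += (tp, tn, fp, fn)
    out["micro"] = ConfusionCounts(*(int(v) for v in totals))
    return out


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        warnings.warn("zero denominator in metric; defining the metric as 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metric_suite(c: ConfusionCounts, standard_dice: bool = False) -> Dict[str, float]:
    """The six metrics for one confusion tally.

    ``dice`` defaults to ``2TP/(2TP+FN)``; pass ``standard_dice=True`` for
    the conventional ``2TP/(2TP+FP+FN)``.  Zero denominators yield 0 with a
    warning.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    if standard_dice:
        dice = _safe_div(2 * tp, 2 * tp + fp + fn)
    else:
        dice = _safe_div(2 * tp, 2 * tp + fn)
    return {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "f1": _safe_div(2 * precision * recall, precision + recall),
        "dice": dice,
        "jaccard": _safe_div(tp, tp + fn + fp),
    }


def macro_metrics(
    per_class: Mapping[Hashable, ConfusionCounts],
    standard_dice: bool = False,
) -> Dict[str, float]:
    """Macro-average the six metrics over the per-class tallies.

    The pooled ``"micro"`` entry, if present, is excluded from the average.
    Macro-F1 is the mean of the per-class ``2PR/(P+R)`` values; the halved
    summed variant ``(1/2)·Σ P·R/(P+R)`` is additionally reported as
    ``f1_paper`` (the two agree only in the single-class case).
    """
    keys = [k for k in per_class if k != "micro"]
    if not keys:
        raise ValueError("no per-class counts supplied")
    suites = [metric_suite(per_class[k], standard_dice=standard_dice) for k in keys]
    out = {m: float(np.mean([s[m] for s in suites])) for m in suites[0]}
    out["f1_paper"] = 0.5 * sum(s["f1"] / 2.0 for s in suites)  # (1/2)·Σ PR/(P+R)
    return out


def mask_overlap(pred: np.ndarray, truth: np.ndarray) -> Dict[str, float]:
    """Pixel-level overlap metrics between two binary masks.

    Returns the full suite with the conventional Dice (FP included), which
    is the appropriate overlap measure for segmentation masks.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return metric_suite(ConfusionCounts(tp, tn, fp, fn), standard_dice=True)
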