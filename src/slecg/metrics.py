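"""Confusion-matrix metrics and trapezoidal AUROC.

AFib is the positive class throughout: sensitivity = TP/(TP+FN) is the
fraction of AFib records caught, specificity = TN/(TN+FP) the fraction
of normal records passed.  The ROC area is accumulated with the
trapezoidal rule over the distinct score thresholds, which equals the
Mann–Whitney pairwise-ordering probability with half credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

POSITIVE = "afib"
NEGATIVE = "norm"


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def confusion(truth, predicted) -> ConfusionMatrix:
    """Count TP/FN/TN/FP with afib as the positive class."""
    if len(truth) == 0 or len(truth) != len(predicted):
        raise ValueError("truth and predictions must be non-empty, equal length")
    for lab in (*truth, *predicted):
        if lab not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {lab!r}")
    t = np.asarray([x == POSITIVE for x in truth])
    p = np.asarray([x == POSITIVE for x in predicted])
    return ConfusionMatrix(tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
                           tn=int(np.sum(~t & ~p)), fp=int(np.sum(~t & p)))


def sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); an undefined ratio is returned as NaN."""
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else float("nan")
    return sens, spec


def auroc_trapezoid(scores, truth) -> float:
    """Trapezoidal ROC area; higher score must mean more likely afib."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([t == POSITIVE for t in truth])
    if scores.size != y.size:
        raise ValueError("scores and truth disagree in length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUROC")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep only the last index of each tied-score run (distinct thresholds)
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(np.sum(0.5 * (tpr[1:] + tpr[:-1]) * np.diff(fpr)))


def evaluation_report(truth, predicted, scores=None) -> dict:
    """Bundle accuracy, sensitivity, specificity (and AUROC when scored)."""
    cm = confusion(truth, predicted)
    sens, spec = sensitivity_specificity(cm)
    out = {"n": cm.n, "accuracy": cm.accuracy, "sensitivity": sens,
           "specificity": spec, "tp": cm.tp, "fn": cm.fn,
           "tn": cm.tn, "fp": cm.fp}
    if scores is not None:
        out["auroc"] = auroc_trapezoid(scores, truth)
    return out
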