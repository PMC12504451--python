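"""Per-record prediction over segments, confidence voting, threshold sweep.

A long single-lead record is scored segment by segment; each segment
gets a class label (norm iff the sigmoid score clears the decision
boundary) and a confidence — the raw score for a norm call, its
complement for an afib call, so confidences live on a common [0, 1]
scale.  The record-level label is decided by summing confidences per
class: the class with the larger sum wins, which lets a single
high-confidence segment overrule two lukewarm ones.  Ties go to afib,
favouring sensitivity in a screening setting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Signal
from .render import rasterize_segment
from .segment import RPeakList, detect_r_peaks, segment_signal

NORM, AFIB = "norm", "afib"


@dataclass
class SegmentPredictions:
    labels: list[str]
    confidences: np.ndarray
    raw_scores: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.confidences = np.asarray(self.confidences, dtype=float)
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)
        if not (len(self.labels) == self.confidences.size == self.raw_scores.size):
            raise ValueError("labels/confidences/raw_scores length mismatch")


@dataclass
class PredictionResult:
    segment_predictions: SegmentPredictions
    final_label: str
    s_norm: float
    s_afib: float

    @property
    def mean_score(self) -> float:
        """Mean raw sigmoid score across segments (used for ROC sweeps)."""
        return float(np.mean(self.segment_predictions.raw_scores))


def vote(labels: list[str], confidences) -> str:
    """Confidence-sum voting: return the class whose summed confidence wins.

    ``S_norm`` and ``S_afib`` accumulate the confidences of the segments
    labelled with each class; afib wins ties.
    """
    conf = np.asarray(confidences, dtype=float)
    if len(labels) == 0:
        raise ValueError("cannot vote over zero segments")
    if len(labels) != conf.size:
        raise ValueError("labels and confidences disagree in length")
    if np.any((conf < 0) | (conf > 1)):
        raise ValueError("confidences must lie in [0, 1]")
    s_norm = float(conf[[l == NORM for l in labels]].sum())
    s_afib = float(conf[[l == AFIB for l in labels]].sum())
    return NORM if s_norm > s_afib else AFIB


def score_segments(model, signal: Signal, *, seg_seconds: float = 10.0,
                   threshold: float = 0.5,
                   anchor: RPeakList | None = None,
                   anchor_rpeaks: bool = False) -> SegmentPredictions:
    """Segment, rasterize and score one harmonized signal."""
    from .model2d import predict_segment  # local import to keep modules light

    if anchor is None and anchor_rpeaks:
        anchor = detect_r_peaks(signal)
    segs = segment_signal(signal, seg_seconds, anchor=anchor)
    images = np.stack([rasterize_segment(s).pixels for s in segs.segments])
    raw = np.atleast_1d(predict_segment(model, images))
    labels = [NORM if r >= threshold else AFIB for r in raw]
    conf = np.where(raw >= threshold, raw, 1.0 - raw)
    return SegmentPredictions(labels, conf, raw, threshold)


def predict_sample(model, signal: Signal, *, seg_seconds: float = 10.0,
                   threshold: float = 0.5,
                   anchor: RPeakList | None = None,
                   anchor_rpeaks: bool = False) -> PredictionResult:
    """Full layer-2/3 inference: per-segment scores then a voted label."""
    preds = score_segments(model, signal, seg_seconds=seg_seconds,
                           threshold=threshold, anchor=anchor,
                           anchor_rpeaks=anchor_rpeaks)
    s_norm = float(preds.confidences[[l == NORM for l in preds.labels]].sum())
    s_afib = float(preds.confidences[[l == AFIB for l in preds.labels]].sum())
    return PredictionResult(preds, vote(preds.labels, preds.confidences),
                            s_norm, s_afib)


def sweep_threshold(scores, truth, grid) -> tuple[float, np.ndarray]:
    """Accuracy at each candidate boundary; returns (best_t, accuracy table).

    Predict norm iff score >= t.  Ties in accuracy are broken toward the
    boundary closest to 0.5 (extreme cutoffs generalize poorly), then
    toward the smaller t.
    """
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    if scores.size == 0 or scores.size != len(truth):
        raise ValueError("scores and truth must be non-empty and equal length")
    y_norm = np.asarray([t == NORM for t in truth])
    acc = np.array([np.mean((scores >= t) == y_norm) for t in grid])
    best = np.lexsort((grid, np.abs(grid - 0.5), -acc))[0]
    return float(grid[best]), acc
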