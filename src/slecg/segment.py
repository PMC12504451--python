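"""Fixed-duration segmentation with R-peak anchoring.

Long records (30–60 s) are cut into contiguous, non-overlapping windows
of a fixed duration (10 s by default).  For clinical-style long records
the first window can be anchored at the first detected R peak so every
window starts on a beat; trailing partial windows are dropped so each
segment represents a full window for the image classifier.

R peaks are found with a Pan–Tompkins-style detector: band-pass 5–15 Hz,
differentiate, square, 150 ms moving-window integration, then peak
picking with a 200 ms refractory period and a threshold adaptive to the
envelope's amplitude.  Peak locations are refined to the largest absolute
band-passed excursion nearby, so polarity does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .io import Signal


@dataclass
class RPeakList:
    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


@dataclass
class SegmentSet:
    segments: np.ndarray       # (n_segments, window) sample matrix
    seg_seconds: float
    fs: float
    start_indices: np.ndarray  # per-segment sample offsets
    source_id: str = ""

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        self.start_indices = np.asarray(self.start_indices, dtype=int)
        window = int(round(self.seg_seconds * self.fs))
        if self.segments.shape[1] != window:
            raise ValueError("segment length must equal round(seg_seconds*fs)")
        if self.start_indices.size > 1 and np.any(np.diff(self.start_indices) <= 0):
            raise ValueError("start indices must be strictly increasing")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def detect_r_peaks(signal: Signal) -> RPeakList:
    """Pan–Tompkins-style R-peak detection."""
    fs = signal.fs
    if fs < 50:
        raise ValueError(f"sampling rate {fs} Hz too low for QRS detection")
    if signal.duration_s < 2.0:
        raise ValueError("need at least 2 s of signal for QRS detection")

    sos = butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, signal.samples)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    peak = float(envelope.max())
    if peak <= 0.0:
        return RPeakList(np.empty(0, dtype=int), fs)
    # adaptive floor: a fraction of the envelope's bulk amplitude, so small
    # ripples between beats are rejected regardless of overall scale
    floor = max(0.25 * peak, 2.0 * float(np.median(envelope)))
    refractory = int(round(0.200 * fs))
    cand, _ = find_peaks(envelope, height=floor, distance=max(1, refractory))

    # refine each candidate to the strongest |band-passed| sample nearby
    half = int(round(0.100 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(signal.n_samples, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)

    # enforce refractory on the refined positions, keeping the stronger peak
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < refractory:
            if abs(bp[idx]) > abs(bp[kept[-1]]):
                kept[-1] = int(idx)
        else:
            kept.append(int(idx))
    return RPeakList(np.asarray(kept, dtype=int), fs)


def segment_signal(signal: Signal, seg_seconds: float = 10.0,
                   anchor: RPeakList | None = None) -> SegmentSet:
    """Cut into non-overlapping windows of round(seg_seconds*fs) samples.

    With a non-empty ``anchor``, window 0 starts at the first anchor peak
    (falling back to sample 0 if that leaves no room for a full window);
    the trailing partial window is dropped.
    """
    window = int(round(seg_seconds * signal.fs))
    if signal.n_samples < window:
        raise ValueError(
            f"signal of {signal.n_samples} samples shorter than one "
            f"{seg_seconds} s window ({window} samples)")
    start = 0
    if anchor is not None and anchor.indices.size:
        start = int(anchor.indices[0])
        if (signal.n_samples - start) // window == 0:
            start = 0
    count = (signal.n_samples - start) // window
    offsets = start + window * np.arange(count)
    segments = np.stack([signal.samples[o:o + window] for o in offsets])
    return SegmentSet(segments, seg_seconds, signal.fs, offsets,
                      source_id=signal.source)
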