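"""Cross-device signal harmonization: resample, normalize, fix polarity.

Clinical recorders and handheld single-lead devices disagree on sampling
rate (100/500 vs 300 Hz), amplitude scale, and sometimes electrode
orientation (an upside-down trace).  This module reconciles the three in
sequence: Fourier resampling to a common rate, peak normalization into a
clip window, and a polarity check that inverts the signal when the
dominant QRS deflection points down.

Polarity is judged on a zero-phase high-passed copy of the signal (so a
baseline-wander offset cannot masquerade as a dominant deflection): the
sample of largest absolute amplitude decides, and ties between equal
positive and negative extremes leave the signal untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, resample, sosfiltfilt

from .io import Signal


@dataclass
class HarmonizeConfig:
    target_fs: float = 100.0
    clip_bounds: tuple[float, float] = (-1.0, 1.0)
    hp_cutoff: float = 0.5   # Hz, high-pass for polarity detection
    hp_order: int = 4

    def __post_init__(self) -> None:
        if not self.target_fs > 0:
            raise ValueError("target_fs must be positive")
        x, y = self.clip_bounds
        if not x < y:
            raise ValueError("clip bounds must satisfy x < y")


def resample_signal(signal: Signal, target_fs: float) -> Signal:
    """Fourier-method resampling to round(len * target_fs / fs) samples."""
    if not target_fs > 0:
        raise ValueError("target sampling rate must be positive")
    if target_fs == signal.fs:
        return signal.with_samples(signal.samples.copy())
    n_out = int(round(signal.n_samples * target_fs / signal.fs))
    return signal.with_samples(resample(signal.samples, n_out), fs=target_fs)


def normalize_amplitude(signal: Signal,
                        bounds: tuple[float, float] = (-1.0, 1.0)) -> Signal:
    """Divide by max(|samples|) and clip into ``bounds``.

    Scaling by the absolute peak (rather than the signed maximum) keeps
    the waveform shape for negative-deflected leads; an identically-zero
    signal passes through unchanged.
    """
    x, y = bounds
    if not x < y:
        raise ValueError("bounds must satisfy x < y")
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        return signal.with_samples(signal.samples.copy())
    return signal.with_samples(np.clip(signal.samples / peak, x, y))


def _highpassed(signal: Signal, config: HarmonizeConfig) -> np.ndarray:
    if signal.n_samples <= 3 * config.hp_order:
        raise ValueError(
            f"signal too short for polarity detection "
            f"(need > {3 * config.hp_order} samples)")
    sos = butter(config.hp_order, config.hp_cutoff, btype="highpass",
                 fs=signal.fs, output="sos")
    return sosfiltfilt(sos, signal.samples)


def detect_dominant_polarity(signal: Signal,
                             config: HarmonizeConfig | None = None) -> str:
    """Return ``"positive"`` or ``"negative"`` for the dominant deflection."""
    config = config or HarmonizeConfig()
    f = _highpassed(signal, config)
    peak = float(np.max(np.abs(f)))
    # tie between equal +/- extremes resolves positive: flip only on clear evidence
    return "positive" if float(np.max(f)) >= peak else "negative"


def correct_polarity(signal: Signal,
                     config: HarmonizeConfig | None = None) -> Signal:
    """Negate the signal iff its dominant deflection is negative."""
    config = config or HarmonizeConfig()
    if detect_dominant_polarity(signal, config) == "negative":
        return signal.with_samples(-signal.samples)
    return signal.with_samples(signal.samples.copy())


def harmonize_signal(signal: Signal,
                     config: HarmonizeConfig | None = None) -> Signal:
    """Full chain: resample -> normalize -> polarity-correct."""
    config = config or HarmonizeConfig()
    out = resample_signal(signal, config.target_fs)
    out = normalize_amplitude(out, config.clip_bounds)
    return correct_polarity(out, config)
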