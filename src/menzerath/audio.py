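"""Recording pre-screen metrics and envelope-based call detection.

Noisy or diffuse recordings are screened out before segmentation using
two scalar metrics, both amplitude-scale invariant and bounded in [0, 1]:

* **spectral flatness** (Wiener entropy): per STFT frame, the geometric
  mean of the power spectrum divided by its arithmetic mean, averaged
  over frames.  Near 1 for broadband noise, near 0 for tonal signals.
  A recording fails above 0.05.
* **temporal entropy**: Shannon entropy of the distribution of signal
  energy across fixed frames, normalized by log(n_frames).  Exactly 1
  for temporally uniform power (no onset/offset structure), 0 when all
  energy sits in one frame.  A recording fails above 0.85.

Call segmentation uses the smoothed Hilbert amplitude envelope: a
threshold at a multiple of the noise floor (a low percentile of the
envelope) defines supra-threshold runs; nearby runs are merged and
too-short runs dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, hilbert

#: exclusion thresholds for the pre-screen
FLATNESS_MAX = 0.05
ENTROPY_MAX = 0.85


class SilentSignalError(ValueError):
    """Metric undefined on an all-zero signal."""


@dataclass
class ScreenMetrics:
    spectral_flatness: float
    temporal_entropy: float
    flatness_max: float = FLATNESS_MAX
    entropy_max: float = ENTROPY_MAX

    @property
    def passed(self) -> bool:
        return (self.spectral_flatness <= self.flatness_max
                and self.temporal_entropy <= self.entropy_max)

    def to_dict(self) -> dict:
        return {
            "spectral_flatness": self.spectral_flatness,
            "temporal_entropy": self.temporal_entropy,
            "pass": self.passed,
            "flatness_max": self.flatness_max,
            "entropy_max": self.entropy_max,
        }


def _frame(signal: np.ndarray, length: int, hop: int) -> np.ndarray:
    """Frame a 1-D signal into rows; the incomplete tail is dropped."""
    n = (len(signal) - length) // hop + 1
    if n < 1:
        raise ValueError(f"signal shorter than one analysis window ({length} samples)")
    idx = np.arange(length)[None, :] + hop * np.arange(n)[:, None]
    return signal[idx]


def spectral_flatness(
    signal: np.ndarray,
    sample_rate: float,
    window: int = 512,
    hop: int | None = None,
) -> float:
    """Mean per-frame Wiener entropy of the power spectrum, in [0, 1].

    Frames use a Hann window of ``window`` samples with 50% overlap by
    default.  Frames with zero power are skipped; an all-zero signal
    raises :class:`SilentSignalError`.
    """
    signal = np.asarray(signal, dtype=float)
    hop = hop or window // 2
    frames = _frame(signal, window, hop)
    frames = frames * get_window("hann", window, fftbins=True)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    tot = power.sum(axis=1)
    live = tot > 0
    if not live.any():
        raise SilentSignalError("all-zero signal: spectral flatness undefined")
    power = power[live]
    am = power.mean(axis=1)
    with np.errstate(divide="ignore"):
        gm = np.exp(np.mean(np.where(power > 0, np.log(power), -np.inf), axis=1))
    return float(np.mean(gm / am))


def temporal_entropy(
    signal: np.ndarray,
    sample_rate: float,
    frame: int = 512,
) -> float:
    """Normalized Shannon entropy of frame energies, in [0, 1].

    Non-overlapping frames of ``frame`` samples (incomplete tail
    dropped).  Zero-energy frames contribute nothing (0 log 0 = 0).
    """
    signal = np.asarray(signal, dtype=float)
    frames = _frame(signal, frame, frame)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for temporal entropy")
    energy = (frames**2).sum(axis=1)
    total = energy.sum()
    if total <= 0:
        raise SilentSignalError("all-zero signal: temporal entropy undefined")
    p = energy / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float(h / np.log(len(frames)))


def load_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV as float64 mono (stereo downmixed by averaging)."""
    path = Path(path)
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)  # raw scale; all metrics are amplitude-invariant
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.size == 0:
        raise ValueError(f"empty WAV file: {path}")
    return data, float(rate)


def prescreen(path: str | Path, window: int = 512, frame: int = 512) -> ScreenMetrics:
    """Compute both screen metrics for one WAV file with pass/fail."""
    data, rate = load_wav(path)
    return ScreenMetrics(
        spectral_flatness=spectral_flatness(data, rate, window=window),
        temporal_entropy=temporal_entropy(data, rate, frame=frame),
    )


def detect_calls(
    signal: np.ndarray,
    sample_rate: float,
    noise_floor_percentile: float = 10.0,
    threshold_factor: float = 3.0,
    min_gap_s: float = 0.03,
    min_dur_s: float = 0.02,
    smooth_s: float = 0.01,
) -> list[tuple[float, float]]:
    """Detect acoustic-signal onsets/offsets from the amplitude envelope.

    The Hilbert-magnitude envelope is smoothed by a ``smooth_s`` moving
    average; the detection threshold is ``threshold_factor`` times the
    ``noise_floor_percentile``-th percentile of the envelope.  Contiguous
    supra-threshold runs become (onset_s, offset_s) segments; runs closer
    than ``min_gap_s`` are merged and segments shorter than ``min_dur_s``
    dropped.  Returns sorted, disjoint intervals.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    env = np.abs(hilbert(signal))
    win = max(1, int(round(smooth_s * sample_rate)))
    env = np.convolve(env, np.ones(win) / win, mode="same")

    floor = np.percentile(env, noise_floor_percentile)
    threshold = threshold_factor * floor
    above = env > threshold
    if not above.any():
        return []

    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1  # exclusive

    segments: list[list[int]] = []
    min_gap = int(round(min_gap_s * sample_rate))
    for s, e in zip(run_starts, run_ends):
        if segments and s - segments[-1][1] < min_gap:
            segments[-1][1] = e
        else:
            segments.append([s, e])

    min_len = int(round(min_dur_s * sample_rate))
    return [
        (s / sample_rate, e / sample_rate)
        for s, e in segments
        if e - s >= min_len
    ]


def write_wav(path: str | Path, signal: np.ndarray, sample_rate: int) -> None:
    """Write a float signal as 16-bit PCM WAV (peak-normalized if needed)."""
    signal = np.asarray(signal, dtype=float)
    peak = np.max(np.abs(signal)) if signal.size else 0.0
    if peak > 1.0:
        signal = signal / peak
    wavfile.write(path, int(sample_rate), (signal * 32767).astype(np.int16))
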