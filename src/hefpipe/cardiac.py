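"""ECG R-peak detection and time-domain heart-rate variability.

The detector is a Pan-Tompkins-style envelope detector: band-pass, squared
derivative, moving-average envelope, adaptive threshold, then refinement to
the local extremum of the band-passed trace.  Because the envelope squares
the signal, detection is polarity-invariant.

HRV measures follow the time-domain conventions: SDNN is the sample standard
deviation (n-1 denominator) of all NN intervals; RMSSD is the root mean
square of successive NN differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ECGTrace",
    "RPeakSeries",
    "NNSeries",
    "detect_r_peaks",
    "nn_intervals",
    "sdnn",
    "rmssd",
    "heart_rate",
]


@dataclass
class ECGTrace:
    """Single-channel ECG, arbitrary voltage units."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG trace contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class RPeakSeries:
    """Detected R-peak sample indices (strictly increasing)."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=int).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.peak_indices.size > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.peak_indices.size and self.peak_indices[0] < 0:
            raise ValueError("peak indices must be non-negative")

    @property
    def n_peaks(self) -> int:
        return self.peak_indices.size

    @property
    def times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs


@dataclass
class NNSeries:
    """Normal-to-normal beat intervals in milliseconds."""

    intervals_ms: np.ndarray

    def __post_init__(self):
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float).ravel()
        if np.any(self.intervals_ms <= 0):
            raise ValueError("NN intervals must be positive")

    @property
    def n(self) -> int:
        return self.intervals_ms.size


def detect_r_peaks(
    trace: ECGTrace,
    min_rr_ms: float = 300.0,
    band: tuple = (5.0, 35.0),
) -> RPeakSeries:
    """Detect R peaks with a band-pass / squared-derivative envelope.

    Steps: 4th-order zero-phase Butterworth band-pass (default 5-35 Hz),
    squared derivative smoothed with a 120 ms moving average, adaptive
    threshold at a fraction of the upper envelope percentile, candidate
    peaks at least ``min_rr_ms`` apart (refractory), then refinement to the
    nearest local extremum of the absolute band-passed trace.

    A flat trace returns an empty series with a warning.
    """
    x = trace.samples
    fs = trace.fs
    if x.size < int(2 * fs):
        raise ValueError("trace must be at least 2 s long")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG trace: no R peaks detected", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs)

    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)

    from scipy.ndimage import uniform_filter1d

    env = np.gradient(filt) ** 2
    env = uniform_filter1d(env, max(3, int(round(0.120 * fs))))

    thr = 0.25 * np.percentile(env, 99.0)
    if thr <= 0:
        warnings.warn("degenerate ECG envelope: no R peaks detected", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs)
    refractory = int(round(min_rr_ms * fs / 1000.0))
    cand, _ = signal.find_peaks(env, height=thr, distance=max(1, refractory))
    if cand.size == 0:
        warnings.warn("no ECG envelope peaks above threshold", stacklevel=2)
        return RPeakSeries(np.array([], dtype=int), fs)

    # refine to the extremum of the median-centered raw trace near each
    # envelope peak (|.| keeps this polarity-invariant)
    half = max(1, int(round(0.050 * fs)))
    absf = np.abs(x - np.median(x))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(absf[lo:hi])))
    refined = np.unique(refined)

    # enforce refractory after refinement: keep the larger-envelope peak
    keep = []
    for r in refined:
        if keep and r - keep[-1] < refractory:
            if absf[r] > absf[keep[-1]]:
                keep[-1] = r
        else:
            keep.append(r)
    return RPeakSeries(np.asarray(keep, dtype=int), fs)


def nn_intervals(peaks: RPeakSeries) -> NNSeries:
    """Successive R-R intervals in ms: diff(peaks) * 1000 / fs."""
    if peaks.n_peaks < 2:
        raise ValueError("need at least 2 peaks to form NN intervals")
    return NNSeries(np.diff(peaks.peak_indices) * 1000.0 / peaks.fs)


def sdnn(nn: NNSeries) -> float:
    """Standard deviation of all NN intervals (n-1 denominator), ms."""
    if nn.n < 2:
        raise ValueError("SDNN requires at least 2 intervals")
    return float(np.std(nn.intervals_ms, ddof=1))


def rmssd(nn: NNSeries) -> float:
    """Root mean square of successive NN differences, ms."""
    if nn.n < 3:
        raise ValueError("RMSSD requires at least 3 intervals")
    d = np.diff(nn.intervals_ms)
    return float(np.sqrt(np.mean(d**2)))


def heart_rate(nn: NNSeries) -> float:
    """Mean heart rate in beats per minute: 60000 / mean NN (ms)."""
    if nn.n < 1:
        raise ValueError("heart rate requires at least 1 interval")
    return float(60000.0 / np.mean(nn.intervals_ms))
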