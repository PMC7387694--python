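"""Morlet time-frequency decomposition, inter-trial coherence, z-maps.

The inter-trial coherence (ITC) at frequency f and time t is the modulus of
the across-trial mean of unit-normalized complex spectral estimates,

    ITC(f, t) = | (1/n) sum_k F_k(f, t) / |F_k(f, t)| |,

bounded in [0, 1]: 0 for phases uniform across trials, 1 for perfect phase
locking.  F_k comes from convolution with complex Morlet wavelets
(Gaussian-windowed complex exponentials, ``n_cycles`` cycles per frequency).

Numerical conventions: wavelets are truncated at +/-2.5 temporal standard
deviations; samples closer than that half-support to an epoch edge are
flagged invalid (masked, never zeroed).  A wavelet whose truncated support
exceeds the epoch raises an error naming the frequency.  Wavelets are
normalized so a unit-amplitude sinusoid at f yields |F| = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .epoching import EpochSet

__all__ = [
    "TFCoefficients",
    "TFMap",
    "morlet_transform",
    "induced_power",
    "itc",
    "itc_from_epochs",
    "reference_stats",
    "normalize_zmap",
    "DEFAULT_FREQS",
]

#: Default analysis grid: 8-24 Hz in 1 Hz steps.
DEFAULT_FREQS = np.arange(8.0, 25.0, 1.0)

#: Gaussian truncation of the wavelet, in temporal SDs.
SUPPORT_SIGMAS = 2.5


@dataclass
class TFCoefficients:
    """Complex Morlet coefficients F_k(f, t).

    ``coeffs`` has shape (n_trials, n_channels, n_freqs, n_times); ``valid``
    (n_freqs, n_times) is False where the wavelet support overhangs an epoch
    edge.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    n_cycles: float
    valid: np.ndarray
    channel_labels: list

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class TFMap:
    """A (channel, frequency, time) map: ITC, induced power, or z-values."""

    values: np.ndarray  # (n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times_ms: np.ndarray
    n_trials: int
    valid: np.ndarray  # (n_freqs, n_times)
    channel_labels: list
    kind: str = "itc"  # "itc" | "power" | "z"
    reference: tuple | None = None  # (mean, sd) used for kind == "z"

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


def _wavelet(freq: float, fs: float, n_cycles: float):
    """Truncated complex Morlet wavelet and its half-support in samples."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(round(SUPPORT_SIGMAS * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-0.5 * (t / sigma_t) ** 2)
    w = gauss * np.exp(2j * np.pi * freq * t)
    w -= w.mean()  # exactly zero-mean despite truncation: DC rejection
    # unit-amplitude sinusoid at freq -> |coefficient| = 0.5
    w /= gauss.sum()
    return w, half


def morlet_transform(
    epochs: EpochSet,
    freqs=None,
    n_cycles: float = 7.0,
    channels=None,
    retained_only: bool = True,
) -> TFCoefficients:
    """Convolve every trial/channel with complex Morlet wavelets.

    Parameters
    ----------
    freqs : array-like, default 8-24 Hz in 1 Hz steps
    n_cycles : wavelet width in cycles, fixed across frequencies
    channels : optional list of channel labels to transform (saves memory)
    retained_only : drop artifact-rejected trials first (default)
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    fs = epochs.fs
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")

    data = epochs.retained() if retained_only else epochs.data
    labels = list(epochs.channel_labels)
    if channels is not None:
        cols = [epochs.channel_index(c) for c in channels]
        data = data[:, cols, :]
        labels = list(channels)
    n_trials, n_ch, n_times = data.shape

    wavelets = []
    for f in freqs:
        w, half = _wavelet(f, fs, n_cycles)
        if w.size > n_times:
            raise ValueError(
                f"wavelet at {f:g} Hz ({w.size} samples at n_cycles={n_cycles:g}) "
                f"is longer than the {n_times}-sample epoch"
            )
        wavelets.append((w, half))

    max_len = max(w.size for w, _ in wavelets)
    nfft = next_fast_len(n_times + max_len - 1)
    spec = fft(data, nfft, axis=-1)

    coeffs = np.empty((n_trials, n_ch, freqs.size, n_times), dtype=complex)
    valid = np.zeros((freqs.size, n_times), dtype=bool)
    for i, (w, half) in enumerate(wavelets):
        wf = fft(w, nfft)
        conv = ifft(spec * wf, axis=-1)
        # 'same' alignment: wavelet center at each output sample
        coeffs[:, :, i, :] = conv[..., half : half + n_times]
        if n_times > 2 * half:
            valid[i, half : n_times - half] = True

    return TFCoefficients(
        coeffs=coeffs,
        freqs=freqs,
        times_ms=epochs.times_ms.copy(),
        n_cycles=n_cycles,
        valid=valid,
        channel_labels=labels,
    )


def induced_power(tf: TFCoefficients) -> TFMap:
    """Across-trial mean of |F_k(f, t)|^2."""
    if tf.n_trials < 1:
        raise ValueError("need at least one trial")
    return TFMap(
        values=np.mean(np.abs(tf.coeffs) ** 2, axis=0),
        freqs=tf.freqs.copy(),
        times_ms=tf.times_ms.copy(),
        n_trials=tf.n_trials,
        valid=tf.valid.copy(),
        channel_labels=list(tf.channel_labels),
        kind="power",
    )


def itc(tf: TFCoefficients) -> TFMap:
    """Inter-trial coherence: modulus of the trial-mean unit phasor.

    Points where a trial has |F_k| = 0 (phase undefined) contribute zero to
    the sum and the point is flagged invalid in the returned map.
    """
    if tf.n_trials < 1:
        raise ValueError("need at least one trial")
    mag = np.abs(tf.coeffs)
    zero = mag == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(zero, 0.0, tf.coeffs / np.where(zero, 1.0, mag))
    values = np.abs(unit.mean(axis=0))
    valid = tf.valid & ~zero.any(axis=(0, 1))
    return TFMap(
        values=values,
        freqs=tf.freqs.copy(),
        times_ms=tf.times_ms.copy(),
        n_trials=tf.n_trials,
        valid=valid,
        channel_labels=list(tf.channel_labels),
        kind="itc",
    )


def itc_from_epochs(
    epochs: EpochSet,
    freqs=None,
    n_cycles: float = 7.0,
    channels=None,
    single_precision: bool = True,
) -> TFMap:
    """ITC computed frequency-by-frequency without storing all coefficients.

    Numerically equivalent to ``itc(morlet_transform(...))`` (to single
    precision by default) but streams over frequencies, so memory stays
    O(n_trials * n_times) instead of O(n_trials * n_freqs * n_times) — the
    path used for cohort-scale runs.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    fs = epochs.fs
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2)")
    data = epochs.retained()
    labels = list(epochs.channel_labels)
    if channels is not None:
        cols = [epochs.channel_index(c) for c in channels]
        data = data[:, cols, :]
        labels = list(channels)
    n_trials, n_ch, n_times = data.shape
    if n_trials < 1:
        raise ValueError("need at least one trial")

    cdtype = np.complex64 if single_precision else np.complex128
    wavelets = []
    for f in freqs:
        w, half = _wavelet(f, fs, n_cycles)
        if w.size > n_times:
            raise ValueError(
                f"wavelet at {f:g} Hz ({w.size} samples) is longer than the "
                f"{n_times}-sample epoch"
            )
        wavelets.append((w.astype(cdtype), half))
    max_len = max(w.size for w, _ in wavelets)
    nfft = next_fast_len(n_times + max_len - 1)
    spec = fft(
        data.astype(np.float32 if single_precision else np.float64), nfft, axis=-1
    )

    values = np.empty((n_ch, freqs.size, n_times))
    valid = np.zeros((freqs.size, n_times), dtype=bool)
    zero_seen = np.zeros((freqs.size, n_times), dtype=bool)
    for i, (w, half) in enumerate(wavelets):
        conv = ifft(spec * fft(w, nfft), axis=-1)[..., half : half + n_times]
        mag = np.abs(conv)
        zero = mag == 0
        if zero.any():
            zero_seen[i] |= zero.any(axis=(0, 1))
            mag[zero] = 1.0
            conv[zero] = 0.0
        values[:, i, :] = np.abs((conv / mag).mean(axis=0))
        if n_times > 2 * half:
            valid[i, half : n_times - half] = True
    return TFMap(
        values=values,
        freqs=freqs,
        times_ms=epochs.times_ms.copy(),
        n_trials=n_trials,
        valid=valid & ~zero_seen,
        channel_labels=labels,
        kind="itc",
    )


def _window_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (axis >= lo) & (axis <= hi)


def reference_stats(
    tfmap: TFMap,
    channel: str,
    t_window_ms: tuple = (200.0, 600.0),
    f_window_hz: tuple = (8.0, 24.0),
):
    """Mean and sample SD over valid (f, t) points of one channel.

    This is the normalization reference (e.g. the insular seed channel in
    the control condition over 200-600 ms and 8-24 Hz).
    """
    ch = tfmap.channel_index(channel)
    fm = _window_mask(tfmap.freqs, *f_window_hz)
    tm = _window_mask(tfmap.times_ms, *t_window_ms)
    if not fm.any() or not tm.any():
        raise ValueError("empty reference window")
    region = np.ix_(fm, tm)
    vals = tfmap.values[ch][region][tfmap.valid[region]]
    if vals.size == 0:
        raise ValueError("reference window contains no valid points")
    if vals.size < 2:
        raise ValueError("reference window has a single valid point; widen it")
    return float(vals.mean()), float(vals.std(ddof=1))


def normalize_zmap(tfmap: TFMap, reference) -> TFMap:
    """Pointwise z-scoring against (mean, sd) reference statistics."""
    mean, sd = reference
    if sd <= 0:
        raise ValueError("reference SD must be positive")
    return TFMap(
        values=(tfmap.values - mean) / sd,
        freqs=tfmap.freqs.copy(),
        times_ms=tfmap.times_ms.copy(),
        n_trials=tfmap.n_trials,
        valid=tfmap.valid.copy(),
        channel_labels=list(tfmap.channel_labels),
        kind="z",
        reference=(float(mean), float(sd)),
    )
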