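"""R-peak-locked epoching, artifact rejection, and evoked averaging.

Heartbeat-evoked fields (HEFs) are obtained by cutting fixed windows out of a
multi-channel recording around each ECG R peak and averaging the retained
trials.  The window convention throughout the package is [-200, +600] ms
relative to the R peak, closed on both ends (801 samples at 1 kHz); t = 0 ms
is the trigger sample.

Artifact rejection follows the peak-to-peak rule: an epoch is discarded when
the max-minus-min amplitude on *any* channel of a given physical type exceeds
that type's threshold (strictly greater than).  Channels tagged ``source``
(reconstructed ROI time courses) never trigger rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MultiChannelRecording",
    "EpochSet",
    "EvokedResponse",
    "extract_epochs",
    "reject_epochs",
    "average_evoked",
    "subtract_conditions",
    "decimate_epochs",
    "CHANNEL_TYPES",
]

#: Recognized channel types.  Rejection thresholds apply to the first two.
CHANNEL_TYPES = ("magnetometer", "gradiometer", "source", "ecg", "misc")

#: Default peak-to-peak rejection thresholds (physical units of the channel:
#: fT for magnetometers, fT/cm for gradiometers).
MAG_REJECT_PTP = 400.0
GRAD_REJECT_PTP = 4000.0


@dataclass
class MultiChannelRecording:
    """Continuous multi-channel time series with block annotations.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    channel_types : list of str
        One of :data:`CHANNEL_TYPES` per channel.
    annotations : list of (start_s, end_s, label)
        Non-overlapping condition blocks, in seconds from recording start.
    """

    data: np.ndarray
    fs: float
    channel_labels: list
    channel_types: list
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_ch = self.data.shape[1]
        if len(self.channel_labels) != n_ch or len(self.channel_types) != n_ch:
            raise ValueError("labels/types must match the number of channels")
        for t in self.channel_types:
            if t not in CHANNEL_TYPES:
                raise ValueError(f"unknown channel type {t!r}")
        spans = sorted((a[0], a[1]) for a in self.annotations)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("annotations overlap")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class EpochSet:
    """Trials x channels x time array locked to R-peak triggers."""

    data: np.ndarray  # (n_trials, n_channels, n_times)
    times_ms: np.ndarray
    fs: float
    triggers: np.ndarray  # sample index of t=0 for each retained trial
    condition: str
    channel_labels: list
    channel_types: list
    rejected_mask: np.ndarray = None  # bool per trial
    reject_reasons: list = None
    n_edge_excluded: int = 0
    n_outside_blocks: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.triggers = np.asarray(self.triggers, dtype=int)
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.n_trials, dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
        if self.reject_reasons is None:
            self.reject_reasons = [None] * self.n_trials
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis mismatch")
        if self.data.shape[0] != self.triggers.size:
            raise ValueError("trigger count mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected_mask).sum())

    @property
    def n_rejected(self) -> int:
        return int(self.rejected_mask.sum())

    def retained(self) -> np.ndarray:
        """Data of retained trials only."""
        return self.data[~self.rejected_mask]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class EvokedResponse:
    """Across-trial mean (channels x time), the HEF waveform."""

    data: np.ndarray
    times_ms: np.ndarray
    n_trials: int
    condition: str
    channel_labels: list

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


def extract_epochs(
    rec: MultiChannelRecording,
    peaks,
    condition: str,
    tmin_ms: float = -200.0,
    tmax_ms: float = 600.0,
) -> EpochSet:
    """Cut one epoch per R peak that falls inside a block of `condition`.

    Peaks outside blocks of the requested condition are excluded and counted
    in ``n_outside_blocks``; peaks whose full window would clip a recording
    edge are excluded and counted in ``n_edge_excluded``.

    Parameters
    ----------
    peaks : RPeakSeries or array of sample indices
    """
    peak_idx = np.asarray(getattr(peaks, "peak_indices", peaks), dtype=int)
    blocks = [(a[0], a[1]) for a in rec.annotations if a[2] == condition]
    if not blocks:
        raise ValueError(f"condition {condition!r} not present in annotations")

    in_block = np.zeros(peak_idx.size, dtype=bool)
    for s, e in blocks:
        in_block |= (peak_idx >= int(round(s * rec.fs))) & (
            peak_idx < int(round(e * rec.fs))
        )
    n_outside = int((~in_block).sum())
    sel = peak_idx[in_block]

    lo = int(round(tmin_ms * rec.fs / 1000.0))
    hi = int(round(tmax_ms * rec.fs / 1000.0))
    ok = (sel + lo >= 0) & (sel + hi < rec.n_samples)
    n_edge = int((~ok).sum())
    sel = sel[ok]
    if sel.size == 0:
        raise ValueError(
            f"no usable triggers for condition {condition!r} "
            f"({n_outside} outside blocks, {n_edge} clipped edges)"
        )

    offsets = np.arange(lo, hi + 1)
    idx = sel[:, None] + offsets[None, :]
    data = rec.data[idx, :].transpose(0, 2, 1)  # trials x channels x time
    times_ms = offsets * 1000.0 / rec.fs
    return EpochSet(
        data=data,
        times_ms=times_ms,
        fs=rec.fs,
        triggers=sel,
        condition=condition,
        channel_labels=list(rec.channel_labels),
        channel_types=list(rec.channel_types),
        n_edge_excluded=n_edge,
        n_outside_blocks=n_outside,
    )


def reject_epochs(
    epochs: EpochSet,
    mag_thresh: float = MAG_REJECT_PTP,
    grad_thresh: float = GRAD_REJECT_PTP,
) -> EpochSet:
    """Flag epochs whose peak-to-peak amplitude exceeds a type threshold.

    Rejection is strict: an epoch is rejected iff max-min over the epoch is
    strictly greater than the threshold on any magnetometer (``mag_thresh``)
    or gradiometer (``grad_thresh``) channel.  ``source``/other channels
    never trigger rejection.  Previously rejected trials stay rejected.
    """
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x ch
    types = np.asarray(epochs.channel_types)
    thresholds = {"magnetometer": mag_thresh, "gradiometer": grad_thresh}

    mask = epochs.rejected_mask.copy()
    reasons = list(epochs.reject_reasons)
    for ch_type, thr in thresholds.items():
        cols = np.flatnonzero(types == ch_type)
        if cols.size == 0:
            continue
        bad = (ptp[:, cols] > thr).any(axis=1)
        for k in np.flatnonzero(bad & ~mask):
            reasons[k] = f"{ch_type} p2p > {thr:g}"
        mask |= bad
    return replace(epochs, rejected_mask=mask, reject_reasons=reasons)


def average_evoked(epochs: EpochSet, baseline_correct: bool = True) -> EvokedResponse:
    """Trial-average of retained epochs; the heartbeat-evoked waveform.

    With ``baseline_correct`` (default), the per-channel mean over the
    pre-trigger window (times <= 0 ms) is subtracted from each trial first.
    """
    kept = epochs.retained()
    if kept.shape[0] == 0:
        raise ValueError("no retained epochs to average")
    if baseline_correct:
        base = epochs.times_ms <= 0
        kept = kept - kept[:, :, base].mean(axis=2, keepdims=True)
    return EvokedResponse(
        data=kept.mean(axis=0),
        times_ms=epochs.times_ms,
        n_trials=kept.shape[0],
        condition=epochs.condition,
        channel_labels=list(epochs.channel_labels),
    )


def decimate_epochs(epochs: EpochSet, factor: int) -> EpochSet:
    """Anti-aliased downsampling of an epoch set by an integer factor.

    A symmetric low-pass FIR (cutoff 0.8x the new Nyquist, centered
    convolution, zero phase) precedes subsampling, so band-limited analyses
    up to ~0.4 * fs / factor are unaffected.  Used to cut the cost of
    time-frequency and connectivity stages whose frequencies of interest
    sit far below the recording Nyquist.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return epochs
    from scipy.signal import fftconvolve, firwin  # local: keep import cost off

    new_nyq = epochs.fs / factor / 2.0
    numtaps = int(round(6 * epochs.fs / new_nyq)) | 1
    taps = firwin(numtaps, 0.8 * new_nyq, fs=epochs.fs)
    filt = fftconvolve(epochs.data, taps[None, None, :], mode="same", axes=-1)
    return replace(
        epochs,
        data=filt[:, :, ::factor],
        times_ms=epochs.times_ms[::factor].copy(),
        fs=epochs.fs / factor,
    )


def subtract_conditions(a: EvokedResponse, b: EvokedResponse) -> EvokedResponse:
    """Elementwise difference a - b of two evoked responses."""
    if a.channel_labels != b.channel_labels:
        raise ValueError("channel sets differ")
    if a.times_ms.shape != b.times_ms.shape or not np.allclose(a.times_ms, b.times_ms):
        raise ValueError("time axes differ")
    return EvokedResponse(
        data=a.data - b.data,
        times_ms=a.times_ms.copy(),
        n_trials=min(a.n_trials, b.n_trials),
        condition=f"{a.condition}-{b.condition}",
        channel_labels=list(a.channel_labels),
    )
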