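"""Phase-lag-index (PLI) connectivity between ROI time courses.

The PLI between two signals is the absolute mean of the sign of their
wrapped instantaneous phase difference,

    PLI = | mean over samples of sign( wrap(phi_a - phi_b) ) |,

with sign(0) contributing 0.  It is bounded in [0, 1], symmetric in its
arguments, invariant to a common phase offset, and — by construction —
insensitive to zero-lag coupling, the signature of volume conduction.

Instantaneous phase comes from a zero-phase band-pass FIR filter (odd-length
symmetric taps applied with centered convolution, hence no group delay)
followed by the analytic signal.  A wavelet-phase variant (complex Morlet at
the band center) is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import firwin, fftconvolve, hilbert

from .epoching import EpochSet
from .spectral import _wavelet

__all__ = [
    "BandSpec",
    "ALPHA_BAND",
    "BETA_BAND",
    "band_phase",
    "pli",
    "fisher_z",
    "seed_pli_table",
]

_CLIP = 1.0 - 1e-12  # PLI clipping before atanh


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


ALPHA_BAND = BandSpec("alpha", 8.0, 13.0)
BETA_BAND = BandSpec("beta", 14.0, 24.0)


def band_phase(
    epochs: EpochSet,
    band: BandSpec,
    channels=None,
    numtaps: int | None = None,
    method: str = "fir",
    retained_only: bool = True,
):
    """Instantaneous phase per (trial, channel, time) within a band.

    Returns ``(phase, valid)`` where ``valid`` (n_times,) is False within
    the filter transient at the epoch edges; per-sample points where the
    analytic amplitude is numerically zero (phase undefined) are also
    invalidated, broadcast into a (trial, channel, time) mask in that case.

    ``method='fir'`` (default): odd-length symmetric band-pass FIR
    (``numtaps`` ~ 1.5 * fs / f_lo) applied as a centered convolution
    (zero phase), then the analytic-signal angle.  ``method='wavelet'``:
    angle of the complex Morlet coefficient at the band center frequency.
    """
    fs = epochs.fs
    if band.f_hi >= fs / 2:
        raise ValueError("band extends to or beyond Nyquist")
    data = epochs.retained() if retained_only else epochs.data
    if channels is not None:
        cols = [epochs.channel_index(c) for c in channels]
        data = data[:, cols, :]
    n_times = data.shape[-1]

    if method == "wavelet":
        n_cycles = 7.0
        w, half = _wavelet(band.center, fs, n_cycles)
        if w.size > n_times:
            raise ValueError("wavelet longer than epoch for this band")
        analytic = fftconvolve(data.astype(complex), w[None, None, :], mode="same",
                               axes=-1)
        margin = half
    elif method == "fir":
        if numtaps is None:
            numtaps = int(round(1.5 * fs / band.f_lo)) | 1  # force odd
        if numtaps >= n_times:
            raise ValueError(
                f"band {band.name!r} needs a {numtaps}-tap filter but epochs "
                f"have only {n_times} samples"
            )
        taps = firwin(numtaps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs)
        filt = fftconvolve(data, taps[None, None, :], mode="same", axes=-1)
        analytic = hilbert(filt, axis=-1)
        margin = numtaps // 2
    else:
        raise ValueError(f"unknown method {method!r}")

    phase = np.angle(analytic)
    valid = np.zeros(n_times, dtype=bool)
    if n_times > 2 * margin:
        valid[margin : n_times - margin] = True

    amp = np.abs(analytic)
    scale = amp.max()
    if scale == 0:
        return phase, np.zeros(data.shape, dtype=bool)
    dead = amp < 1e-12 * scale
    if dead.any():
        full = np.broadcast_to(valid, data.shape).copy()
        full[dead] = False
        return phase, full
    return phase, valid


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]; exact zeros stay zero."""
    return np.angle(np.exp(1j * d))


def pli(phase_a, phase_b, valid=None, per_trial: bool = False):
    """Phase lag index over pooled valid samples.

    ``phase_a``/``phase_b`` are broadcastable arrays (e.g. trials x times);
    ``valid`` is an optional boolean mask over the same (broadcast) shape.
    With ``per_trial`` the sign-average is taken within each trial (last
    axis) first and the per-trial PLIs are averaged — a sensitivity variant.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    signs = np.sign(_wrap(a - b))
    if valid is not None:
        valid = np.broadcast_to(valid, signs.shape)
        if not valid.any():
            raise ValueError("no valid samples for PLI")
        if per_trial:
            cnt = valid.sum(axis=-1)
            s = np.where(valid, signs, 0.0).sum(axis=-1)
            ok = cnt > 0
            return float(np.mean(np.abs(s[ok] / cnt[ok])))
        return float(np.abs(signs[valid].mean()))
    if signs.size == 0:
        raise ValueError("no samples for PLI")
    if per_trial:
        return float(np.mean(np.abs(signs.mean(axis=-1))))
    return float(np.abs(signs.mean()))


def fisher_z(pli_value: float) -> float:
    """Variance-stabilizing atanh transform of a PLI in [0, 1].

    Values are clipped to 1 - 1e-12 so the transform stays finite at
    perfect coupling.
    """
    p = float(pli_value)
    if not 0.0 <= p <= 1.0:
        raise ValueError("PLI must lie in [0, 1]")
    return float(np.arctanh(min(p, _CLIP)))


def seed_pli_table(
    epochs_by_condition: dict,
    seed_roi: str,
    rois=None,
    bands=(ALPHA_BAND, BETA_BAND),
    t_window_ms: tuple = (200.0, 500.0),
    per_trial: bool = False,
    method: str = "fir",
) -> pd.DataFrame:
    """Seed-to-all PLI per band and condition, Fisher-z transformed.

    Returns a DataFrame with one row per (condition, band, target):
    columns seed_roi, target_roi, band, condition, pli, fisher_z, n_epochs.
    """
    first = next(iter(epochs_by_condition.values()))
    if rois is None:
        rois = list(first.channel_labels)
    if seed_roi not in rois:
        raise ValueError("seed ROI must be among the ROIs")
    targets = [r for r in rois if r != seed_roi]

    rows = []
    for cond, epochs in epochs_by_condition.items():
        tmask = (epochs.times_ms >= t_window_ms[0]) & (
            epochs.times_ms <= t_window_ms[1]
        )
        for band in bands:
            phase, valid = band_phase(epochs, band, channels=rois, method=method)
            n_epochs = phase.shape[0]
            seed_ix = rois.index(seed_roi)
            for tgt in targets:
                t_ix = rois.index(tgt)
                pa = phase[:, seed_ix, :][:, tmask]
                pb = phase[:, t_ix, :][:, tmask]
                if valid.ndim == 1:
                    v = np.broadcast_to(valid[tmask], pa.shape)
                else:
                    v = valid[:, seed_ix, :][:, tmask] & valid[:, t_ix, :][:, tmask]
                value = pli(pa, pb, valid=v, per_trial=per_trial)
                rows.append(
                    {
                        "seed_roi": seed_roi,
                        "target_roi": tgt,
                        "band": band.name,
                        "condition": cond,
                        "pli": value,
                        "fisher_z": fisher_z(value),
                        "n_epochs": n_epochs,
                    }
                )
    return pd.DataFrame(rows)
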