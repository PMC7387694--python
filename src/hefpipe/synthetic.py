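"""Synthetic cardiac-brain recordings with known ground truth.

Every downstream stage of the pipeline is exercised against data from this
module: an AR(1) RR-interval generator with separately controllable SDNN and
RMSSD, a biphasic QRS synthesizer, and a multi-ROI recording builder that
plants heartbeat-locked evoked bumps, von-Mises phase-locked oscillatory
bursts (the substrate of inter-trial coherence), fixed inter-ROI phase lags
(the substrate of the phase lag index), and 1/f + white noise.

The default session emulates the study regime this package targets: two
conditions in 3-minute alternating blocks (two blocks each, 12 min total),
heart rate near 66-67 bpm so a 6-min condition yields roughly 400 beats,
an evoked bump peaking ~265 ms after the R peak, phase-locked bursts at
19 and 23 Hz in one condition and at 14 Hz in the other, and a constant
0.5 rad beta-band lag between the insular seed and one coupled ROI.

For an AR(1) RR series with marginal SD sigma and lag-1 correlation rho,
RMSSD = sigma * sqrt(2 * (1 - rho)), so (rr_sd, rr_ar1) map one-to-one onto
(SDNN, RMSSD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .cardiac import ECGTrace
from .epoching import MultiChannelRecording

__all__ = [
    "CardiacParams",
    "OscillationSpec",
    "ConditionSpec",
    "SessionConfig",
    "SimulatedSession",
    "generate_rr_series",
    "synthesize_ecg",
    "generate_recording",
    "default_session_config",
]


@dataclass
class CardiacParams:
    """RR-interval and QRS morphology parameters.

    mean_rr/rr_sd in ms; rr_ar1 in [-1, 1] sets the RMSSD/SDNN ratio
    (sqrt(2*(1-rr_ar1))); qrs_amplitude in arbitrary voltage units.
    """

    mean_rr: float = 900.0
    rr_sd: float = 43.0
    rr_ar1: float = 0.67
    qrs_amplitude: float = 1.0
    fs: float = 1000.0

    def __post_init__(self):
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be non-negative")
        if not -1.0 <= self.rr_ar1 <= 1.0:
            raise ValueError("rr_ar1 must lie in [-1, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class OscillationSpec:
    """A beat-locked oscillatory burst on one ROI.

    The burst has a Gaussian amplitude envelope (SD ``envelope_sd_ms``)
    centered ``lock_latency_ms`` after each R peak.  Its phase *at the lock
    latency* is drawn per beat from a von Mises distribution with mean
    ``phase_mu`` and concentration ``phase_kappa`` (kappa=0: uniform;
    kappa=None: deterministic, the perfect-locking limit); elsewhere the
    phase advances linearly at 2*pi*freq, which makes the downstream ITC
    analytically predictable at exactly (freq, lock_latency).

    ``lag_from=(roi, lag_rad)`` instead copies, beat by beat, the phase of
    the same-frequency oscillation on another ROI and adds a constant lag —
    the ground truth for phase-lag-index recovery.
    """

    roi: str
    freq: float
    amplitude: float = 1.0
    phase_kappa: float | None = 0.0
    phase_mu: float = 0.0
    lock_latency_ms: float = 300.0
    envelope_sd_ms: float = 100.0
    lag_from: tuple | None = None  # (source roi, lag in radians)

    def __post_init__(self):
        if self.freq <= 0:
            raise ValueError("freq must be positive")
        if self.phase_kappa is not None and self.phase_kappa < 0:
            raise ValueError("phase_kappa must be >= 0 (or None for deterministic)")


@dataclass
class ConditionSpec:
    """Everything that differs between experimental conditions."""

    cardiac: CardiacParams = field(default_factory=CardiacParams)
    oscillations: list = field(default_factory=list)
    bump_amplitude: float = 1.0
    bump_latency_ms: float = 265.0
    bump_sd_ms: float = 40.0
    noise_white_sd: float = 2.0
    noise_pink_sd: float = 1.0


@dataclass
class SessionConfig:
    """Block design and per-condition parameters for one session."""

    conditions: dict  # condition label -> ConditionSpec
    rois: list
    block_duration_s: float = 180.0
    n_blocks_per_condition: int = 2
    channel_types: dict = field(default_factory=dict)  # roi -> type, default source
    ecg_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.block_duration_s <= 0:
            raise ValueError("block_duration_s must be positive")
        if len(self.conditions) < 2:
            raise ValueError("both conditions must be present")
        if self.n_blocks_per_condition < 1:
            raise ValueError("n_blocks_per_condition must be >= 1")
        for cond, spec in self.conditions.items():
            fs = spec.cardiac.fs
            for osc in spec.oscillations:
                if osc.freq >= fs / 2:
                    raise ValueError(
                        f"oscillation at {osc.freq} Hz in condition {cond!r} "
                        f"is at or above Nyquist ({fs / 2} Hz)"
                    )
                if osc.roi not in self.rois:
                    raise ValueError(f"oscillation ROI {osc.roi!r} not in rois")


@dataclass
class SimulatedSession:
    """A generated recording plus all ground truth used to build it."""

    recording: MultiChannelRecording
    ecg: ECGTrace
    true_peaks: np.ndarray  # sample indices, all conditions pooled
    beats_by_condition: dict  # condition -> sample indices
    phases_by_condition: dict  # condition -> {(roi, freq): per-beat phases}
    config: SessionConfig


def generate_rr_series(params: CardiacParams, n_beats: int, rng=None) -> np.ndarray:
    """AR(1) Gaussian RR series, ms.

    Marginal mean ``mean_rr``, marginal SD ``rr_sd``, lag-1 autocorrelation
    ``rr_ar1``; the process is started from its stationary distribution.
    Intervals are clipped to stay positive (floor 1 ms).
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    rng = np.random.default_rng(rng)
    if params.rr_sd == 0:
        return np.full(n_beats, params.mean_rr)
    rho = params.rr_ar1
    eps = rng.standard_normal(n_beats)
    x = np.empty(n_beats)
    x[0] = eps[0]
    if abs(rho) < 1.0:
        c = math.sqrt(1.0 - rho**2)
        x[1:], _ = lfilter([c], [1.0, -rho], eps[1:], zi=np.array([rho * x[0]]))
    else:
        x[:] = x[0] * np.sign(rho) ** np.arange(n_beats)
    rr = params.mean_rr + params.rr_sd * x
    return np.maximum(rr, 1.0)


def _qrs_template(fs: float, amplitude: float, sigma_ms: float = 5.0):
    """Sharp biphasic QRS-like pulse: dominant R wave with a smaller S dip.

    Returns (offsets, values), recentered so the positive extremum —
    the ground-truth R-peak sample — sits exactly at offset 0.  Total
    width ~4*sigma_ms (20 ms by default).
    """
    s = sigma_ms * fs / 1000.0
    offsets = np.arange(-int(round(4 * s)), int(round(4 * s)) + 1)
    r_wave = np.exp(-0.5 * (offsets / s) ** 2)
    s_wave = 0.45 * np.exp(-0.5 * ((offsets - 1.8 * s) / (0.7 * s)) ** 2)
    h = amplitude * (r_wave - s_wave)
    offsets = offsets - offsets[np.argmax(np.abs(h))]
    return offsets, h


def synthesize_ecg(
    rr_series,
    params: CardiacParams,
    rng=None,
    noise_sd: float = 0.0,
    pad_s: float = 0.5,
):
    """Place a QRS-like template at each cumulative RR position.

    Returns ``(ECGTrace, true_peak_indices)``; the ground-truth index of
    each beat is the sample of the template's positive extremum.
    """
    rr = np.asarray(rr_series, dtype=float)
    if rr.size == 0:
        raise ValueError("rr_series is empty")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    fs = params.fs
    peaks = np.round(np.cumsum(rr) * fs / 1000.0).astype(int)
    n = peaks[-1] + int(round(pad_s * fs)) + 1
    trace = np.zeros(n)
    offsets, tmpl = _qrs_template(fs, params.qrs_amplitude)
    _scatter_add(trace, peaks, offsets, np.broadcast_to(tmpl, (peaks.size, tmpl.size)))
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        trace = trace + noise_sd * rng.standard_normal(n)
    return ECGTrace(trace, fs), peaks


def _scatter_add(signal_out, centers, offsets, values):
    """Add values[b, :] into signal_out around each center, clipping edges."""
    n = signal_out.size
    idx = centers[:, None] + offsets[None, :]
    ok = (idx >= 0) & (idx < n)
    np.add.at(signal_out, idx[ok], np.asarray(values)[ok])


def _pink_noise(n: int, rng) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    spec *= scale
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _draw_phases(osc: OscillationSpec, n_beats: int, rng) -> np.ndarray:
    if osc.phase_kappa is None or np.isinf(osc.phase_kappa):
        return np.full(n_beats, osc.phase_mu)
    if osc.phase_kappa == 0:
        return rng.uniform(-np.pi, np.pi, n_beats)
    return rng.vonmises(osc.phase_mu, osc.phase_kappa, n_beats)


def generate_recording(config: SessionConfig, rng=None) -> SimulatedSession:
    """Build the full synthetic session (ECG + ROI channels + annotations).

    Blocks alternate between conditions (A, B, A, B, ...).  For each beat of
    a block, every ROI receives (i) a Gaussian evoked bump at the condition's
    bump latency, (ii) its oscillatory bursts with per-beat von Mises phases
    (lagged copies for coupled ROIs), and (iii) white plus 1/f noise.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    cond_names = list(config.conditions)
    block_labels = cond_names * config.n_blocks_per_condition  # A,B,A,B,...
    fs = next(iter(config.conditions.values())).cardiac.fs
    block_len = int(round(config.block_duration_s * fs))
    n_samples = block_len * len(block_labels)

    annotations = []
    beats_by_cond = {c: [] for c in cond_names}
    for b, cond in enumerate(block_labels):
        start = b * block_len
        annotations.append((start / fs, (start + block_len) / fs, cond))
        cp = config.conditions[cond].cardiac
        n_est = int(config.block_duration_s * 1000.0 / cp.mean_rr) + 10
        rr = generate_rr_series(cp, max(n_est, 2), rng)
        beat_ms = np.cumsum(rr)
        # keep beats whose epoch window [-200, +600] ms stays inside the block
        beat_ms = beat_ms[beat_ms < config.block_duration_s * 1000.0 - 650.0]
        beats_by_cond[cond].append(start + np.round(beat_ms * fs / 1000.0).astype(int))
    beats_by_cond = {c: np.concatenate(v) for c, v in beats_by_cond.items()}
    all_beats = np.sort(np.concatenate(list(beats_by_cond.values())))

    # --- ECG channel
    ecg = np.zeros(n_samples)
    for cond in cond_names:
        cp = config.conditions[cond].cardiac
        offs, tmpl = _qrs_template(fs, cp.qrs_amplitude)
        beats = beats_by_cond[cond]
        _scatter_add(ecg, beats, offs, np.broadcast_to(tmpl, (beats.size, tmpl.size)))
    if config.ecg_noise_sd > 0:
        ecg += config.ecg_noise_sd * rng.standard_normal(n_samples)

    # --- ROI channels
    rois = list(config.rois)
    data = np.zeros((n_samples, len(rois)))
    phases_by_cond = {}
    for cond in cond_names:
        spec = config.conditions[cond]
        beats = beats_by_cond[cond]
        nb = beats.size

        # evoked bump on every ROI
        if spec.bump_amplitude != 0:
            sd = spec.bump_sd_ms * fs / 1000.0
            center = int(round(spec.bump_latency_ms * fs / 1000.0))
            offs = np.arange(-int(round(4 * sd)), int(round(4 * sd)) + 1) + center
            kern = spec.bump_amplitude * np.exp(
                -0.5 * ((offs - spec.bump_latency_ms * fs / 1000.0) / sd) ** 2
            )
            for j in range(len(rois)):
                _scatter_add(data[:, j], beats, offs, np.broadcast_to(kern, (nb, kern.size)))

        # oscillatory bursts: draw source phases first, then lagged copies
        phases = {}
        for osc in spec.oscillations:
            if osc.lag_from is None:
                phases[(osc.roi, osc.freq)] = _draw_phases(osc, nb, rng)
        for osc in spec.oscillations:
            if osc.lag_from is not None:
                src_roi, lag = osc.lag_from
                key = (src_roi, osc.freq)
                if key not in phases:
                    raise ValueError(
                        f"lag_from references missing oscillation {key!r}"
                    )
                phases[(osc.roi, osc.freq)] = phases[key] + lag

        for osc in spec.oscillations:
            phi = phases[(osc.roi, osc.freq)]
            sd = osc.envelope_sd_ms * fs / 1000.0
            lock = osc.lock_latency_ms * fs / 1000.0
            offs = np.arange(
                int(round(lock - 4 * sd)), int(round(lock + 4 * sd)) + 1
            )
            t_rel = (offs - lock) / fs  # seconds relative to lock latency
            env = osc.amplitude * np.exp(-0.5 * ((offs - lock) / sd) ** 2)
            wave = env[None, :] * np.cos(
                2.0 * np.pi * osc.freq * t_rel[None, :] + phi[:, None]
            )
            j = rois.index(osc.roi)
            _scatter_add(data[:, j], beats, offs, wave)
        phases_by_cond[cond] = phases

    # --- noise: per-ROI white + pink, scaled block-wise so each block gets
    # its condition's noise level.
    for j in range(len(rois)):
        white = rng.standard_normal(n_samples)
        pink = _pink_noise(n_samples, rng)
        for b, cond in enumerate(block_labels):
            spec = config.conditions[cond]
            sl = slice(b * block_len, (b + 1) * block_len)
            data[sl, j] += spec.noise_white_sd * white[sl]
            data[sl, j] += spec.noise_pink_sd * pink[sl]

    types = [config.channel_types.get(r, "source") for r in rois]
    recording = MultiChannelRecording(
        data=data,
        fs=fs,
        channel_labels=rois,
        channel_types=types,
        annotations=annotations,
    )
    return SimulatedSession(
        recording=recording,
        ecg=ECGTrace(ecg, fs),
        true_peaks=all_beats,
        beats_by_condition=beats_by_cond,
        phases_by_condition=phases_by_cond,
        config=config,
    )


# ---------------------------------------------------------------------------
# Default study conditions

SEED_ROI = "R_ant_ventral_insula"
COUPLED_ROI = "L_VMPFC"
DEFAULT_ROIS = [SEED_ROI, COUPLED_ROI, "L_pars_opercularis", "R_post_cingulate"]


def default_session_config(seed: int = 0, block_duration_s: float = 180.0,
                           n_blocks_per_condition: int = 2) -> SessionConfig:
    """The bundled study conditions.

    ``disgust``: phase-locked bursts (kappa=2) at 19 and 23 Hz on the insular
    seed near 420 ms, plus a random-phase 20 Hz burst shared between the seed
    and L_VMPFC with a constant 0.5 rad lag (beta coupling).  ``control``:
    a phase-locked 14 Hz burst near 300 ms on the seed.  Both conditions have
    the same cardiac regime (~66.7 bpm, SDNN ~43 ms, RMSSD ~35 ms) and the
    same evoked bump and noise levels.
    """
    def cardiac():
        return CardiacParams(mean_rr=900.0, rr_sd=43.0, rr_ar1=0.67)

    disgust = ConditionSpec(
        cardiac=cardiac(),
        oscillations=[
            OscillationSpec(SEED_ROI, 19.0, amplitude=1.0, phase_kappa=2.0,
                            lock_latency_ms=420.0, envelope_sd_ms=100.0),
            OscillationSpec(SEED_ROI, 23.0, amplitude=1.0, phase_kappa=2.0,
                            lock_latency_ms=420.0, envelope_sd_ms=100.0),
            OscillationSpec(SEED_ROI, 20.0, amplitude=1.0, phase_kappa=0.0,
                            lock_latency_ms=350.0, envelope_sd_ms=150.0),
            OscillationSpec(COUPLED_ROI, 20.0, amplitude=1.0,
                            lock_latency_ms=350.0, envelope_sd_ms=150.0,
                            lag_from=(SEED_ROI, 0.5)),
        ],
    )
    control = ConditionSpec(
        cardiac=cardiac(),
        oscillations=[
            OscillationSpec(SEED_ROI, 14.0, amplitude=1.0, phase_kappa=2.0,
                            lock_latency_ms=300.0, envelope_sd_ms=100.0),
        ],
    )
    return SessionConfig(
        conditions={"disgust": disgust, "control": control},
        rois=list(DEFAULT_ROIS),
        block_duration_s=block_duration_s,
        n_blocks_per_condition=n_blocks_per_condition,
        seed=seed,
    )


def subject_session_config(base: SessionConfig, subject_rng) -> SessionConfig:
    """Per-subject variant of a session config with jittered heart rate.

    Mean RR is drawn N(900, 120) ms clipped to [650, 1250] (heart rates of
    48-92 bpm, matching the between-subject spread of ~66.6 +/- 8.9 bpm and
    a 6-min beat count in the 290-550 range).
    """
    mean_rr = float(np.clip(subject_rng.normal(900.0, 120.0), 650.0, 1250.0))
    rr_sd = float(np.clip(subject_rng.normal(43.0, 10.0), 15.0, 90.0))
    conditions = {}
    for name, spec in base.conditions.items():
        cp = replace(spec.cardiac, mean_rr=mean_rr, rr_sd=rr_sd)
        conditions[name] = replace(spec, cardiac=cp)
    seed = int(subject_rng.integers(0, 2**31 - 1))
    return replace(base, conditions=conditions, seed=seed)
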