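import numpy as np
import pytest

from hefpipe.epoching import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(
    data,
    fs=1000.0,
    tmin_ms=-200.0,
    condition="test",
    channel_types=None,
    channel_labels=None,
):
    """Build an EpochSet straight from a (trials, channels, times) array."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_times = data.shape
    times_ms = tmin_ms + np.arange(n_times) * 1000.0 / fs
    return EpochSet(
        data=data,
        times_ms=times_ms,
        fs=fs,
        triggers=np.arange(n_trials) * n_times + int(-tmin_ms * fs / 1000),
        condition=condition,
        channel_labels=channel_labels or [f"ch{i}" for i in range(n_ch)],
        channel_types=channel_types or ["source"] * n_ch,
    )


@pytest.fixture
def make_epochs_factory():
    return make_epochs


@pytest.fixture(scope="session")
def clean_session():
    """Small noise-free session: deterministic phases, no noise.

    One 60 s block per condition; used for perfect-locking and
    constant-lag ground-truth checks.
    """
    from hefpipe import synthetic

    disgust = synthetic.ConditionSpec(
        cardiac=synthetic.CardiacParams(mean_rr=900.0, rr_sd=20.0, rr_ar1=0.0),
        oscillations=[
            # perfect locking on its own ROI (kept out of the seed's band
            # content so the seed<->coupled phase difference stays constant)
            synthetic.OscillationSpec(
                "L_pars_opercularis", 19.0, phase_kappa=None,
                lock_latency_ms=400.0, envelope_sd_ms=120.0,
            ),
            synthetic.OscillationSpec(
                synthetic.SEED_ROI, 16.0, phase_kappa=0.0,
                lock_latency_ms=350.0, envelope_sd_ms=150.0,
            ),
            synthetic.OscillationSpec(
                synthetic.COUPLED_ROI, 16.0,
                lock_latency_ms=350.0, envelope_sd_ms=150.0,
                lag_from=(synthetic.SEED_ROI, 0.5),
            ),
        ],
        noise_white_sd=0.0,
        noise_pink_sd=0.0,
    )
    control = synthetic.ConditionSpec(
        cardiac=synthetic.CardiacParams(mean_rr=900.0, rr_sd=20.0, rr_ar1=0.0),
        oscillations=[],
        noise_white_sd=0.0,
        noise_pink_sd=0.0,
    )
    cfg = synthetic.SessionConfig(
        conditions={"disgust": disgust, "control": control},
        rois=list(synthetic.DEFAULT_ROIS),
        block_duration_s=60.0,
        n_blocks_per_condition=1,
        seed=7,
    )
    return synthetic.generate_recording(cfg)


@pytest.fixture(scope="session")
def noisy_session():
    """One subject under the bundled study conditions (short blocks)."""
    from hefpipe import synthetic

    cfg = synthetic.default_session_config(
        seed=11, block_duration_s=120.0, n_blocks_per_condition=1
    )
    return synthetic.generate_recording(cfg)
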