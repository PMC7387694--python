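import numpy as np
import pytest

from hefpipe.epoching import (
    EvokedResponse,
    MultiChannelRecording,
    average_evoked,
    decimate_epochs,
    extract_epochs,
    reject_epochs,
    subtract_conditions,
)

from conftest import make_epochs


@pytest.fixture
def recording(rng):
    data = rng.standard_normal((8000, 2))
    return MultiChannelRecording(
        data=data,
        fs=1000.0,
        channel_labels=["MEG1", "ROI1"],
        channel_types=["magnetometer", "source"],
        annotations=[(0.0, 4.0, "a"), (4.0, 8.0, "b")],
    )


class TestExtractEpochs:
    def test_window_is_801_samples_at_1khz(self, recording):
        ep = extract_epochs(recording, np.array([1000, 2000]), "a")
        assert ep.data.shape == (2, 2, 801)
        assert ep.times_ms[0] == -200.0 and ep.times_ms[-1] == 600.0

    def test_edge_and_annotation_exclusion_are_counted(self, recording):
        # 100: clips the left edge; 4500: other condition; 7900: clips right edge
        peaks = np.array([100, 1000, 2500, 4500, 7900])
        ep = extract_epochs(recording, peaks, "a")
        assert ep.n_trials == 2
        assert ep.n_edge_excluded == 1
        assert ep.n_outside_blocks == 2  # 4500 in 'b', 7900 also outside 'a'
        assert ep.n_trials + ep.n_edge_excluded + ep.n_outside_blocks == peaks.size

    def test_epoch_values_come_from_the_recording(self, recording):
        ep = extract_epochs(recording, np.array([1000]), "a")
        assert np.array_equal(ep.data[0, 0], recording.data[800:1601, 0])

    def test_unknown_condition_rejected(self, recording):
        with pytest.raises(ValueError, match="not present"):
            extract_epochs(recording, np.array([1000]), "c")

    def test_no_usable_triggers_rejected(self, recording):
        with pytest.raises(ValueError, match="no usable"):
            extract_epochs(recording, np.array([100]), "a")


class TestRejectEpochs:
    def _epochs(self, mag_scale, src_scale=1.0):
        data = np.zeros((3, 2, 101))
        data[1, 0, 50] = mag_scale  # peak-to-peak = mag_scale on the magnetometer
        data[2, 1, 50] = src_scale
        return make_epochs(data, channel_types=["magnetometer", "source"])

    def test_strictly_above_threshold_rejected(self):
        ep = reject_epochs(self._epochs(500.0))
        assert list(ep.rejected_mask) == [False, True, False]
        assert "magnetometer" in ep.reject_reasons[1]

    def test_exactly_at_threshold_retained(self):
        ep = reject_epochs(self._epochs(400.0))
        assert ep.n_rejected == 0

    def test_source_channels_never_reject(self):
        ep = reject_epochs(self._epochs(0.0, src_scale=1e9))
        assert ep.n_rejected == 0

    def test_gradiometer_threshold(self):
        data = np.zeros((2, 1, 101))
        data[0, 0, 50] = 4000.5
        ep = reject_epochs(make_epochs(data, channel_types=["gradiometer"]))
        assert list(ep.rejected_mask) == [True, False]

    def test_clean_synthetic_set_fully_retained(self, rng):
        data = 10.0 * rng.standard_normal((20, 2, 101))
        ep = reject_epochs(
            make_epochs(data, channel_types=["magnetometer", "gradiometer"])
        )
        assert ep.n_rejected == 0
        assert ep.n_retained + ep.n_rejected == ep.n_trials


class TestAverageEvoked:
    def test_identical_epochs_average_to_one_epoch(self, rng):
        one = rng.standard_normal((1, 2, 101))
        ep = make_epochs(np.repeat(one, 5, axis=0))
        ev = average_evoked(ep, baseline_correct=False)
        assert np.allclose(ev.data, one[0])
        assert ev.n_trials == 5

    def test_baseline_correction_zeroes_prestim_mean(self, rng):
        data = rng.standard_normal((10, 2, 801)) + 5.0
        ev = average_evoked(make_epochs(data), baseline_correct=True)
        base = ev.times_ms <= 0
        assert np.allclose(ev.data[:, base].mean(axis=1), 0.0, atol=1e-12)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        """Quadrupling trials halves the residual RMS of the average."""
        data = rng.standard_normal((400, 1, 201))
        rms_100 = np.sqrt(
            (average_evoked(make_epochs(data[:100]), False).data ** 2).mean()
        )
        rms_400 = np.sqrt((average_evoked(make_epochs(data), False).data ** 2).mean())
        assert rms_400 / rms_100 == pytest.approx(0.5, rel=0.20)

    def test_linearity_in_recording_scale(self, rng):
        data = rng.standard_normal((7, 2, 101))
        ev1 = average_evoked(make_epochs(data), baseline_correct=False)
        ev3 = average_evoked(make_epochs(3.0 * data), baseline_correct=False)
        assert np.allclose(ev3.data, 3.0 * ev1.data)

    def test_all_rejected_is_an_error(self, rng):
        ep = make_epochs(rng.standard_normal((3, 1, 101)))
        ep.rejected_mask[:] = True
        with pytest.raises(ValueError, match="no retained"):
            average_evoked(ep)

    def test_recovers_planted_bump_latency(self):
        """Evoked peak lands at the generator's bump latency (~265 ms)."""
        from hefpipe import synthetic
        from hefpipe.cardiac import detect_r_peaks

        # oscillation-free conditions: the bump is the only locked component
        cond = lambda: synthetic.ConditionSpec(
            noise_white_sd=0.5, noise_pink_sd=0.25
        )
        cfg = synthetic.SessionConfig(
            conditions={"disgust": cond(), "control": cond()},
            rois=list(synthetic.DEFAULT_ROIS),
            block_duration_s=120.0,
            n_blocks_per_condition=1,
            seed=31,
        )
        sess = synthetic.generate_recording(cfg)
        peaks = detect_r_peaks(sess.ecg)
        ep = extract_epochs(sess.recording, peaks, "control")
        ev = average_evoked(ep)
        ch = ev.channel_index(synthetic.SEED_ROI)
        peak_ms = ev.times_ms[np.argmax(ev.data[ch])]
        assert abs(peak_ms - 265.0) <= 10.0


class TestSubtract:
    def test_self_subtraction_is_zero(self, rng):
        ev = average_evoked(make_epochs(rng.standard_normal((4, 2, 101))))
        diff = subtract_conditions(ev, ev)
        assert np.allclose(diff.data, 0.0)

    def test_zero_reference_returns_original(self, rng):
        ev = average_evoked(make_epochs(rng.standard_normal((4, 2, 101))))
        zero = EvokedResponse(
            np.zeros_like(ev.data), ev.times_ms, 4, "z", list(ev.channel_labels)
        )
        assert np.allclose(subtract_conditions(ev, zero).data, ev.data)

    def test_mismatched_channels_rejected(self, rng):
        ev1 = average_evoked(make_epochs(rng.standard_normal((4, 2, 101))))
        ev2 = average_evoked(
            make_epochs(
                rng.standard_normal((4, 2, 101)), channel_labels=["x", "y"]
            )
        )
        with pytest.raises(ValueError, match="channel"):
            subtract_conditions(ev1, ev2)


class TestDecimate:
    def test_band_limited_signal_survives(self):
        fs = 1000.0
        t = np.arange(801) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        ep = make_epochs(sig[None, None, :], fs=fs)
        dec = decimate_epochs(ep, 4)
        assert dec.fs == 250.0
        assert dec.times_ms[1] - dec.times_ms[0] == 4.0
        mid = slice(30, 170)  # away from filter transients
        assert np.allclose(dec.data[0, 0, mid], sig[::4][mid], atol=0.01)

    def test_factor_one_is_identity(self, rng):
        ep = make_epochs(rng.standard_normal((2, 1, 101)))
        assert decimate_epochs(ep, 1) is ep
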