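import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hefpipe.spectral import (
    induced_power,
    itc,
    itc_from_epochs,
    morlet_transform,
    normalize_zmap,
    reference_stats,
)

from conftest import make_epochs

FS = 1000.0


def _cosine_epochs(freq, n_trials=3, n_times=801, phases=None, amp=1.0):
    t = np.arange(n_times) / FS
    phases = np.zeros(n_trials) if phases is None else np.asarray(phases)
    data = amp * np.cos(2 * np.pi * freq * t[None, :] + phases[:, None])
    return make_epochs(data[:, None, :], fs=FS)


def brute_force_itc(coeffs):
    """Independent oracle: angles per trial, then mean resultant length."""
    n_trials = coeffs.shape[0]
    out = np.zeros(coeffs.shape[1:])
    flat = coeffs.reshape(n_trials, -1)
    res = []
    for j in range(flat.shape[1]):
        cos_sum = 0.0
        sin_sum = 0.0
        for k in range(n_trials):
            ang = np.angle(flat[k, j])
            cos_sum += np.cos(ang)
            sin_sum += np.sin(ang)
        res.append(np.hypot(cos_sum / n_trials, sin_sum / n_trials))
    return np.array(res).reshape(out.shape)


class TestMorlet:
    def test_pure_tone_peaks_at_its_frequency(self):
        ep = _cosine_epochs(19.0)
        tf = morlet_transform(ep, freqs=np.arange(8.0, 25.0))
        mag = np.abs(tf.coeffs[0, 0])  # (freq, time)
        interior = tf.valid.all(axis=0)
        assert np.all(mag[:, interior].argmax(axis=0) == 11)  # 19 Hz row
        # normalization: unit cosine -> |F| ~ 0.5 at the matching frequency
        assert np.allclose(mag[11, interior], 0.5, rtol=0.02)

    def test_dc_epoch_yields_null_coefficients(self):
        ep = make_epochs(np.full((2, 1, 801), 7.0))
        tf = morlet_transform(ep, freqs=np.arange(8.0, 25.0))
        assert np.all(np.abs(tf.coeffs[:, :, :, tf.valid.all(axis=0)]) < 1e-6 * 7.0)

    def test_shift_covariance(self, rng):
        """Sliding the analysis window slides the coefficients with it."""
        x = rng.standard_normal(901)
        shift = 40
        ep_a = make_epochs(x[None, None, :801])
        ep_b = make_epochs(x[None, None, shift : shift + 801])
        tf_a = morlet_transform(ep_a)
        tf_b = morlet_transform(ep_b)
        # compare times whose wavelet support lies inside both windows
        sl_a = slice(390, 450)
        sl_b = slice(390 - shift, 450 - shift)
        assert np.allclose(
            tf_a.coeffs[0, 0, :, sl_a], tf_b.coeffs[0, 0, :, sl_b], rtol=1e-9
        )

    def test_overlong_wavelet_names_frequency(self):
        ep = make_epochs(np.zeros((1, 1, 200)))
        with pytest.raises(ValueError, match="8"):
            morlet_transform(ep, freqs=np.array([8.0]))

    def test_edge_samples_flagged_invalid(self):
        ep = make_epochs(np.zeros((1, 1, 801)))
        tf = morlet_transform(ep, freqs=np.array([8.0, 24.0]))
        assert not tf.valid[0, 0] and not tf.valid[0, -1]
        assert tf.valid[1].sum() > tf.valid[0].sum()  # higher f, shorter wavelet


class TestInducedPower:
    def test_single_trial_power_is_squared_modulus(self, rng):
        ep = make_epochs(rng.standard_normal((1, 1, 801)))
        tf = morlet_transform(ep)
        pw = induced_power(tf)
        assert np.allclose(pw.values, np.abs(tf.coeffs[0]) ** 2)

    def test_quadratic_amplitude_scaling(self):
        p1 = induced_power(morlet_transform(_cosine_epochs(14.0, amp=1.0)))
        p2 = induced_power(morlet_transform(_cosine_epochs(14.0, amp=2.0)))
        assert np.allclose(p2.values, 4.0 * p1.values, rtol=1e-9)

    def test_power_is_phase_blind(self):
        pa = induced_power(
            morlet_transform(_cosine_epochs(14.0, n_trials=2, phases=[0.0, 0.0]))
        )
        pb = induced_power(
            morlet_transform(_cosine_epochs(14.0, n_trials=2, phases=[0.0, np.pi]))
        )
        mid = pa.valid
        assert np.allclose(pa.values[0][mid], pb.values[0][mid], rtol=1e-6)


class TestITC:
    def test_identical_phases_give_unity(self):
        ep = _cosine_epochs(19.0, n_trials=8)
        m = itc(morlet_transform(ep))
        assert np.allclose(m.values[0][m.valid], 1.0, atol=1e-9)

    def test_opposite_phases_cancel(self):
        ep = _cosine_epochs(19.0, n_trials=2, phases=[0.0, np.pi])
        m = itc(morlet_transform(ep, freqs=np.array([19.0])))
        assert np.all(m.values[0][m.valid] < 1e-9)

    def test_matches_brute_force_loop(self, rng):
        from hefpipe.spectral import TFCoefficients

        coeffs = rng.standard_normal((30, 1, 3, 5)) + 1j * rng.standard_normal(
            (30, 1, 3, 5)
        )
        tf = TFCoefficients(
            coeffs=coeffs,
            freqs=np.array([8.0, 9.0, 10.0]),
            times_ms=np.arange(5.0),
            n_cycles=7.0,
            valid=np.ones((3, 5), dtype=bool),
            channel_labels=["ch0"],
        )
        assert np.allclose(
            itc(tf).values, brute_force_itc(coeffs), atol=1e-12
        )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_on_arbitrary_coefficients(self, seed):
        from hefpipe.spectral import TFCoefficients

        r = np.random.default_rng(seed)
        coeffs = r.standard_normal((7, 1, 2, 4)) + 1j * r.standard_normal((7, 1, 2, 4))
        tf = TFCoefficients(
            coeffs=coeffs,
            freqs=np.array([8.0, 9.0]),
            times_ms=np.arange(4.0),
            n_cycles=7.0,
            valid=np.ones((2, 4), dtype=bool),
            channel_labels=["ch0"],
        )
        v = itc(tf).values
        assert np.all(v >= 0.0) and np.all(v <= 1.0 + 1e-12)

    def test_invariant_to_per_trial_amplitude(self, rng):
        from hefpipe.spectral import TFCoefficients

        coeffs = rng.standard_normal((12, 1, 2, 6)) + 1j * rng.standard_normal(
            (12, 1, 2, 6)
        )
        scales = rng.uniform(0.1, 10.0, size=12)[:, None, None, None]
        mk = lambda c: TFCoefficients(
            coeffs=c,
            freqs=np.array([8.0, 9.0]),
            times_ms=np.arange(6.0),
            n_cycles=7.0,
            valid=np.ones((2, 6), dtype=bool),
            channel_labels=["ch0"],
        )
        assert np.allclose(
            itc(mk(coeffs)).values, itc(mk(scales * coeffs)).values, atol=1e-12
        )

    def test_uniform_phase_null_level(self, rng):
        """Mean resultant length of uniform phasors ~ sqrt(pi)/(2 sqrt(n))."""
        n = 200
        reps = 300
        phases = rng.uniform(-np.pi, np.pi, size=(reps, n))
        r_vals = np.abs(np.exp(1j * phases).mean(axis=1))
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        se = r_vals.std(ddof=1) / np.sqrt(reps)
        assert abs(r_vals.mean() - expected) < 3 * se

    def test_monotone_in_von_mises_concentration(self):
        from hefpipe.spectral import TFCoefficients

        r = np.random.default_rng(99)
        levels = []
        for kappa in (0.0, 1.0, 4.0, 16.0):
            ph = (
                r.uniform(-np.pi, np.pi, 300)
                if kappa == 0
                else r.vonmises(0.0, kappa, 300)
            )
            coeffs = np.exp(1j * ph)[:, None, None, None]
            tf = TFCoefficients(
                coeffs=coeffs,
                freqs=np.array([19.0]),
                times_ms=np.array([0.0]),
                n_cycles=7.0,
                valid=np.ones((1, 1), dtype=bool),
                channel_labels=["ch0"],
            )
            levels.append(itc(tf).values.item())
        assert np.all(np.diff(levels) > 0)

    def test_streaming_path_matches_op_route(self, rng):
        ep = make_epochs(rng.standard_normal((10, 2, 801)))
        a = itc(morlet_transform(ep))
        b = itc_from_epochs(ep)
        assert np.array_equal(a.valid, b.valid)
        assert np.allclose(a.values[:, a.valid], b.values[:, a.valid], atol=1e-5)

    def test_agrees_with_mne_oracle(self, rng):
        """Cross-check against an independent Morlet ITC implementation."""
        mne = pytest.importorskip("mne")
        data = rng.standard_normal((20, 1, 801))
        # plant partial locking so the comparison is not all-noise
        t = np.arange(801) / FS
        ph = rng.vonmises(0.0, 2.0, 20)
        data += 2.0 * np.cos(2 * np.pi * 19.0 * t[None, None, :] + ph[:, None, None])
        ep = make_epochs(data, fs=FS)
        freqs = np.arange(14.0, 25.0)  # mne's 5-sigma wavelets must fit too
        ours = itc(morlet_transform(ep, freqs=freqs, n_cycles=7.0))
        out = mne.time_frequency.tfr_array_morlet(
            data, FS, freqs, n_cycles=7.0, output="itc", zero_mean=True
        )
        # restrict to samples where both implementations have full wavelet
        # overlap (mne truncates at 5 sigma, we truncate earlier)
        both = ours.valid.copy()
        n_times = ours.times_ms.size
        for i, f in enumerate(freqs):
            half = int(np.ceil(5.0 * 7.0 / (2 * np.pi * f) * FS))
            both[i, :half] = False
            both[i, n_times - half :] = False
        assert both.any()
        assert np.allclose(ours.values[0][both], out[0][both], atol=0.05)


@pytest.fixture(scope="module")
def clean_itc(clean_session):
    from hefpipe.cardiac import detect_r_peaks
    from hefpipe.epoching import extract_epochs

    peaks = detect_r_peaks(clean_session.ecg)
    ep = extract_epochs(clean_session.recording, peaks, "disgust")
    return itc(morlet_transform(ep, freqs=np.arange(14.0, 25.0)))


class TestGeneratorGroundTruth:
    def test_deterministic_phase_gives_full_coherence(self, clean_itc):
        """kappa -> infinity limit: ITC at (f, lock latency) -> 1."""
        m = clean_itc
        ch = m.channel_index("L_pars_opercularis")
        fi = int(np.flatnonzero(m.freqs == 19.0)[0])
        ti = int(np.argmin(np.abs(m.times_ms - 400.0)))
        assert m.valid[fi, ti]
        assert m.values[ch, fi, ti] > 0.98

    def test_uniform_phase_stays_near_null_level(self, clean_itc):
        """kappa = 0: ITC at the lock point stays near E[R_n] for uniform
        phases (sqrt(pi)/(2 sqrt(n)) plus sampling spread)."""
        from hefpipe.synthetic import SEED_ROI

        m = clean_itc
        ch = m.channel_index(SEED_ROI)
        fi = int(np.flatnonzero(m.freqs == 16.0)[0])
        ti = int(np.argmin(np.abs(m.times_ms - 350.0)))
        n = m.n_trials
        expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
        # R_n concentrates below ~3x its mean for uniform phases
        assert m.values[ch, fi, ti] < expected + 3.0 / np.sqrt(n)


class TestNormalization:
    def _map(self, values, valid=None):
        from hefpipe.spectral import TFMap

        values = np.asarray(values, dtype=float)
        return TFMap(
            values=values,
            freqs=np.arange(values.shape[1], dtype=float) + 8.0,
            times_ms=np.arange(values.shape[2], dtype=float) * 100.0,
            n_trials=10,
            valid=np.ones(values.shape[1:], dtype=bool) if valid is None else valid,
            channel_labels=["ch0"],
        )

    def test_reference_stats_hand_computed(self):
        m = self._map(np.arange(12.0).reshape(1, 3, 4))
        mean, sd = reference_stats(m, "ch0", t_window_ms=(0.0, 300.0),
                                   f_window_hz=(8.0, 10.0))
        vals = np.arange(12.0)
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=1))

    def test_uniform_map_has_zero_sd_and_blocks_zmap(self):
        m = self._map(np.full((1, 3, 4), 2.5))
        mean, sd = reference_stats(m, "ch0")
        assert (mean, sd) == (2.5, 0.0)
        with pytest.raises(ValueError, match="SD"):
            normalize_zmap(m, (mean, sd))

    def test_single_point_window_rejected(self):
        m = self._map(np.arange(12.0).reshape(1, 3, 4))
        with pytest.raises(ValueError, match="single valid point"):
            reference_stats(m, "ch0", t_window_ms=(0.0, 0.0), f_window_hz=(8.0, 8.0))

    def test_empty_window_rejected(self):
        m = self._map(np.arange(12.0).reshape(1, 3, 4))
        with pytest.raises(ValueError, match="empty"):
            reference_stats(m, "ch0", t_window_ms=(900.0, 950.0))

    def test_identity_and_centering(self, rng):
        m = self._map(rng.standard_normal((1, 3, 4)))
        z = normalize_zmap(m, (0.0, 1.0))
        assert np.allclose(z.values, m.values)
        z2 = normalize_zmap(m, (m.values.mean(), 2.0))
        assert z2.values.mean() == pytest.approx(0.0, abs=1e-12)
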