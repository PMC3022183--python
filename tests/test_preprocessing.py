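import numpy as np
import pytest

from eegtopo import (
    MarkerList,
    Recording,
    average_epochs,
    downsample,
    envelope,
    extract_epochs,
    filter_recording,
    gfp_curve,
    reject_epochs_amplitude,
    rereference,
)


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestRereference:
    def test_average_reference_zero_column_sums(self, random_recording):
        out = rereference(random_recording, "average")
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-9)
        assert out.reference == "average"

    def test_single_channel_becomes_zero(self, rng):
        rec = Recording(data=rng.normal(size=(3, 10)), sampling_rate=100.0)
        out = rereference(rec, "E2")
        np.testing.assert_allclose(out.data[1], 0.0, atol=1e-12)

    def test_simple_column(self):
        rec = Recording(data=np.array([[1.0], [2.0], [3.0]]),
                        sampling_rate=100.0)
        out = rereference(rec, "average")
        np.testing.assert_allclose(out.data[:, 0], [-1.0, 0.0, 1.0])

    def test_gfp_invariance(self, random_recording):
        base = gfp_curve(random_recording)
        for target in ["average", "E1", ["E2", "E5"]]:
            out = rereference(random_recording, target)
            np.testing.assert_allclose(gfp_curve(out), base, atol=1e-9)

    def test_unknown_channel_rejected(self, random_recording):
        with pytest.raises(ValueError):
            rereference(random_recording, "Oz")


class TestFilter:
    def test_remove_dc_zeroes_constant_channel(self):
        data = np.vstack([np.full(100, 7.0), np.zeros(100)])
        rec = Recording(data=data, sampling_rate=100.0)
        out = filter_recording(rec, remove_dc=True)
        np.testing.assert_allclose(out.data[0], 0.0, atol=1e-12)

    def test_order2_rolloff_12db_per_octave(self):
        """Single-pass order-2 Butterworth attenuates ~12 dB more at 8fc
        than at 4fc in the far stop-band."""
        rate, fc = 1000.0, 10.0
        t = np.arange(int(rate * 20)) / rate
        att = []
        for f in (4 * fc, 8 * fc):
            x = np.sin(2 * np.pi * f * t)
            rec = Recording(data=np.vstack([x, x]), sampling_rate=rate)
            y = filter_recording(rec, high_hz=fc, order=2,
                                 zero_phase=False).data[0]
            steady = y[len(y) // 2 :]
            att.append(-20 * np.log10(_rms(steady) / _rms(x)))
        assert att[1] - att[0] == pytest.approx(12.0, abs=1.0)

    def test_notch_removes_line_frequency(self):
        rate = 500.0
        t = np.arange(int(rate * 30)) / rate
        x = np.sin(2 * np.pi * 50.0 * t)
        rec = Recording(data=np.vstack([x, x]), sampling_rate=rate)
        out = filter_recording(rec, notch_hz=50.0).data[0]
        assert _rms(out) < 0.05 * _rms(x)

    def test_cutoff_at_nyquist_rejected(self, random_recording):
        with pytest.raises(ValueError):
            filter_recording(random_recording, high_hz=125.0)

    def test_no_cross_channel_leakage(self, rng):
        """An impulse on channel 0 must produce nothing on channel 1."""
        data = np.zeros((3, 200))
        data[0, 100] = 1.0
        rec = Recording(data=data, sampling_rate=250.0)
        for out in (
            filter_recording(rec, low_hz=1.0, high_hz=40.0),
            downsample(rec, 2),
            envelope(rec, "abs", smooth_hz=10.0),
        ):
            assert np.abs(out.data[1]).max() == 0.0
            assert np.abs(out.data[0]).max() > 0.0


class TestEnvelope:
    def test_constant_input_abs(self):
        rec = Recording(data=np.full((2, 500), 3.0), sampling_rate=250.0)
        out = envelope(rec, "abs", smooth_hz=10.0)
        mid = out.data[0, 100:400]
        np.testing.assert_allclose(mid, 3.0, rtol=0.02)

    def test_rectified_sine_mean(self):
        rate, amp = 1000.0, 2.0
        t = np.arange(int(rate * 4)) / rate
        x = amp * np.sin(2 * np.pi * 20.0 * t)
        rec = Recording(data=np.vstack([x, x]), sampling_rate=rate)
        out = envelope(rec, "abs", smooth_hz=2.0)
        mid = out.data[0, 1000:3000].mean()
        assert mid == pytest.approx(2 * amp / np.pi, rel=0.05)

    def test_square_wave_squared(self):
        x = np.tile([1.0, -1.0], 250)
        rec = Recording(data=np.vstack([x, x]), sampling_rate=500.0)
        out = envelope(rec, "square", smooth_hz=5.0)
        np.testing.assert_allclose(out.data[0, 100:400], 1.0, rtol=0.02)

    def test_bad_mode_rejected(self, random_recording):
        with pytest.raises(ValueError):
            envelope(random_recording, "rectify")


class TestDownsample:
    def test_shape_and_rate(self, rng):
        rec = Recording(data=rng.normal(size=(4, 100)), sampling_rate=400.0)
        out = downsample(rec, 4)
        assert out.n_timeframes == 25
        assert out.sampling_rate == 100.0

    def test_dc_preserved(self):
        rec = Recording(data=np.full((2, 200), 5.0), sampling_rate=200.0)
        out = downsample(rec, 2)
        np.testing.assert_allclose(out.data, 5.0, rtol=0.01)

    def test_alias_tone_suppressed(self):
        rate = 1000.0
        t = np.arange(int(rate * 4)) / rate
        x = np.sin(2 * np.pi * 200.0 * t)  # above new Nyquist of 125 Hz
        rec = Recording(data=np.vstack([x, x]), sampling_rate=rate)
        out = downsample(rec, 4)
        assert 20 * np.log10(_rms(x) / _rms(out.data[0])) >= 20.0

    def test_factor_below_two_rejected(self, random_recording):
        with pytest.raises(ValueError):
            downsample(random_recording, 1)


class TestEpochs:
    @pytest.fixture()
    def rec_with_markers(self, rng):
        return Recording(data=rng.normal(size=(4, 120)), sampling_rate=250.0)

    def test_window_placement(self, rec_with_markers):
        ml = MarkerList(((50, 50, "stim"),))
        es = extract_epochs(rec_with_markers, ml, "stim", pre_tf=10,
                            post_tf=20)
        assert es.epochs.shape == (1, 4, 31)
        np.testing.assert_array_equal(es.epochs[0],
                                      rec_with_markers.data[:, 40:71])

    def test_out_of_bounds_dropped_with_count(self, rec_with_markers):
        ml = MarkerList(((2, 2, "stim"), (60, 60, "stim")))
        es = extract_epochs(rec_with_markers, ml, "stim", 10, 20)
        assert es.n_epochs == 1
        assert es.n_dropped == 1

    def test_order_preserved_and_label_filter(self, rec_with_markers):
        ml = MarkerList(((30, 30, "stim"), (40, 40, "other"),
                         (70, 70, "stim")))
        es = extract_epochs(rec_with_markers, ml, "stim", 5, 5)
        assert es.n_epochs == 2
        np.testing.assert_array_equal(es.epochs[0],
                                      rec_with_markers.data[:, 25:36])

    def test_absent_label_gives_empty_set(self, rec_with_markers):
        ml = MarkerList(((30, 30, "stim"),))
        es = extract_epochs(rec_with_markers, ml, "nope", 5, 5)
        assert es.n_epochs == 0


class TestRejectAndAverage:
    @pytest.fixture()
    def epochs(self, rng):
        rec = Recording(data=rng.normal(size=(4, 300)), sampling_rate=250.0)
        ml = MarkerList(tuple((t, t, "s") for t in (50, 100, 150, 200)))
        return extract_epochs(rec, ml, "s", 10, 10)

    def test_within_threshold_all_kept(self, epochs):
        assert reject_epochs_amplitude(epochs, 1e6).n_kept == epochs.n_epochs

    def test_single_bad_sample_rejects_only_that_epoch(self, epochs):
        bad = epochs.epochs.copy()
        peak = np.abs(bad).max()
        bad[2, 0, 5] = 2 * peak
        es = type(epochs)(epochs=bad, sampling_rate=epochs.sampling_rate,
                          event_label="s",
                          kept_mask=np.ones(epochs.n_epochs, bool))
        out = reject_epochs_amplitude(es, 1.5 * peak)
        assert list(out.kept_mask) == [True, True, False, True]

    def test_tiny_threshold_rejects_all(self, epochs):
        assert reject_epochs_amplitude(epochs, 1e-12).n_kept == 0

    def test_average_of_identical_epochs(self, rng):
        ep = np.repeat(rng.normal(size=(1, 3, 20)), 4, axis=0)
        from eegtopo import EpochSet

        es = EpochSet(epochs=ep, sampling_rate=250.0, event_label="s",
                      kept_mask=np.ones(4, bool))
        erp = average_epochs(es)
        np.testing.assert_allclose(erp.data, ep[0], atol=1e-12)

    def test_symmetric_noise_cancels(self, rng):
        sig = rng.normal(size=(3, 20))
        noise = rng.normal(size=(3, 20))
        from eegtopo import EpochSet

        es = EpochSet(epochs=np.stack([sig + noise, sig - noise]),
                      sampling_rate=250.0, event_label="s",
                      kept_mask=np.ones(2, bool))
        erp = average_epochs(es)
        np.testing.assert_allclose(erp.data, sig, atol=1e-12)

    def test_full_window_baseline_zeroes_means(self, epochs):
        erp = average_epochs(epochs, baseline_tf=(0, 20))
        np.testing.assert_allclose(erp.data.mean(axis=1), 0.0, atol=1e-12)

    def test_zero_kept_is_error(self, epochs):
        empty = reject_epochs_amplitude(epochs, 1e-12)
        with pytest.raises(ValueError):
            average_epochs(empty)
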