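"""Feature extraction, channel selection and delay embedding."""

import numpy as np
import pytest

from eegintent.core_io import ChannelLayout, EEGRecording
from eegintent.features import (
    FeatureSeries,
    band_power,
    build_feature_matrix,
    mrcp_amplitude,
    rms_series,
    select_channels,
)


def _rec(data, names=None, fs=500.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, layout=ChannelLayout(tuple(names)))


def _tone(f_hz, dur_s=30.0, fs=500.0):
    t = np.arange(int(dur_s * fs)) / fs
    return np.sin(2 * np.pi * f_hz * t)


class TestMRCPAmplitude:
    def test_passband_tone_preserved(self):
        out = mrcp_amplitude(_rec(_tone(1.0)))[0]
        core = out.values[2000:-2000]
        assert np.max(np.abs(core)) >= 0.7

    def test_stopband_tone_suppressed(self):
        out = mrcp_amplitude(_rec(_tone(10.0)))[0]
        assert np.max(np.abs(out.values[2000:-2000])) <= 0.1

    def test_zero_in_zero_out(self):
        out = mrcp_amplitude(_rec(np.zeros((2, 5000))))
        for s in out:
            assert np.allclose(s.values, 0.0)


class TestBandPower:
    def test_alpha_tone_power_is_half(self):
        """Unit 10 Hz sinusoid through unity-gain alpha band: mean sin^2 = 1/2."""
        out = band_power(_rec(_tone(10.0)), "alpha")[0]
        assert out.values.min() >= 0.0
        assert np.mean(out.values[2000:-2000]) == pytest.approx(0.5, rel=0.10)

    def test_alpha_tone_invisible_in_delta(self):
        out = band_power(_rec(_tone(10.0)), "delta")[0]
        assert np.mean(out.values[2000:-2000]) <= 0.01

    def test_zero_in_zero_out(self):
        out = band_power(_rec(np.zeros((1, 5000))), "alpha")[0]
        assert np.allclose(out.values, 0.0)

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="delta|alpha"):
            band_power(_rec(np.zeros((1, 5000))), "beta")


class TestRMS:
    def test_constant_signal_reproduced(self):
        out = rms_series(_rec(np.full((1, 1000), -3.0)), band=None)[0]
        np.testing.assert_allclose(out.values[10:], 3.0)

    def test_hand_computed_two_sample_window(self):
        """Samples (3, 4) with a 2-sample window: sqrt((9+16)/2)."""
        rec = _rec([[3.0, 4.0]], fs=500.0)
        out = rms_series(rec, window_ms=4.0, band=None)[0]
        assert out.values[1] == pytest.approx(np.sqrt(12.5))
        assert out.values[0] == pytest.approx(3.0)  # shorter prefix

    def test_window_sample_count_at_500hz(self):
        """400 ms at 500 Hz is a 200-sample window: constant reached
        exactly after 200 samples of a step input."""
        x = np.r_[np.zeros(300), np.ones(700)]
        out = rms_series(_rec([x]), window_ms=400.0, band=None)[0]
        assert out.values[300 + 199] == pytest.approx(1.0)
        assert out.values[300 + 198] < 1.0

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window exceeds signal"):
            rms_series(_rec(np.zeros((1, 10))), window_ms=400.0, band=None)

    def test_non_negative_everywhere(self, small_session):
        out = rms_series(small_session.eeg)
        for s in out:
            assert (s.values >= 0).all()


class TestSelectChannels:
    def _series(self, names, values, fs=500.0):
        return {
            n: FeatureSeries("mrcp", n, v, fs) for n, v in zip(names, values)
        }

    def test_override_short_circuits(self):
        sbc = self._series(["a", "b", "c"], np.zeros((3, 100)))
        labels = np.zeros(100, int)
        assert select_channels(sbc, labels, override=("FC2", "C2")) == ("FC2", "C2")
        assert select_channels(sbc, labels, override=("P3", "Pz")) == ("P3", "Pz")

    def test_event_locked_channel_ranked_first(self):
        rng = np.random.default_rng(0)
        labels = np.r_[np.zeros(500, int), np.ones(500, int)]
        quiet = rng.normal(0, 1, (4, 1000))
        active = rng.normal(0, 1, 1000)
        active[500:] -= 6.0  # event-locked negative shift on C2 only
        names = ["Fz", "C2", "Cz", "P3", "T3"]
        sbc = self._series(names, np.vstack([quiet[:1], active, quiet[1:]]))
        assert select_channels(sbc, labels, k=2)[0] == "C2"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.zeros(300, int), np.ones(300, int)]
        vals = rng.normal(0, 1, (5, 600))
        vals[2, 300:] += 3.0
        vals[4, 300:] += 1.5
        names = ["a", "b", "c", "d", "e"]
        fwd = select_channels(self._series(names, vals), labels, k=3)
        rev = select_channels(
            self._series(names[::-1], vals[::-1]), labels, k=3
        )
        assert fwd == rev

    def test_k_exceeding_channels_rejected(self):
        sbc = self._series(["a"], np.zeros((1, 10)))
        with pytest.raises(ValueError, match="k exceeds"):
            select_channels(sbc, np.zeros(10, int), k=2)


class TestFeatureMatrix:
    def test_lag_samples_at_500hz(self):
        s = FeatureSeries("mrcp", "C2", np.arange(2000.0), 500.0)
        fm = build_feature_matrix([s], lag_ms=250.0)
        # 250 ms at 500 Hz = 125 samples: first row at t = 250 samples
        assert fm.row_index[0] == 250
        np.testing.assert_allclose(fm.rows[0], [250.0, 125.0, 0.0])

    def test_single_channel_ramp_unit_lag(self):
        s = FeatureSeries("mrcp", "C2", np.arange(10.0), 1000.0)
        fm = build_feature_matrix([s], lag_ms=1.0)
        np.testing.assert_allclose(fm.rows[0], [2.0, 1.0, 0.0])

    def test_two_channels_three_lags_is_six_wide(self, small_session):
        from eegintent.preprocessing import common_average_reference

        car = common_average_reference(small_session.eeg)
        series = [s for s in mrcp_amplitude(car) if s.channel in ("FC2", "C2")]
        fm = build_feature_matrix(series)
        assert fm.rows.shape[1] == 6

    def test_columns_are_exact_shifted_copies(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 700)
        s = FeatureSeries("rms", "Pz", np.abs(vals), 500.0)
        fm = build_feature_matrix([s], lag_ms=50.0)
        lag = 25
        for j in range(3):
            np.testing.assert_array_equal(
                fm.rows[:, j], s.values[fm.row_index - j * lag]
            )

    def test_insufficient_history_rejected(self):
        s = FeatureSeries("mrcp", "C2", np.arange(100.0), 500.0)
        with pytest.raises(ValueError, match="insufficient history"):
            build_feature_matrix([s], lag_ms=250.0)
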