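"""sEMG preprocessing and sliding-window feature extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emg2lip import signal_features as sf


def _recording(samples, fs=1000.0, **kw):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = tuple(sf.MUSCLES[: samples.shape[0]])
    return sf.EMGRecording(samples=samples, fs=fs, channel_labels=labels, **kw)


class TestBandpass:
    def test_below_passband_attenuated(self):
        fs, t = 2048.0, np.arange(4096) / 2048.0
        rec = _recording(np.sin(2 * np.pi * 5 * t), fs=fs)
        out = sf.bandpass_filter(rec)
        power_ratio = np.mean(out.samples**2) / np.mean(rec.samples**2)
        assert 10 * np.log10(power_ratio) < -20

    def test_mid_passband_preserved(self):
        fs, t = 2048.0, np.arange(8192) / 2048.0
        rec = _recording(np.sin(2 * np.pi * 100 * t), fs=fs)
        out = sf.bandpass_filter(rec)
        mid = out.samples[0, 2000:-2000]
        assert abs(mid.max() - 1.0) < 0.05

    def test_zero_in_zero_out(self):
        out = sf.bandpass_filter(_recording(np.zeros(2048), fs=2048.0))
        assert np.allclose(out.samples, 0.0)

    def test_invalid_band_rejected(self):
        rec = _recording(np.zeros(256), fs=500.0)
        with pytest.raises(sf.InvalidBandError):
            sf.bandpass_filter(rec, high=400.0)  # above Nyquist of 250


class TestBipolarDerivation:
    def test_common_mode_rejected(self):
        sig = np.full((16, 50), 3.7)
        rec = sf.EMGRecording(sig, fs=2048.0,
                              channel_labels=tuple(f"c{i}" for i in range(16)))
        out = sf.derive_bipolar(rec)
        assert out.n_channels == 8
        assert out.configuration == "bipolar"
        assert np.allclose(out.samples, 0.0)

    def test_pair_against_zero_passes_signal(self):
        s = np.sin(np.arange(100) / 7.0)
        sig = np.vstack([np.zeros(100), s] + [np.zeros(100)] * 14)
        rec = sf.EMGRecording(sig, fs=2048.0,
                              channel_labels=tuple(f"c{i}" for i in range(16)))
        out = sf.derive_bipolar(rec, pairing=[(0, 1)] + [(0, 0)] * 7)
        assert np.allclose(out.samples[0], s)

    def test_wrong_channel_count_rejected(self):
        rec = _recording(np.zeros((3, 10)), fs=100.0)
        with pytest.raises(sf.ConfigurationError):
            sf.derive_bipolar(rec)


class TestWindowSamples:
    @pytest.mark.parametrize(
        "window_ms,expected",
        [(50, 103), (100, 205), (150, 307), (200, 409), (250, 513), (300, 615)],
    )
    def test_grid_windows_at_2048(self, window_ms, expected):
        N = sf.window_samples(window_ms, 2048.0)
        assert N == expected and N % 2 == 1


class TestExtractFeature:
    @pytest.mark.parametrize(
        "feature,signal,s_lim,expected",
        [
            ("MAV", [1.0, -1.0, 2.0], None, 4.0 / 3.0),
            ("RMS", [-2.5, -2.5, -2.5], None, 2.5),
            ("WL", [4.0, 4.0, 4.0], None, 0.0),
            # hand enumeration: diffs 15, 10, 20, 0 -> three reach the
            # threshold 10 (trailing repeat keeps the window length odd)
            ("WAMP", [0.0, 15.0, 5.0, 25.0, 25.0], 10.0, 3.0),
        ],
    )
    def test_single_window_values(self, feature, signal, s_lim, expected):
        n = len(signal)
        rec = _recording(signal, fs=1000.0)
        out = sf.extract_feature(rec, feature, window_ms=n, s_lim=s_lim)
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(expected)

    @given(
        n=st.integers(min_value=700, max_value=1200),
        window_ms=st.sampled_from(sf.WINDOW_GRID_MS),
    )
    def test_output_length_law(self, n, window_ms):
        """A record of n samples and a window of p samples yields a series
        of n - p + 1 samples, for every grid window length."""
        rec = _recording(np.sin(np.arange(n)), fs=2048.0)
        out = sf.extract_feature(rec, "MAV", window_ms)
        assert out.n_samples == n - out.window_samples + 1

    def test_mav_bounded_by_rms(self, rng):
        """Power-mean inequality within every window."""
        rec = _recording(rng.normal(size=(8, 500)), fs=1000.0)
        mav = sf.extract_feature(rec, "MAV", 50)
        rms = sf.extract_feature(rec, "RMS", 50)
        assert np.all(mav.values <= rms.values + 1e-12)

    def test_wamp_monotone_in_threshold(self, rng):
        rec = _recording(rng.normal(scale=10, size=(4, 400)), fs=1000.0)
        counts = [
            sf.extract_feature(rec, "WAMP", 60, s_lim=s).values
            for s in (2.0, 5.0, 10.0, 20.0)
        ]
        for lo, hi in zip(counts[1:], counts[:-1]):
            assert np.all(lo <= hi)

    def test_wamp_counts_are_bounded_integers(self, rng):
        rec = _recording(rng.normal(scale=10, size=(2, 300)), fs=1000.0)
        out = sf.extract_feature(rec, "WAMP", 51, s_lim=5.0)
        assert np.all(out.values == np.rint(out.values))
        assert np.all((0 <= out.values) & (out.values <= out.window_samples - 1))

    @pytest.mark.parametrize("feature,s_lim", [("MAV", None), ("RMS", None),
                                               ("WL", None), ("WAMP", 8.0)])
    def test_time_reversal_invariance(self, rng, feature, s_lim):
        """All four features are invariant to reversing the record."""
        x = rng.normal(scale=10, size=(3, 257))
        fwd = sf.extract_feature(_recording(x, fs=1000.0), feature, 57, s_lim=s_lim)
        rev = sf.extract_feature(_recording(x[:, ::-1], fs=1000.0), feature, 57,
                                 s_lim=s_lim)
        assert np.allclose(fwd.values, rev.values[:, ::-1])

    def test_wamp_without_threshold_rejected(self):
        with pytest.raises(ValueError, match="s_lim"):
            sf.extract_feature(_recording(np.zeros(100)), "WAMP", 10)

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(sf.WindowError):
            sf.extract_feature(_recording(np.zeros(50)), "MAV", 100)

    def test_averaged_feature_variance_shrinks_with_length(self, rng):
        """For i.i.d. input the variance of the time-averaged feature
        scales like 1/length (checked at 3x the Monte-Carlo SE)."""
        n_rep, n_short = 300, 400
        def avg_mav(n):
            vals = np.empty(n_rep)
            for i in range(n_rep):
                rec = _recording(rng.normal(size=n), fs=1000.0)
                vals[i] = sf.extract_feature(rec, "MAV", 21).values.mean()
            return vals
        v_short = avg_mav(n_short).var()
        v_long = avg_mav(4 * n_short).var()
        ratio = v_short / v_long
        se = ratio * np.sqrt(4.0 / n_rep)
        assert abs(ratio - 4.0) < 3 * se + 1.0


class TestTruncation:
    def _series(self, length):
        return sf.FeatureSeries(
            values=np.arange(8 * length, dtype=float).reshape(8, length),
            feature_type="MAV", window_ms=300, window_samples=615,
        )

    def test_truncates_to_default_target(self):
        out = sf.truncate_series(self._series(7000))
        assert out.n_samples == sf.TARGET_FEATURE_SAMPLES
        assert np.allclose(out.values, self._series(7000).values[:, :6145])

    def test_exact_length_unchanged(self):
        s = self._series(sf.TARGET_FEATURE_SAMPLES)
        assert sf.truncate_series(s) is s

    def test_short_series_rejected_with_required_length(self):
        with pytest.raises(sf.TruncationError, match="6145"):
            sf.truncate_series(self._series(6000))


class TestAveragingAndAugmentation:
    def test_constant_series_average(self):
        values = np.tile(np.arange(8.0)[:, None], (1, 11))
        s = sf.FeatureSeries(values=values, feature_type="RMS",
                             window_ms=50, window_samples=103)
        fv = sf.average_features(s)
        assert np.allclose(fv.gbar, np.arange(8.0))

    def test_average_is_permutation_invariant(self, rng):
        values = rng.normal(size=(8, 20))
        perm = rng.permutation(20)
        s1 = sf.FeatureSeries(values=values, feature_type="MAV",
                              window_ms=50, window_samples=103)
        s2 = sf.FeatureSeries(values=values[:, perm], feature_type="MAV",
                              window_ms=50, window_samples=103)
        assert np.allclose(sf.average_features(s1).gbar,
                           sf.average_features(s2).gbar)

    def test_quadratic_terms_small_analogue(self):
        a, b = 2.0, 3.0
        assert np.allclose(sf.quadratic_terms([a, b]), [a * a, a * b, b * b])

    def test_augmentation_layout(self, rng):
        g = rng.normal(size=8)
        aug = sf.augment_quadratic(g)
        assert aug.shape == (44,)
        assert np.allclose(aug[:8], g)
        assert np.allclose(aug[8:], sf.quadratic_terms(g))

    def test_zero_vector_maps_to_zero(self):
        assert np.allclose(sf.augment_quadratic(np.zeros(8)), 0.0)

    def test_non_finite_rejected(self):
        g = np.zeros(8)
        g[3] = np.nan
        with pytest.raises(ValueError):
            sf.augment_quadratic(g)
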