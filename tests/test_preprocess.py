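"""Filtering, z-scoring and sliding-window segmentation contracts."""

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from emgfuse.preprocess import (
    ChannelStats,
    FilterSpec,
    WindowSpec,
    apply_normalizer,
    bandpass_filter,
    build_datasets,
    fit_normalizer,
    segment_windows,
    window_count,
)


def _sine(freq, fs=2000.0, seconds=4.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)[:, None]


def _gain_at(freq, spec=FilterSpec(), fs=2000.0):
    """Independent oracle: the designed filter's frequency-response magnitude."""
    sos = butter(spec.order, spec.band_hz, btype="bandpass", fs=fs, output="sos")
    _, h = sosfreqz(sos, worN=[freq], fs=fs)
    # forward-backward application squares the magnitude response
    return np.abs(h[0]) ** 2


class TestBandpass:
    def test_passband_tone_preserved(self):
        y = bandpass_filter(_sine(100.0), FilterSpec(), 2000.0)
        amp = np.sqrt(2) * np.std(y[2000:6000])
        assert abs(amp - 1.0) < 0.05
        assert abs(amp - _gain_at(100.0)) < 0.02

    def test_stopband_tone_suppressed(self):
        y = bandpass_filter(_sine(1.0), FilterSpec(), 2000.0)
        amp = np.sqrt(2) * np.std(y[2000:6000])
        assert amp < 0.1
        assert _gain_at(1.0) < 0.1

    def test_linearity(self, rng):
        a, b = rng.normal(size=(900, 3)), rng.normal(size=(900, 3))
        lhs = bandpass_filter(a + b)
        rhs = bandpass_filter(a) + bandpass_filter(b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_band_edge_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros((1000, 2)), FilterSpec(), fs=500.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass_filter(np.zeros((10, 2)), FilterSpec(), fs=2000.0)


class TestNormalizer:
    def test_two_point_channel(self):
        stats = fit_normalizer(np.array([[1.0], [3.0]]))
        assert stats.mean[0] == 2.0
        assert stats.std[0] == 1.0  # population convention

    def test_constant_channel_named_in_error(self):
        x = np.random.default_rng(0).normal(size=(100, 3))
        x[:, 1] = 5.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_normalizer(x)

    def test_matches_per_channel_loop_oracle(self, rng):
        x = rng.normal(2.0, 3.0, size=(1000, 12))
        stats = fit_normalizer(x)
        for c in range(12):
            col = x[:, c]
            mu = sum(col) / len(col)
            sd = (sum((v - mu) ** 2 for v in col) / len(col)) ** 0.5
            assert abs(stats.mean[c] - mu) < 1e-12
            assert abs(stats.std[c] - sd) < 1e-10

    def test_fit_then_apply_standardizes(self, rng):
        x = rng.normal(5.0, 7.0, size=(5000, 12))
        y = apply_normalizer(x, fit_normalizer(x))
        assert np.abs(y.mean(axis=0)).max() < 1e-8
        assert np.abs(y.std(axis=0) - 1).max() < 1e-6

    def test_already_standard_is_identity(self, rng):
        x = rng.normal(size=(4000, 4))
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        y = apply_normalizer(x, fit_normalizer(x))
        np.testing.assert_allclose(y, x, atol=1e-9)

    def test_constant_at_mean_maps_to_zero(self):
        stats = ChannelStats(mean=np.array([2.0, -1.0]), std=np.array([3.0, 0.5]))
        x = np.tile(stats.mean, (10, 1))
        np.testing.assert_array_equal(apply_normalizer(x, stats), 0.0)

    def test_inversion_recovers_input(self, rng):
        x = rng.normal(3.0, 2.0, size=(500, 6))
        stats = fit_normalizer(x)
        y = apply_normalizer(x, stats)
        np.testing.assert_allclose(y * stats.std + stats.mean, x, atol=1e-9)

    def test_channel_mismatch_rejected(self):
        stats = ChannelStats(mean=np.zeros(3), std=np.ones(3))
        with pytest.raises(ValueError, match="channels"):
            apply_normalizer(np.zeros((10, 4)), stats)


class TestWindowSpec:
    @pytest.mark.parametrize(
        "T,expected_L", [(100.0, 200), (150.0, 300), (200.0, 400), (250.0, 500)]
    )
    def test_length_arithmetic_at_2khz(self, T, expected_L):
        spec = WindowSpec(T_ms=T, S_ms=50.0, sampling_rate_hz=2000.0)
        assert spec.L == expected_L
        assert spec.Ld == 100

    def test_adapts_to_sampling_rate(self):
        spec = WindowSpec(T_ms=200.0, S_ms=50.0, sampling_rate_hz=500.0)
        assert (spec.L, spec.Ld) == (100, 25)

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            WindowSpec(T_ms=0.3, S_ms=0.1, sampling_rate_hz=2000.0)


class TestSegmentation:
    def test_single_label_window_count(self):
        spec = WindowSpec(200.0, 50.0, 2000.0)
        x = np.random.default_rng(0).normal(size=(10000, 2))
        ws = segment_windows(x, np.full(10000, 3), spec)
        assert ws.n_windows == (10000 - 400) // 100 + 1 == 97
        assert (ws.labels == 3).all()
        assert ws.x.shape == (97, 2, 400)

    def test_short_signal_yields_empty_set_with_warning(self):
        spec = WindowSpec(200.0, 50.0, 2000.0)
        with pytest.warns(UserWarning, match="shorter than one window"):
            ws = segment_windows(np.zeros((399, 2)), np.zeros(399, dtype=int), spec)
        assert ws.n_windows == 0

    def test_count_matches_offset_loop_oracle(self):
        spec = WindowSpec(200.0, 50.0, 2000.0)
        rng = np.random.default_rng(5)
        for n in rng.integers(400, 20000, size=20):
            x = np.zeros((n, 1))
            ws = segment_windows(x, np.ones(n, dtype=int), spec)
            expected = sum(1 for s in range(0, n, 100) if s + 400 <= n)
            assert ws.n_windows == expected == window_count(n, 400, 100)

    def test_windows_are_contiguous_slices(self, rng):
        spec = WindowSpec(200.0, 50.0, 500.0)  # L=100, Ld=25
        x = rng.normal(size=(730, 3))
        ws = segment_windows(x, np.ones(730, dtype=int), spec)
        for i in range(ws.n_windows):
            start = i * spec.Ld
            np.testing.assert_array_equal(ws.x[i], x[start : start + spec.L].T)

    def test_majority_label_and_rest_mixing(self):
        spec = WindowSpec(T_ms=8.0, S_ms=8.0, sampling_rate_hz=1000.0)  # L=Ld=8
        labels = np.array([1] * 8 + [1] * 5 + [2] * 3 + [0] * 4 + [2] * 4)
        x = np.zeros((len(labels), 1))
        ws = segment_windows(x, labels, spec)
        # window 2 mixes rest with movement and is dropped
        np.testing.assert_array_equal(ws.labels, [1, 1])

    def test_strict_policy_drops_any_mixed_window(self):
        spec = WindowSpec(T_ms=8.0, S_ms=8.0, sampling_rate_hz=1000.0)
        labels = np.array([1] * 8 + [1] * 5 + [2] * 3)
        ws = segment_windows(np.zeros((16, 1)), labels, spec, labeling="strict")
        np.testing.assert_array_equal(ws.labels, [1])

    def test_majority_tie_breaks_toward_lower_label(self):
        spec = WindowSpec(T_ms=8.0, S_ms=8.0, sampling_rate_hz=1000.0)
        labels = np.array([4] * 4 + [2] * 4)
        ws = segment_windows(np.zeros((8, 1)), labels, spec)
        assert ws.labels[0] == 2


class TestBuildDatasets:
    def test_streams_paired_and_aligned(self, desk_session):
        ds = build_datasets(desk_session)
        for part in (ds.train, ds.test):
            assert part.emg.n_windows == part.acc.n_windows
            np.testing.assert_array_equal(part.emg.labels, part.acc.labels)
        assert ds.train.n_windows > ds.test.n_windows > 0
        # repetition split => train has 4 of 6 repetitions of each class
        assert set(np.unique(ds.train.labels)) == set(np.unique(ds.test.labels))

    def test_stats_fitted_on_training_samples_only(self, desk_session):
        from emgfuse.ninapro_io import split_by_repetition
        from emgfuse.preprocess import default_filter_for_fs

        ds = build_datasets(desk_session)
        fs = desk_session.sampling_rate_hz
        emg_f = bandpass_filter(desk_session.emg, default_filter_for_fs(fs), fs)
        train_mask, _ = split_by_repetition(desk_session)
        expected = fit_normalizer(emg_f[train_mask])
        np.testing.assert_allclose(ds.emg_stats.mean, expected.mean, atol=1e-12)
        np.testing.assert_allclose(ds.emg_stats.std, expected.std, atol=1e-12)
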