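"""Stockwell/modified-Stockwell transform and feature-extraction tests."""

import numpy as np
import pytest

from mipso import (
    MSTConfig,
    TrialTensor,
    downsample,
    extract_features,
    modified_stockwell_transform,
    mst_sigma,
    stockwell_transform,
)
from oracles import direct_stockwell, fourier_coefficient


def _sine_trials(f0, fs, n_samples, n_trials=4, n_channels=2):
    t = np.arange(n_samples) / fs
    data = np.tile(np.sin(2 * np.pi * f0 * t), (n_trials, n_channels, 1))
    labels = np.resize([1, -1], n_trials)
    return TrialTensor(data, labels, fs)


class TestDownsample:
    def test_decimation_1000_to_100(self):
        trials = _sine_trials(5.0, 1000.0, 3000)
        out = downsample(trials, 100.0)
        assert out.n_samples == 300
        assert out.fs == 100.0
        assert np.array_equal(out.labels, trials.labels)

    def test_identity_when_rates_match(self):
        trials = _sine_trials(5.0, 100.0, 300)
        out = downsample(trials, 100.0)
        assert np.array_equal(out.data, trials.data)

    def test_tone_survives_decimation(self):
        """A 5 Hz tone keeps its dominant DFT bin through 1000 -> 100 Hz."""
        trials = _sine_trials(5.0, 1000.0, 3000)
        out = downsample(trials, 100.0)
        spec_before = np.abs(np.fft.rfft(trials.data[0, 0]))
        spec_after = np.abs(np.fft.rfft(out.data[0, 0]))
        f_before = np.fft.rfftfreq(3000, 1 / 1000.0)[np.argmax(spec_before)]
        f_after = np.fft.rfftfreq(300, 1 / 100.0)[np.argmax(spec_after)]
        assert f_before == f_after == 5.0

    def test_non_integer_ratio_rejected(self):
        trials = _sine_trials(5.0, 250.0, 750)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(trials, 100.0)


class TestStockwell:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs, n, f0 = 64.0, 128, 8.0
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * f0 * t)
        tf = stockwell_transform(x, fs, np.arange(1.0, 21.0))
        assert tf.freqs[np.argmax(np.abs(tf.values).mean(axis=1))] == f0

    def test_time_marginal_recovers_fourier_spectrum(self):
        """sum_tau S(tau, f) dtau ~ X(f) wherever |X(f)| is appreciable."""
        fs, n = 64.0, 128
        rng = np.random.default_rng(3)
        t = np.arange(n) / fs
        x = (
            np.cos(2 * np.pi * 7 * t)
            + 0.6 * np.sin(2 * np.pi * 12.5 * t)
            + 0.1 * rng.standard_normal(n)
        )
        freqs = np.arange(2.0, 21.0)
        for tf in (
            stockwell_transform(x, fs, freqs),
            modified_stockwell_transform(x, fs, MSTConfig(f_min=2, f_max=20)),
        ):
            marginal = tf.values.sum(axis=1) / fs
            X = np.array([fourier_coefficient(x, fs, f) for f in tf.freqs])
            appreciable = np.abs(X) > 0.05 * np.abs(X).max()
            rel = np.abs(marginal - X)[appreciable] / np.abs(X)[appreciable]
            assert rel.max() < 1e-3

    def test_zero_signal_gives_zero_map(self):
        tf = stockwell_transform(np.zeros(64), 32.0, np.arange(1.0, 11.0))
        assert np.all(tf.values == 0)

    def test_matches_direct_discretisation(self):
        """Fast FFT path equals the literal double-loop oracle on 64 samples."""
        fs, n = 32.0, 64
        rng = np.random.default_rng(11)
        x = rng.standard_normal(n)
        freqs = np.array([1.0, 3.0, 7.0, 12.0])
        ref = direct_stockwell(x, fs, freqs, p=1.0, q=1.0)
        tf = stockwell_transform(x, fs, freqs)
        scale = np.abs(ref).max()
        assert np.max(np.abs(tf.values - ref)) / scale < 1e-6

    def test_mst_matches_direct_discretisation(self):
        fs, n = 32.0, 64
        rng = np.random.default_rng(12)
        x = rng.standard_normal(n)
        cfg = MSTConfig(p=0.85, q=1.0, f_min=1, f_max=12, f_step=3)
        ref = direct_stockwell(x, fs, cfg.freqs, p=0.85, q=1.0)
        tf = modified_stockwell_transform(x, fs, cfg)
        assert np.max(np.abs(tf.values - ref)) / np.abs(ref).max() < 1e-6

    def test_rejects_nonpositive_frequencies(self):
        with pytest.raises(ValueError, match="positive"):
            stockwell_transform(np.ones(32), 32.0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="positive"):
            stockwell_transform(np.ones(32), 32.0, np.array([-2.0]))


class TestModifiedStockwell:
    def test_reduces_to_standard_st_at_p1_q1(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        fs = 128.0
        cfg = MSTConfig(p=1.0, q=1.0, f_min=1, f_max=35)
        st = stockwell_transform(x, fs, cfg.freqs)
        mst = modified_stockwell_transform(x, fs, cfg)
        assert np.max(np.abs(mst.values - st.values)) < 1e-8

    def test_window_sigma_arithmetic(self):
        assert mst_sigma(10.0, p=0.85, q=1.0) == pytest.approx(0.085)
        with pytest.raises(ValueError):
            mst_sigma(10.0, p=-1.0)

    def test_smaller_p_narrows_the_time_window(self):
        """An impulse's |S| time profile is the analysis window itself, so
        its spread at fixed f scales with p (0.085 s vs 0.1 s at 10 Hz)."""
        fs, n = 128.0, 512
        t = np.arange(n) / fs
        x = np.zeros(n)
        x[n // 2] = 1.0

        def impulse_width(p):
            cfg = MSTConfig(p=p, q=1.0, f_min=10, f_max=10)
            row = np.abs(modified_stockwell_transform(x, fs, cfg).values[0])
            w = row / row.sum()
            mu = np.sum(t * w)
            return np.sqrt(np.sum((t - mu) ** 2 * w))

        w85, w100 = impulse_width(0.85), impulse_width(1.0)
        assert w85 < w100
        assert w85 / w100 == pytest.approx(0.85, rel=0.02)

    def test_rejects_bad_scale_factors(self):
        with pytest.raises(ValueError):
            MSTConfig(p=0.0)
        with pytest.raises(ValueError):
            MSTConfig(q=-1.0)


class TestExtractFeatures:
    def test_channel_major_column_count(self):
        trials = _sine_trials(10.0, 100.0, 100, n_trials=2, n_channels=3)
        fm = extract_features(trials, MSTConfig())
        assert fm.n_features == 3 * 35
        assert fm.columns[:3] == [(0, 1.0), (0, 2.0), (0, 3.0)]
        assert fm.columns[35] == (1, 1.0)

    def test_pure_tone_feature_dominates_its_channel(self):
        """10 Hz sinusoid: the (ch, 10 Hz) feature beats every other frequency,
        matching the channel's periodogram peak."""
        fs, n = 100.0, 200
        t = np.arange(n) / fs
        data = np.zeros((1, 1, n))
        data[0, 0] = np.sin(2 * np.pi * 10 * t)
        fm = extract_features(TrialTensor(data, [1], fs), MSTConfig())
        row = fm.values[0]
        assert fm.columns[np.argmax(row)] == (0, 10.0)
        spec = np.abs(np.fft.rfft(data[0, 0])) ** 2
        assert np.fft.rfftfreq(n, 1 / fs)[np.argmax(spec)] == 10.0

    def test_zero_trial_gives_zero_row(self):
        data = np.zeros((3, 2, 100))
        data[1, :, :] = np.random.default_rng(0).standard_normal((2, 100))
        fm = extract_features(TrialTensor(data, [1, -1, 1], 100.0), MSTConfig())
        assert np.all(fm.values[0] == 0)
        assert np.all(fm.values[2] == 0)
        assert np.all(fm.values[1] > 0)

    def test_nonnegative_and_column_identity(self, tiny_fixture):
        fm = extract_features(tiny_fixture.train, MSTConfig())
        assert np.all(fm.values >= 0)
        assert fm.n_features == tiny_fixture.train.n_channels * 35

    def test_too_short_trials_rejected(self):
        trials = _sine_trials(10.0, 100.0, 50)
        with pytest.raises(ValueError, match="too short"):
            extract_features(trials, MSTConfig(f_min=1.0))
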