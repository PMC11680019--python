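"""Filtering, differentiation, DC extraction and beat segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsefeat import (ConfigurationError, FilterSpec, SimConfig,
                       WaveformRecord, bandpass_filter, dc_component, derive,
                       differentiate_smooth, iter_beats, segment_beats,
                       simulate_record)


def _sine_record(freq, fs, duration, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return WaveformRecord({"green": amp * np.sin(2 * np.pi * freq * t)},
                          sampling_rate=fs), t


def _mid_amplitude(x):
    third = x.size // 3
    return np.max(np.abs(x[third:2 * third]))


class TestBandpass:
    def test_passband_gain_at_5hz(self):
        rec, _ = _sine_record(5.0, 1000.0, 10.0)
        out = bandpass_filter(rec).channels["green"]
        assert 0.95 <= _mid_amplitude(out) <= 1.0

    def test_dc_fully_rejected(self):
        rec = WaveformRecord({"green": np.full(5000, 1234.0)},
                             sampling_rate=1000.0)
        out = bandpass_filter(rec).channels["green"]
        assert np.max(np.abs(out)) < 1e-6 * 1234.0

    def test_deep_stopband_below_lowcut(self):
        rec, _ = _sine_record(0.05, 250.0, 80.0)
        out = bandpass_filter(rec).channels["green"]
        assert _mid_amplitude(out) < 0.1

    def test_rejects_sampling_rate_below_highcut(self):
        rec = WaveformRecord({"green": np.zeros(200)}, sampling_rate=30.0)
        with pytest.raises(ConfigurationError, match="high_cut"):
            bandpass_filter(rec, FilterSpec())

    def test_channel_symmetry_preserves_shift(self):
        # two channels that are exact 7-sample shifted copies stay
        # shifted by 7 samples through the whole derived chain
        fs = 1000.0
        t = np.arange(int(8 * fs)) / fs
        base = np.zeros(t.size)
        for c in np.arange(0.5, 7.5, 1.0):
            base += np.exp(-0.5 * ((t - c) / 0.04) ** 2)
        shift = 7
        rec = WaveformRecord(
            {"green": np.roll(base, shift), "nir": base}, sampling_rate=fs)
        filt = bandpass_filter(rec)
        for ch_a, ch_b in [(filt.channels["green"], filt.channels["nir"])]:
            da, db = derive(ch_a, fs), derive(ch_b, fs)
            for xa, xb in ((da.ppg, db.ppg), (da.vpg, db.vpg),
                           (da.apg, db.apg)):
                xc = np.correlate(xa[1000:-1000], xb[1000:-1000], "full")
                lag = int(np.argmax(xc)) - (xa.size - 2001)
                assert abs(lag - shift) < 1


class TestDifferentiateSmooth:
    def test_ramp_derivative_is_constant(self):
        fs = 500.0
        x = 3.0 * np.arange(2000) / fs
        d = differentiate_smooth(x, fs, window=0.05)
        assert np.allclose(d[100:-100], 3.0, atol=1e-9)

    def test_sine_matches_closed_form(self):
        fs = 1000.0
        f = 2.0
        t = np.arange(int(5 * fs)) / fs
        d = differentiate_smooth(np.sin(2 * np.pi * f * t), fs,
                                 window=1.0 / fs)  # one-sample window
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        err = np.max(np.abs(d[50:-50] - expected[50:-50]))
        assert err < 0.01 * 2 * np.pi * f

    def test_constant_gives_zeros(self):
        d = differentiate_smooth(np.full(1000, 7.7), 100.0)
        assert np.allclose(d, 0.0, atol=1e-10)

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(ConfigurationError):
            differentiate_smooth(np.zeros(20), 100.0, window=1.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5),
           seed=st.integers(0, 2 ** 16))
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=400), r.normal(size=400)
        fs = 100.0
        lhs = differentiate_smooth(a * x + b * y, fs)
        rhs = (a * differentiate_smooth(x, fs)
               + b * differentiate_smooth(y, fs))
        assert np.allclose(lhs, rhs, atol=1e-8 * max(1, abs(a) + abs(b)))


class TestDcComponent:
    def test_constant_passthrough(self):
        out = dc_component(np.full(3000, 1000.0), 500.0, window=2.0)
        assert np.allclose(out, 1000.0)

    def test_pulse_train_attenuated_to_one_percent(self):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        pulse = 50.0 * np.sin(2 * np.pi * 1.3 * t)  # zero-mean, 1.3 Hz
        out = dc_component(1000.0 + pulse, fs, window=2.0)
        mid = out[int(3 * fs):-int(3 * fs)]
        assert np.max(np.abs(mid - 1000.0)) < 10.0  # +/-1% of 1000

    def test_step_settles_within_one_window(self):
        fs = 200.0
        x = np.where(np.arange(int(30 * fs)) / fs < 15.0, 1000.0, 1200.0)
        out = dc_component(x, fs, window=2.0)
        k = int(16.01 * fs)  # one window length after the press
        assert abs(out[k] - 1200.0) < 1.0
        assert abs(out[int(14 * fs) - int(fs)] - 1000.0) < 1.0

    def test_additive_constant(self, rng):
        x = rng.normal(size=4000)
        fs = 400.0
        assert np.allclose(dc_component(x + 11.5, fs),
                           dc_component(x, fs) + 11.5)


class TestSegmentBeats:
    def test_fixed_rate_beat_count_and_spacing(self):
        cfg = SimConfig(duration=10.0, heart_rate=60.0, hrv_cv=0.0,
                        noise_sd=0.0, target_inv_fwhm=8.0, seed=0)
        record, _ = simulate_record(cfg)
        fs = record.sampling_rate
        d = derive(bandpass_filter(record).channels["green"], fs)
        index = segment_beats(d, fs)
        assert index.beat_count in (9, 10)
        spacing = np.diff([i0 for i0, _ in iter_beats(index)]) / fs
        assert np.allclose(spacing, 1.0, atol=0.01)

    def test_constant_signal_flagged_empty(self):
        fs = 500.0
        d = derive(np.full(int(5 * fs), 3.3), fs)
        index = segment_beats(d, fs)
        assert index.beat_count == 0
        assert index.flagged

    def test_hrv_mean_spacing(self):
        cfg = SimConfig(duration=20.0, heart_rate=75.0, hrv_cv=0.05,
                        noise_sd=0.0, target_inv_fwhm=8.0, seed=5)
        record, _ = simulate_record(cfg)
        fs = record.sampling_rate
        d = derive(bandpass_filter(record).channels["green"], fs)
        index = segment_beats(d, fs)
        spacing = [(i1 - i0) / fs for i0, i1 in iter_beats(index)]
        assert abs(np.mean(spacing) - 0.8) < 0.02 * 0.8

    def test_simulated_count_matches_truth(self, sim_record, config):
        record, truth = sim_record
        fs = record.sampling_rate
        d = derive(bandpass_filter(record).channels["nir"], fs)
        index = segment_beats(d, fs)
        assert abs(index.beat_count - len(truth)) <= 1
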