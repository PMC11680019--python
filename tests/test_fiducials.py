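"""Beat landmarks, pulse-height S, FWHM, feature arithmetic, delays."""

import numpy as np
import pytest

from pulsefeat import (BeatFiducials, SimConfig, aggregate_record,
                       beat_features, channel_delay, corrected_height_S,
                       detect_apg_waves, fwhm_vpg, measure_record,
                       simulate_record)
from pulsefeat.fiducials import FiducialPoint


def _gauss(t, c, a, s):
    return a * np.exp(-0.5 * ((t - c) / s) ** 2)


class TestCorrectedHeight:
    fs = 1000.0

    def _tilted_beat(self):
        # minima (0 s, 10) and (1 s, 14); narrow bump peaking 38.8 above
        # the connecting line at t=0.3, i.e. raw maximum 50
        t = np.arange(0, 1.001, 1 / self.fs)
        line = 10.0 + 4.0 * t
        return line + _gauss(t, 0.3, 38.8, 0.03)

    def test_hand_computed_height(self):
        beat = self._tilted_beat()
        s, ok = corrected_height_S(beat, 0, beat.size - 1, self.fs)
        assert ok
        assert s == pytest.approx(38.8, abs=1e-6)
        # brute-force oracle: max over dense samples of ppg - line
        line = np.linspace(beat[0], beat[-1], beat.size)
        assert s == pytest.approx(np.max(beat - line), abs=1e-12)

    def test_flat_baseline(self):
        t = np.arange(0, 1.001, 1 / self.fs)
        beat = 10.0 + _gauss(t, 0.4, 50.0, 0.05)
        s, ok = corrected_height_S(beat, 0, beat.size - 1, self.fs)
        assert ok and s == pytest.approx(50.0, abs=1e-6)

    def test_offset_invariance(self):
        beat = self._tilted_beat()
        s1, _ = corrected_height_S(beat, 0, beat.size - 1, self.fs)
        s2, _ = corrected_height_S(beat + 123.4, 0, beat.size - 1, self.fs)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_monotone_beat_invalid(self):
        beat = np.linspace(0.0, 10.0, 500)
        _, ok = corrected_height_S(beat, 0, beat.size - 1, self.fs)
        assert not ok


class TestApgWaves:
    def test_separated_gaussians_recovered_within_2ms(self):
        fs = 1000.0
        t = np.arange(0, 0.45, 1 / fs)
        centers = [(0.05, 1.0), (0.12, -0.6), (0.20, 0.2),
                   (0.26, -0.3), (0.33, 0.15)]
        apg = sum(_gauss(t, c, a, 0.015) for c, a in centers)
        # plausible PPG context: maximum well after the a-wave
        ppg = _gauss(t, 0.25, 1.0, 0.08)
        vpg = np.gradient(ppg, 1 / fs)
        fid = detect_apg_waves(apg, vpg, ppg, 0, t.size - 1, fs)
        assert fid.valid
        got = [fid.apg_a, fid.apg_b, fid.apg_c, fid.apg_d, fid.apg_e]
        for pt, (c, a) in zip(got, centers):
            assert pt is not None
            assert pt.time == pytest.approx(c, abs=0.002)
            assert np.sign(pt.amplitude) == np.sign(a)

    def test_a_wave_precedes_ppg_max(self, sim_record, config):
        from pulsefeat import bandpass_filter, derive, extract_beats, segment_beats
        record, _ = sim_record
        fs = record.sampling_rate
        d = derive(bandpass_filter(record).channels["green"], fs)
        fids, _ = extract_beats(d, segment_beats(d, fs))
        assert fids
        for fid in fids:
            if fid.valid:
                assert fid.apg_a.time < fid.ppg_max.time

    def test_pure_noise_flagged_not_raised(self, rng):
        fs = 500.0
        n = 400
        noise = rng.normal(size=n)
        fid = detect_apg_waves(noise, noise, noise, 0, n - 1, fs)
        assert isinstance(fid, BeatFiducials)  # contract: no exception


class TestFwhm:
    def test_triangle_closed_form(self):
        fs = 10000.0
        t = np.arange(0, 0.2001, 1 / fs)
        tri = np.where(t <= 0.1, t / 0.1, (0.2 - t) / 0.1)
        w = fwhm_vpg(tri, 0, tri.size - 1, fs)
        assert w == pytest.approx(0.1, abs=1e-3)
        assert 1.0 / w == pytest.approx(10.0, rel=0.01)

    def test_gaussian_closed_form(self):
        fs = 1000.0
        t = np.arange(0, 0.6, 1 / fs)
        sigma = 0.05
        g = _gauss(t, 0.3, 1.0, sigma)
        w = fwhm_vpg(g, 0, g.size - 1, fs)
        assert w == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma,
                                  abs=5e-4)

    def test_diabetes_mean_reciprocal_consistency(self):
        # a measured steepness of 5.6 1/s corresponds to a VPG width of
        # 1/5.6 ~ 0.1786 s; the two reported forms must stay consistent
        fs = 2000.0
        t = np.arange(0, 1.0, 1 / fs)
        sigma = (1.0 / 5.6) / (2 * np.sqrt(2 * np.log(2)))
        g = _gauss(t, 0.5, 1.0, sigma)
        w = fwhm_vpg(g, 0, g.size - 1, fs)
        assert w == pytest.approx(0.1786, abs=5e-4)
        assert 1.0 / w == pytest.approx(5.6, rel=0.005)

    def test_half_level_not_crossed_is_invalid(self):
        fs = 500.0
        x = np.linspace(0.6, 1.0, 300)  # rises into the boundary
        assert fwhm_vpg(x, 0, x.size - 1, fs) is None


class TestBeatFeatures:
    def _fid(self):
        fid = BeatFiducials()
        fid.apg_a = FiducialPoint(0.05, 1.0)
        fid.apg_b = FiducialPoint(0.12, -0.6)
        fid.apg_d = FiducialPoint(0.26, -0.3)
        return fid

    def test_hand_arithmetic(self):
        f = beat_features(self._fid(), S=38.8, fwhm=0.125)
        assert f.ab_time == pytest.approx(0.07, abs=1e-12)
        assert f.inv_ab_time == pytest.approx(14.2857, rel=1e-4)
        assert f.norm_ab == pytest.approx(1.6, abs=1e-12)
        assert f.norm_ad == pytest.approx(1.3, abs=1e-12)
        assert f.ab_over_ad == pytest.approx(1.230769, rel=1e-5)

    def test_a_over_s(self):
        fid = self._fid()
        fid.apg_a = FiducialPoint(0.05, 400.0)
        f = beat_features(fid, S=38.8, fwhm=None)
        assert f.a_over_S == pytest.approx(10.309, rel=1e-3)
        assert f.inv_S == pytest.approx(1 / 38.8)

    def test_apg_scaling_leaves_normalized_features(self):
        f1 = beat_features(self._fid(), S=10.0, fwhm=0.1)
        fid2 = self._fid()
        for name in ("apg_a", "apg_b", "apg_d"):
            p = getattr(fid2, name)
            setattr(fid2, name, FiducialPoint(p.time, 7.3 * p.amplitude))
        f2 = beat_features(fid2, S=10.0, fwhm=0.1)
        for name in ("norm_ab", "norm_ad", "ab_over_ad", "ab_time"):
            assert getattr(f1, name) == pytest.approx(getattr(f2, name))

    def test_missing_denominator_drops_only_that_feature(self):
        fid = self._fid()
        fid.apg_d = None
        f = beat_features(fid, S=None, fwhm=0.1)
        assert f.norm_ad is None and f.ab_over_ad is None
        assert f.a_over_S is None and f.inv_S is None
        assert f.norm_ab is not None and f.inv_fwhm_vpg is not None


def _fids_at(times):
    out = []
    for t in times:
        fid = BeatFiducials()
        fid.apg_a = FiducialPoint(t, 1.0)
        fid.apg_b = FiducialPoint(t + 0.05, -0.5)
        out.append(fid)
    return out


class TestChannelDelay:
    def test_constant_shift_recovered(self):
        nir = _fids_at(np.arange(10) * 0.9)
        green = _fids_at(np.arange(10) * 0.9 + 0.012)
        series = channel_delay(green, nir)
        assert np.allclose(series.delays, 0.012, atol=1e-3)
        assert series.summary == pytest.approx(0.012, abs=1e-3)

    def test_identical_channels_zero(self):
        nir = _fids_at(np.arange(8) * 0.9)
        series = channel_delay(_fids_at(np.arange(8) * 0.9), nir)
        assert np.allclose(series.delays, 0.0)

    def test_unpaired_peaks_dropped_and_empty_flagged(self):
        nir = _fids_at(np.arange(8) * 0.9)
        green = _fids_at(np.arange(8) * 0.9 + 0.012)[:4]
        series = channel_delay(green, nir, pairing_window=0.3)
        assert len(series.delays) == 4
        empty = channel_delay([], nir)
        assert empty.flagged and empty.summary is None

    def test_simulated_mean_delay_recovery(self):
        cfg = SimConfig(duration=25.0, target_inv_fwhm=6.0,
                        channel_delay=0.028, delay_jitter_sd=0.004, seed=9)
        record, truth = simulate_record(cfg)
        res = measure_record(record)
        assert res.features["delay_green_nir"] == pytest.approx(
            0.028, rel=0.10)


class TestAggregateRecord:
    def test_median_of_beats(self):
        from pulsefeat import BeatFeatures
        feats = [BeatFeatures(inv_fwhm_vpg=v, S=1.0) for v in (7.0, 8.0, 9.0)]
        agg = aggregate_record(feats, None)
        assert agg["inv_fwhm_vpg"] == 8.0

    def test_single_beat_passthrough(self):
        from pulsefeat import BeatFeatures
        feats = [BeatFeatures(inv_fwhm_vpg=7.5, S=2.0, norm_ab=1.2)]
        agg = aggregate_record(feats, None)
        assert agg["inv_fwhm_vpg"] == 7.5
        assert agg["norm_ab"] == 1.2
        assert agg["n_beats"] == 1

    def test_noisy_beats_aggregate_close_to_truth(self, rng):
        from pulsefeat import BeatFeatures
        truth = 9.0
        feats = [BeatFeatures(inv_fwhm_vpg=truth * (1 + rng.normal(0, 0.05)),
                              S=1.0)
                 for _ in range(50)]
        agg = aggregate_record(feats, None)
        assert agg["inv_fwhm_vpg"] == pytest.approx(truth, rel=0.05)


class TestRecordInvariances:
    def test_amplitude_scaling(self, sim_record, config):
        record, _ = sim_record
        res1 = measure_record(record, config)
        k = 3.7
        scaled = record.with_channels(
            {ch: k * x for ch, x in record.channels.items()})
        res2 = measure_record(scaled, config)
        f1, f2 = res1.features, res2.features
        for name in ("fwhm_vpg", "inv_fwhm_vpg", "ab_time", "norm_ab",
                     "norm_ad", "ab_over_ad", "a_over_S",
                     "delay_green_nir"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-6), name
        assert f2["S"] == pytest.approx(k * f1["S"], rel=1e-9)
        assert f2["a"] == pytest.approx(k * f1["a"], rel=1e-9)

    def test_green_shift_moves_delay(self, sim_record, config):
        record, _ = sim_record
        res1 = measure_record(record, config)
        shift = 5  # samples = 5 ms at 1 kHz
        shifted = record.with_channels({
            "green": np.roll(record.channels["green"], shift),
            "nir": record.channels["nir"]})
        res2 = measure_record(shifted, config)
        moved = res2.features["delay_green_nir"] - res1.features[
            "delay_green_nir"]
        assert moved == pytest.approx(shift / record.sampling_rate,
                                      abs=0.001)

    def test_common_shift_changes_nothing(self, sim_record, config):
        record, _ = sim_record
        res1 = measure_record(record, config)
        shift = 40
        shifted = record.with_channels(
            {ch: np.roll(x, shift) for ch, x in record.channels.items()})
        res2 = measure_record(shifted, config)
        for name in ("inv_fwhm_vpg", "S", "delay_green_nir", "norm_ab"):
            assert res2.features[name] == pytest.approx(
                res1.features[name], rel=0.01), name
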