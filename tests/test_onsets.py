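"""Onset envelope, peak picking, and the onset/IOI feature formulas."""

import numpy as np
import pytest

from pataka import (
    OnsetSeries, Recording, SyllableTrainSpec, detect_onsets,
    detect_recording_onsets, onset_ioi_features, onset_strength_envelope,
    synthesize_ddk_recording,
)
from pataka.preprocess import preprocess_recording

from conftest import match_onsets


class TestEnvelope:
    def test_silence_gives_zero_envelope(self):
        rec = Recording(np.zeros(16000), 16000)
        _, env = onset_strength_envelope(rec)
        assert np.allclose(env, 0.0)

    def test_steady_tone_flat_after_attack(self):
        sr = 16000
        x = np.zeros(2 * sr)
        t = np.arange(int(1.5 * sr)) / sr
        x[sr // 2 :] = np.sin(2 * np.pi * 200 * t)  # tone switches on at 0.5 s
        times, env = onset_strength_envelope(Recording(x, sr))
        attack = np.max(env[np.abs(times - 0.5) < 0.05])
        after = np.max(env[times > 0.7])
        assert after < 0.05 * attack

    def test_single_burst_peak_near_burst_time(self):
        sr = 16000
        rng = np.random.default_rng(0)
        x = np.zeros(3 * sr)
        x[sr : sr + 160] = rng.standard_normal(160)  # 10-ms burst at t=1.0
        times, env = onset_strength_envelope(Recording(x, sr))
        # the flux peak leads the burst by the (compensated) window lead;
        # within one hop of the uncompensated peak position
        assert abs((times[np.argmax(env)] + 0.014) - 1.0) <= 0.025

    def test_too_short_recording_fails(self):
        with pytest.raises(ValueError):
            onset_strength_envelope(Recording(np.zeros(100), 16000))


class TestDetect:
    def test_seven_repetitions_recovered_within_10ms(self):
        spec = SyllableTrainSpec(duration=3.0, n_repetitions=7, ioi_mean=0.25,
                                 ioi_sd=0.01, snr_db=30, seed=7)
        rec, man = synthesize_ddk_recording(spec)
        ons = detect_recording_onsets(preprocess_recording(rec))
        assert len(ons) == 7
        assert np.all(np.abs(ons.times - man.onset_times) <= 0.010)

    def test_forty_repetitions_at_four_per_second(self):
        spec = SyllableTrainSpec(duration=10.5, n_repetitions=40, ioi_mean=0.25,
                                 ioi_sd=0.0, snr_db=30, seed=8)
        rec, man = synthesize_ddk_recording(spec)
        assert man.n_repetitions == 40
        ons = detect_recording_onsets(preprocess_recording(rec))
        assert len(ons) == 40

    def test_min_separation_suppresses_close_peaks(self):
        # two envelope peaks 30 ms apart with a 100-ms refractory period
        times = np.arange(0, 1.0, 0.01)
        env = np.zeros_like(times)
        env[50] = 1.0
        env[53] = 0.8
        ons = detect_onsets(times, env, min_separation=0.100)
        assert len(ons) == 1

    def test_empty_envelope_gives_empty_series(self):
        ons = detect_onsets(np.empty(0), np.empty(0))
        assert len(ons) == 0

    def test_time_shift_equivariance(self):
        # same seeded train placed 0.25 s later in the recording
        shift = 0.25
        base = dict(duration=4.0, n_repetitions=10, ioi_mean=0.25,
                    ioi_sd=0.005, snr_db=40, seed=9)
        rec_a, _ = synthesize_ddk_recording(SyllableTrainSpec(lead_silence=0.3, **base))
        rec_b, _ = synthesize_ddk_recording(SyllableTrainSpec(lead_silence=0.3 + shift, **base))
        a = detect_recording_onsets(preprocess_recording(rec_a))
        b = detect_recording_onsets(preprocess_recording(rec_b))
        assert len(a) == len(b)
        assert np.all(np.abs((b.times - a.times) - shift) <= 0.010 + 1e-9)

    def test_amplitude_scale_invariance(self, standard_train):
        _, rec, _ = standard_train
        a = detect_recording_onsets(preprocess_recording(rec))
        b = detect_recording_onsets(preprocess_recording(rec.with_samples(0.2 * rec.samples)))
        assert np.array_equal(a.times, b.times)


class TestFeatureFormulas:
    def test_constant_ioi_series(self):
        times = 0.5 + 0.2 * np.arange(41)  # 41 onsets, IOIs all 0.2 s
        ons = OnsetSeries(times, np.ones(41))
        f = onset_ioi_features(ons, total_duration=10.0)
        assert f["onset_count"] == 41
        assert f["onset_rate"] == pytest.approx(4.1, abs=1e-9)
        assert f["ioi_mean"] == pytest.approx(0.2, abs=1e-9)
        assert f["ioi_sd"] == pytest.approx(0.0, abs=1e-9)
        assert f["inverse_min_ioi"] == pytest.approx(5.0, abs=1e-9)
        assert f["decrement_on_ioi"] == pytest.approx(0.0, abs=1e-9)
        assert f["inverse_ioi_mean"] == pytest.approx(5.0, abs=1e-9)
        assert f["inverse_ioi_cov"] == pytest.approx(0.0, abs=1e-9)
        assert f["onset_strength_cov"] == pytest.approx(0.0, abs=1e-9)

    def test_two_ioi_decrement_case(self):
        ons = OnsetSeries(np.array([0.0, 0.1, 0.3]), np.array([0.5, 1.0, 0.5]))
        f = onset_ioi_features(ons, total_duration=1.0)
        assert f["decrement_on_ioi"] == pytest.approx(np.log(2) / 2, abs=1e-9)
        assert f["inverse_ioi_mean"] == pytest.approx(7.5, abs=1e-9)

    def test_onset_rate_arithmetic(self):
        ons = OnsetSeries(np.linspace(0.1, 9.85, 40), np.ones(40))
        f = onset_ioi_features(ons, total_duration=10.0)
        assert f["onset_count"] == 40
        assert f["onset_rate"] == pytest.approx(4.0, abs=1e-9)

    @pytest.mark.parametrize("n,defined", [(0, []), (1, []),
                                           (2, ["ioi_mean", "inverse_min_ioi",
                                                "decrement_on_ioi", "inverse_ioi_mean"])])
    def test_undefined_flags_below_minimum_onsets(self, n, defined):
        ons = OnsetSeries(np.arange(n) * 0.2, np.ones(n)) if n else OnsetSeries(np.empty(0), np.empty(0))
        f = onset_ioi_features(ons, total_duration=10.0)
        for key in ("ioi_mean", "ioi_sd", "inverse_min_ioi", "decrement_on_ioi",
                    "inverse_ioi_mean", "inverse_ioi_cov"):
            if key in defined:
                assert np.isfinite(f[key])
            else:
                assert np.isnan(f[key])

    def test_min_ioi_inverse_at_least_inverse_of_mean(self):
        rng = np.random.default_rng(12)
        times = np.cumsum(rng.uniform(0.1, 0.4, 30))
        s = rng.uniform(0.2, 1.0, 30); s[0] = 1.0
        f = onset_ioi_features(OnsetSeries(times, s / s.max()), total_duration=12.0)
        assert f["inverse_min_ioi"] >= 1.0 / f["ioi_mean"]
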