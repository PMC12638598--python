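"""Generator contracts: timing manifests, determinism, and cohort simulation."""

import numpy as np
import pytest

from pataka import (
    CohortSpec, SyllableTrainSpec, sample_timing, simulate_cohort,
    synthesize_ddk_recording,
)
from pataka.features import FEATURE_NAMES
from pataka.synth import _COVARIATE_CENTER


def test_zero_repetitions_gives_noise_only_waveform_and_empty_manifest():
    spec = SyllableTrainSpec(n_repetitions=0, seed=1)
    rec, manifest = synthesize_ddk_recording(spec)
    assert manifest.n_repetitions == 0
    assert manifest.syllable_intervals == []
    assert len(rec.samples) == round(spec.duration * spec.sample_rate)
    # pure background noise: no sample anywhere near a vowel's amplitude
    assert np.max(np.abs(rec.samples)) < 0.2


def test_degenerate_jitter_gives_exact_iois():
    spec = SyllableTrainSpec(n_repetitions=40, ioi_mean=0.2, ioi_sd=0.0,
                             ioi_drift=0.0, syllable_duration=0.12, seed=2)
    manifest = sample_timing(spec)
    assert np.allclose(manifest.iois, 0.2, atol=1e-12)


def test_seed_determinism():
    spec = SyllableTrainSpec(seed=1)
    rec1, man1 = synthesize_ddk_recording(spec)
    rec2, man2 = synthesize_ddk_recording(spec)
    assert np.array_equal(rec1.samples, rec2.samples)
    assert np.array_equal(man1.onset_times, man2.onset_times)


def test_overflowing_repetitions_are_truncated():
    spec = SyllableTrainSpec(duration=2.0, n_repetitions=100, ioi_mean=0.25,
                             ioi_sd=0.0, seed=3)
    rec, manifest = synthesize_ddk_recording(spec)
    assert manifest.n_repetitions < 100
    last_start, last_end = manifest.syllable_intervals[-1]
    assert last_end <= spec.duration
    assert len(rec.samples) == round(2.0 * spec.sample_rate)


def test_drift_controls_ioi_slope_sign():
    up = sample_timing(SyllableTrainSpec(n_repetitions=30, ioi_drift=0.3, ioi_sd=0.0, seed=4))
    down = sample_timing(SyllableTrainSpec(n_repetitions=30, ioi_drift=-0.3, ioi_sd=0.0, seed=4))
    assert up.iois[-1] > up.iois[0]
    assert down.iois[-1] < down.iois[0]


def test_manifest_invariants():
    spec = SyllableTrainSpec(n_repetitions=25, seed=5)
    _, man = synthesize_ddk_recording(spec)
    assert np.all(np.diff(man.onset_times) > 0)
    assert np.all(man.voice_onset_times >= man.onset_times)
    assert len(man.voice_onset_times) == len(man.onset_times)
    # syllables and pauses tile the active span
    ends = [e for _, e in man.syllable_intervals[:-1]]
    starts = [s for s, _ in man.syllable_intervals[1:]]
    for (ps, pe), e, s in zip(man.pause_intervals, ends, starts):
        assert ps == pytest.approx(e) and pe == pytest.approx(s)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        SyllableTrainSpec(ioi_mean=0.1, syllable_duration=0.12)
    with pytest.raises(ValueError):
        SyllableTrainSpec(ioi_sd=-0.01)
    with pytest.raises(ValueError):
        SyllableTrainSpec(vot=0.2, syllable_duration=0.12)


class TestSimulateCohort:
    def test_null_world_outcomes_depend_only_on_covariates(self):
        spec = CohortSpec(n_participants=50, feature_effects={}, seed=6)
        table = simulate_cohort(spec)
        assert table.truth["feature_effects"] == {}
        eta = table.truth["eta"]
        coefs = table.truth["null_coefficients"]
        p = table.participants
        expected = (
            coefs["intercept_episodic_memory_errors"]
            + coefs["age"] * (p["age"] - _COVARIATE_CENTER["age"])
            + coefs["sex_male"] * p["sex_male"]
            + coefs["education"] * (p["education"] - _COVARIATE_CENTER["education"])
            + coefs["psychiatric"] * p["psychiatric"]
            + coefs["hads_anxiety"] * (p["hads_anxiety"] - _COVARIATE_CENTER["hads_anxiety"])
            + coefs["hads_depression"] * (p["hads_depression"] - _COVARIATE_CENTER["hads_depression"])
        )
        assert np.allclose(eta["episodic_memory_errors"], expected)

    def test_large_dispersion_approaches_poisson(self):
        # NB variance -> mean as the size parameter grows
        spec = CohortSpec(n_participants=10_000, nb_dispersion=1e6, seed=7,
                          feature_effects={})
        table = simulate_cohort(spec)
        y = table.participants["working_memory_errors"]
        ratio = y.var() / y.mean()
        # eta varies between participants, which itself inflates the ratio;
        # compare against the Poisson mixture bound rather than exactly 1
        eta = table.truth["eta"]["working_memory_errors"]
        mu = np.exp(eta)
        mixture_ratio = 1 + mu.var() / mu.mean()
        assert ratio == pytest.approx(mixture_ratio, rel=0.1)

    def test_outcome_mean_matches_exp_eta(self):
        spec = CohortSpec(n_participants=10_000, seed=8, feature_effects={})
        table = simulate_cohort(spec)
        mu = np.exp(table.truth["eta"]["episodic_memory_errors"])
        y = table.participants["episodic_memory_errors"]
        assert y.mean() == pytest.approx(mu.mean(), rel=0.02)
        # the executive score rides on a floor of one
        mu_s = np.exp(table.truth["eta"]["executive_strategy"])
        assert table.participants["executive_strategy"].mean() == pytest.approx(
            1 + mu_s.mean(), rel=0.02
        )

    def test_missingness_rate_binomial(self):
        spec = CohortSpec(n_participants=1000, missing_recording_rate=0.07, seed=9)
        table = simulate_cohort(spec)
        n_missing = table.features["pa"].isna().all(axis=1).sum()
        # binomial(1000, 0.07) central 95% interval
        assert 54 <= n_missing <= 86

    def test_true_features_complete_and_deterministic(self):
        spec = CohortSpec(n_participants=20, missing_recording_rate=0.0, seed=10)
        t1, t2 = simulate_cohort(spec), simulate_cohort(spec)
        assert list(t1.features["ta"].columns) == list(FEATURE_NAMES)
        assert t1.features["ta"].notna().all().all()
        assert t1.participants.equals(t2.participants)
        assert t1.features["ka"].equals(t2.features["ka"])

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(nb_dispersion=0.0)

    def test_unknown_feature_effect_rejected(self):
        spec = CohortSpec(n_participants=10, seed=1,
                          feature_effects={"episodic_memory_errors": {"bogus": 1.0}})
        with pytest.raises(ValueError, match="bogus"):
            simulate_cohort(spec)
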