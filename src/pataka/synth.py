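"""Synthetic DDK recordings and simulated cohorts with known ground truth.

No public DDK/cognition cohort exists for this analysis, so every downstream
stage is validated against data generated here.

Audio model.  A DDK trial is a train of repetitions inside a fixed-length
recording.  Each repetition is a voiceless plosive burst (short broadband
noise), a silent voicing gap, then a voiced vowel modeled as a 3-harmonic
tone with a 10-ms raised-cosine attack — enough periodicity structure for an
unambiguous voicing onset without full formant synthesis.  Inter-onset
intervals are drawn around a mean with Gaussian jitter and a linear drift of
the per-repetition mean from ``ioi_mean*(1-drift/2)`` to
``ioi_mean*(1+drift/2)``, so slowing across the trial ("decrement on IOI")
has a controllable sign.  Gaussian background noise is added at a target SNR
defined over the active-speech span only.  The exact event times are returned
as a :class:`~pataka.types.TimingManifest`.

Cohort model.  Covariates follow the study population's summaries (age
truncated-normal around 67, ~72% female, 5-level education, psychiatric
diagnosis flag, small-count HADS scores).  Each participant carries latent
timing parameters (cycle time, jitter, VOT, ...) from which per-test timing
manifests — and hence ground-truth feature vectors — are generated.  Count
outcomes are drawn from log-link GLMs: Poisson for the executive-strategy
score (floored at 1), negative binomial for the episodic- and working-memory
error counts, with a linear predictor combining the null covariate block and
planted per-feature effects.  All generating coefficients are stored in
``CohortTable.truth``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, NULL_COVARIATES, OUTCOMES, CohortTable, manifest_features
from .types import Recording, TimingManifest, TEST_LABELS

log = logging.getLogger(__name__)


@dataclass
class SyllableTrainSpec:
    """Parameters of one synthetic DDK trial.

    ``vot`` is the burst-onset-to-voicing interval (the quantity the VOT
    features measure), so the vowel starts at ``onset + vot``; the burst
    occupies ``[onset, onset + burst_duration]``.
    """

    sample_rate: int = 16000
    duration: float = 10.0
    n_repetitions: int = 40
    ioi_mean: float = 0.22
    ioi_sd: float = 0.010
    ioi_drift: float = 0.0
    syllable_duration: float = 0.12
    burst_duration: float = 0.010
    vot: float = 0.040
    vowel_f0: float = 140.0
    snr_db: float = 30.0
    seed: int = 0
    lead_silence: float = 0.5
    strength_jitter: float = 0.08   # relative spread of per-repetition loudness

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_repetitions < 0:
            raise ValueError("n_repetitions must be >= 0")
        if self.ioi_sd < 0:
            raise ValueError("ioi_sd must be >= 0")
        if not (self.ioi_mean > self.syllable_duration):
            raise ValueError("ioi_mean must exceed syllable_duration")
        if self.syllable_duration < max(self.burst_duration, self.vot) or self.burst_duration < 0 or self.vot < 0:
            raise ValueError("need syllable_duration >= max(burst_duration, vot) >= 0")


def sample_timing(spec: SyllableTrainSpec, rng: np.random.Generator | None = None) -> TimingManifest:
    """Draw the event times of a trial (pure function of ``spec.seed``).

    Repetitions that would overflow the recording are truncated; the manifest
    reflects only emitted repetitions.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_repetitions
    if n == 0:
        return TimingManifest()
    n_ioi = n - 1
    if n_ioi > 0:
        if n_ioi > 1:
            ramp = np.linspace(-0.5, 0.5, n_ioi)
        else:
            ramp = np.zeros(1)
        means = spec.ioi_mean * (1.0 + spec.ioi_drift * ramp)
        iois = rng.normal(means, spec.ioi_sd)
        iois = np.maximum(iois, spec.syllable_duration + 1e-3)
        onsets = spec.lead_silence + np.concatenate([[0.0], np.cumsum(iois)])
    else:
        onsets = np.array([spec.lead_silence])
    keep = onsets + spec.syllable_duration <= spec.duration
    onsets = onsets[keep]
    if onsets.size == 0:
        return TimingManifest()
    voice_onsets = onsets + spec.vot
    syllables = [(t, t + spec.syllable_duration) for t in onsets]
    pauses = [
        (s_end, next_start)
        for (_, s_end), (next_start, _) in zip(syllables[:-1], syllables[1:])
        if next_start - s_end > 0
    ]
    return TimingManifest(onsets, voice_onsets, syllables, pauses)


def _vowel(n: int, sr: int, f0: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / sr
    wave = np.zeros(n)
    for h, amp in enumerate((1.0, 0.5, 0.25), start=1):
        wave += amp * np.sin(2 * np.pi * f0 * h * t)
    wave /= np.max(np.abs(wave)) if n else 1.0
    attack = min(int(0.010 * sr), n)
    release = min(int(0.010 * sr), n - attack)
    env = np.ones(n)
    if attack:
        env[:attack] = 0.5 * (1 - np.cos(np.pi * np.arange(attack) / attack))
    if release:
        env[n - release:] = 0.5 * (1 + np.cos(np.pi * np.arange(release) / release))
    return wave * env


def synthesize_ddk_recording(
    spec: SyllableTrainSpec,
    test_label: str = "pa",
    participant_id: str = "",
) -> tuple[Recording, TimingManifest]:
    """Render a DDK trial to audio with its exact event-time manifest.

    Identical specs (including seed) give bit-identical waveforms and
    manifests.  The target SNR is defined on the active-speech span; with no
    repetitions the noise level falls back to a nominal speech RMS reference.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = sample_timing(spec, rng)
    sr = spec.sample_rate
    n_samples = int(round(spec.duration * sr))
    x = np.zeros(n_samples)
    strengths = 1.0 + spec.strength_jitter * rng.standard_normal(manifest.n_repetitions)
    strengths = np.clip(strengths, 0.3, None)
    for k, onset in enumerate(manifest.onset_times):
        o = int(round(onset * sr))
        amp = strengths[k]
        b_n = int(round(spec.burst_duration * sr))
        burst = rng.standard_normal(b_n)
        taper = min(max(int(0.002 * sr), 1), b_n)
        if b_n:
            burst[-taper:] *= np.linspace(1, 0, taper)
            burst *= 0.7 * amp / max(np.max(np.abs(burst)), 1e-12)
            x[o : o + b_n] += burst[: max(n_samples - o, 0)]
        v0 = int(round((onset + spec.vot) * sr))
        v_n = int(round((spec.syllable_duration - spec.vot) * sr))
        if v_n > 0 and v0 < n_samples:
            vow = amp * _vowel(v_n, sr, spec.vowel_f0, rng)
            x[v0 : v0 + v_n] += vow[: n_samples - v0]
    active = np.zeros(n_samples, dtype=bool)
    for s, e in manifest.syllable_intervals:
        active[int(s * sr) : int(e * sr)] = True
    if active.any():
        p_signal = float(np.mean(x[active] ** 2))
    else:
        p_signal = 0.25**2  # nominal speech RMS reference for empty trains
    sigma = np.sqrt(p_signal / 10 ** (spec.snr_db / 10))
    x = x + sigma * rng.standard_normal(n_samples)
    rec = Recording(x, sr, test_label=test_label, participant_id=participant_id)
    return rec, manifest


def write_wav(path: str | Path, rec: Recording) -> None:
    """Write 16-bit PCM mono RIFF WAV."""
    from scipy.io import wavfile

    peak = max(float(np.max(np.abs(rec.samples))), 1e-9)
    scaled = np.clip(rec.samples / peak, -1, 1) * 32767
    wavfile.write(str(path), rec.sample_rate, scaled.astype(np.int16))


def write_manifest(path: str | Path, manifest: TimingManifest) -> None:
    """Sidecar manifest: one ``event<TAB>time`` or ``zone<TAB>start<TAB>end`` line."""
    with open(path, "w") as fh:
        fh.write("event\tstart\tend\n")
        for t, v in zip(manifest.onset_times, manifest.voice_onset_times):
            fh.write(f"onset\t{t:.6f}\t\n")
            fh.write(f"voice_onset\t{v:.6f}\t\n")
        for s, e in manifest.syllable_intervals:
            fh.write(f"syllable\t{s:.6f}\t{e:.6f}\n")
        for s, e in manifest.pause_intervals:
            fh.write(f"pause\t{s:.6f}\t{e:.6f}\n")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _default_null_coefficients() -> dict[str, float]:
    # modest, plausible covariate effects on log-mean count outcomes
    return {
        "intercept_episodic_memory_errors": np.log(4.1),
        "intercept_executive_strategy": np.log(6.7),  # excess over the floor of 1
        "intercept_working_memory_errors": np.log(3.2),
        "age": 0.015,            # per year over 67
        "sex_male": 0.05,
        "education": -0.05,      # per ordinal level over 3
        "psychiatric": 0.10,
        "hads_anxiety": 0.010,   # per point over 5
        "hads_depression": 0.020,  # per point over 2.5
    }


#: Centering applied to covariates inside the linear predictor.
_COVARIATE_CENTER = {
    "age": 67.0, "sex_male": 0.0, "education": 3.0,
    "psychiatric": 0.0, "hads_anxiety": 5.0, "hads_depression": 2.5,
}


@dataclass
class CohortSpec:
    """Generating parameters of a simulated cohort.

    ``feature_effects`` maps outcome name -> {feature name: effect per
    in-sample SD of the participant-level true feature} on the log-link
    linear predictor.  ``sci_shift`` scales how much worse (slower, more
    variable) the SCI group's latent timing parameters are, in latent-SD
    units.
    """

    n_participants: int = 200
    group_fraction_sci: float = 0.169
    null_coefficients: dict[str, float] = field(default_factory=_default_null_coefficients)
    feature_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    nb_dispersion: float = 1.2
    missing_recording_rate: float = 0.07
    seed: int = 0
    sci_shift: float = 0.3
    # latent timing population (mean, sd)
    ioi_mean_pop: tuple[float, float] = (0.220, 0.025)
    ioi_sd_pop: tuple[float, float] = (0.011, 0.004)
    ioi_drift_pop: tuple[float, float] = (0.05, 0.05)
    vot_pop: tuple[float, float] = (0.045, 0.010)
    syllable_frac_pop: tuple[float, float] = (0.55, 0.05)
    snr_pop: tuple[float, float] = (30.0, 4.0)
    duration: float = 10.0
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        for name, v in (("group_fraction_sci", self.group_fraction_sci),
                        ("missing_recording_rate", self.missing_recording_rate)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for out in self.feature_effects:
            if out not in OUTCOMES:
                raise ValueError(f"unknown outcome {out!r} in feature_effects")


#: per-test multiplicative tempo factors ("pa" is typically fastest)
_TEST_TEMPO = {"pa": 0.98, "ta": 1.00, "ka": 1.03}


def participant_train_spec(
    latents: dict[str, float], test_label: str, seed: int,
    duration: float = 10.0, sample_rate: int = 16000,
) -> SyllableTrainSpec:
    """Build the synthesis spec for one (participant, test) from latents."""
    ioi = latents["ioi_mean"] * _TEST_TEMPO[test_label]
    syll = min(max(latents["syllable_frac"] * ioi, latents["vot"] + 0.02), ioi - 0.02)
    n_max = int(np.floor((duration - 0.5 - syll) / ioi)) + 1
    return SyllableTrainSpec(
        sample_rate=sample_rate,
        duration=duration,
        n_repetitions=n_max,
        ioi_mean=ioi,
        ioi_sd=latents["ioi_sd"],
        ioi_drift=latents["ioi_drift"],
        syllable_duration=syll,
        burst_duration=0.010,
        vot=latents["vot"],
        vowel_f0=latents["f0"],
        snr_db=latents["snr_db"],
        seed=seed,
        strength_jitter=latents["strength_jitter"],
    )


def _draw_latents(rng: np.random.Generator, spec: CohortSpec, is_sci: bool) -> dict[str, float]:
    shift = spec.sci_shift if is_sci else 0.0
    def tn(mean, sd, lo, hi, k=0.0):
        return float(np.clip(rng.normal(mean + k * sd, sd), lo, hi))
    return {
        "ioi_mean": tn(*spec.ioi_mean_pop, 0.15, 0.45, shift),
        "ioi_sd": tn(*spec.ioi_sd_pop, 0.002, 0.05, shift),
        "ioi_drift": tn(*spec.ioi_drift_pop, -0.3, 0.4, shift),
        "vot": tn(*spec.vot_pop, 0.015, 0.10, shift),
        "syllable_frac": tn(*spec.syllable_frac_pop, 0.35, 0.75),
        "snr_db": tn(*spec.snr_pop, 18.0, 45.0),
        "f0": tn(165.0, 30.0, 90.0, 260.0),
        "strength_jitter": tn(0.08, 0.03, 0.02, 0.2),
    }


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Simulate covariates, per-test true features, and count outcomes.

    True features are computed by construction: each (participant, test) gets
    a timing manifest drawn from the participant's latent parameters, and the
    feature formulas are applied to those exact event times.  Outcomes are
    drawn from log-link count GLMs whose linear predictor is the null
    covariate block plus the planted ``feature_effects`` applied to z-scored
    participant-level true features.  The generating record (coefficients,
    latents, per-test synthesis specs, realized linear predictors) is stored
    in ``CohortTable.truth``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    ids = [f"P{i:04d}" for i in range(n)]
    is_sci = rng.random(n) < spec.group_fraction_sci

    age = np.clip(rng.normal(67.0, 7.3, n), 50, None).round()
    sex_male = (rng.random(n) < 0.28).astype(int)
    education = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.10, 0.08, 0.20, 0.23, 0.39])
    psychiatric = (rng.random(n) < np.where(is_sci, 0.30, 0.15)).astype(int)

    def hads(mean, var):
        theta = mean**2 / max(var - mean, 1e-6)
        return np.minimum(rng.negative_binomial(theta, theta / (theta + mean), n), 21)

    anx = np.where(is_sci, hads(6.5, 15.2), hads(5.0, 11.6))
    dep = np.where(is_sci, hads(4.7, 10.2), hads(2.5, 4.8))

    # latent timing parameters and per-test true features
    seedseq = np.random.SeedSequence(spec.seed, spawn_key=(1,))
    child_seeds = seedseq.generate_state(n * len(TEST_LABELS) * 2).reshape(n, len(TEST_LABELS), 2)
    latents = [_draw_latents(rng, spec, bool(s)) for s in is_sci]
    feature_rows: dict[str, list[dict[str, float]]] = {t: [] for t in TEST_LABELS}
    train_specs: dict[tuple[str, str], SyllableTrainSpec] = {}
    for i, pid in enumerate(ids):
        for j, label in enumerate(TEST_LABELS):
            seed_ij = int(child_seeds[i, j, 0] % (2**31 - 1))
            tspec = participant_train_spec(
                latents[i], label, seed_ij, spec.duration, spec.sample_rate
            )
            train_specs[(pid, label)] = tspec
            manifest = sample_timing(tspec)
            s_rng = np.random.default_rng(int(child_seeds[i, j, 1] % (2**31 - 1)))
            strengths = np.clip(
                1.0 + latents[i]["strength_jitter"] * s_rng.standard_normal(manifest.n_repetitions),
                0.3, None,
            )
            feature_rows[label].append(manifest_features(manifest, spec.duration, strengths))
    feature_tables = {
        t: pd.DataFrame(feature_rows[t], index=pd.Index(ids, name="participant_id"))
        for t in TEST_LABELS
    }

    # participant-level true features: mean across tests, z-scored in-sample
    stacked = sum(feature_tables[t] for t in TEST_LABELS) / len(TEST_LABELS)
    mu, sd = stacked.mean(), stacked.std(ddof=1)
    z = (stacked - mu) / sd.replace(0, np.nan)

    coefs = spec.null_coefficients
    eta_base = (
        coefs["age"] * (age - _COVARIATE_CENTER["age"])
        + coefs["sex_male"] * sex_male
        + coefs["education"] * (education - _COVARIATE_CENTER["education"])
        + coefs["psychiatric"] * psychiatric
        + coefs["hads_anxiety"] * (anx - _COVARIATE_CENTER["hads_anxiety"])
        + coefs["hads_depression"] * (dep - _COVARIATE_CENTER["hads_depression"])
    )
    outcomes: dict[str, np.ndarray] = {}
    etas: dict[str, np.ndarray] = {}
    for out in OUTCOMES:
        eta = eta_base + coefs[f"intercept_{out}"]
        for feat, beta in spec.feature_effects.get(out, {}).items():
            if feat not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {feat!r} in feature_effects[{out!r}]")
            zf = z[feat].to_numpy()
            eta = eta + beta * np.nan_to_num(zf)
        if not np.all(np.isfinite(eta)):
            raise ValueError(f"non-finite linear predictor for outcome {out!r}; "
                             f"check intercept_{out} and its feature effects")
        mean = np.exp(eta)
        etas[out] = eta
        if out == "executive_strategy":
            outcomes[out] = 1 + rng.poisson(mean)
        else:
            theta = spec.nb_dispersion
            outcomes[out] = rng.negative_binomial(theta, theta / (theta + mean))

    participants = pd.DataFrame(
        {
            "group": np.where(is_sci, "SCI", "HC"),
            "age": age, "sex_male": sex_male, "education": education,
            "psychiatric": psychiatric, "hads_anxiety": anx, "hads_depression": dep,
            **outcomes,
        },
        index=pd.Index(ids, name="participant_id"),
    )

    # missingness: each (participant, test) independently loses its recording
    missing = rng.random((n, len(TEST_LABELS))) < spec.missing_recording_rate
    for j, t in enumerate(TEST_LABELS):
        feature_tables[t].loc[missing[:, j], :] = np.nan

    truth = {
        "null_coefficients": dict(coefs),
        "feature_effects": {k: dict(v) for k, v in spec.feature_effects.items()},
        "nb_dispersion": spec.nb_dispersion,
        "latents": pd.DataFrame(latents, index=participants.index),
        "train_specs": train_specs,
        "eta": pd.DataFrame(etas, index=participants.index),
        "feature_standardization": pd.DataFrame({"mean": mu, "sd": sd}),
        "missing": pd.DataFrame(missing, index=participants.index, columns=list(TEST_LABELS)),
    }
    return CohortTable(participants, feature_tables, truth=truth)
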