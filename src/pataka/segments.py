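"""Speech/pause segmentation, voice onset time, and the timing features.

Each DDK repetition divides into a "syllable" zone (active speech: plosive
burst, a short voiceless gap, then the voiced vowel) and a "pause" zone (the
silence between the end of one utterance and the start of the next
repetition).  Segmentation runs a smoothed short-time RMS energy track through
a hysteresis threshold (separate enter-speech and exit-speech levels anchored
between the noise floor and the speech level), with minimum-duration
constraints on both zone types.

Voice onset time (VOT) is the interval from the plosive burst onset (the start
of a speech interval) to the onset of vocal-fold voicing, detected as the
first analysis window whose normalized autocorrelation shows a periodicity
peak in the 70-400 Hz fundamental band.  The coarse voicing frame is refined
on the amplitude envelope so VOT is accurate to a few milliseconds on clean
recordings.

Conventions: leading silence before the first utterance and trailing silence
after the last are excluded from the pause totals — pauses exist only between
repetitions — while the percent features use the full sample duration as
denominator, so speech% + pause% <= 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import Recording, intervals_total


@dataclass
class SegmentationConfig:
    rms_window: float = 0.012       # s; short window keeps zone edges sharp
    rms_hop: float = 0.003          # s
    enter_frac: float = 0.12        # enter-speech level, fraction of floor->peak range
    exit_frac: float = 0.06         # exit-speech level (hysteresis)
    min_speech: float = 0.040       # s; shorter blips are dropped
    min_pause: float = 0.030        # s; shorter gaps are bridged
    blip_merge_gap: float = 0.150   # s; a sub-min blip (a lone plosive burst)
                                    # is merged forward across a gap up to this
                                    # long (the VOT ceiling), keeping the burst
                                    # and its vowel in one syllable interval
    noise_percentile: float = 15.0  # RMS percentile taken as the noise floor
    peak_percentile: float = 97.0   # RMS percentile taken as the speech level


@dataclass
class VOTConfig:
    window: float = 0.030           # autocorrelation window, s
    step: float = 0.005             # scan step, s
    f0_min: float = 70.0            # Hz, lag band for the periodicity peak
    f0_max: float = 400.0
    voicing_threshold: float = 0.5  # normalized autocorrelation peak
    ceiling: float = 0.150          # s; longer gaps are segmentation errors
    attack_compensation: float = 0.005  # s; half of the vowel's amplitude attack


@dataclass
class SegmentSet:
    """Speech and pause zones of one recording (seconds)."""

    speech_intervals: list[tuple[float, float]] = field(default_factory=list)
    pause_intervals: list[tuple[float, float]] = field(default_factory=list)
    total_duration: float = 0.0

    def __post_init__(self) -> None:
        for s, e in self.speech_intervals + self.pause_intervals:
            if e <= s:
                raise ValueError("intervals must have end > start")
            if s < -1e-9 or e > self.total_duration + 1e-9:
                raise ValueError("interval outside [0, total_duration]")
        starts = [s for s, _ in self.speech_intervals]
        if starts != sorted(starts):
            raise ValueError("speech intervals must be ascending")

    @property
    def total_speech(self) -> float:
        return intervals_total(self.speech_intervals)

    @property
    def total_pause(self) -> float:
        return intervals_total(self.pause_intervals)


@dataclass
class VOTSeries:
    """Per-repetition voice onset times that survived quality control.

    ``n_attempted`` counts every speech interval examined, including those
    where no voicing was found or the measured gap exceeded the ceiling.
    """

    vots: np.ndarray
    n_attempted: int

    def __post_init__(self) -> None:
        self.vots = np.asarray(self.vots, dtype=np.float64)
        if len(self.vots) > self.n_attempted:
            raise ValueError("more VOTs than attempts")
        if np.any(self.vots < 0):
            raise ValueError("VOT cannot be negative")


def _rms_track(x: np.ndarray, sr: int, window: float, hop: float) -> tuple[np.ndarray, np.ndarray]:
    win_n = max(int(round(window * sr)), 2)
    hop_n = max(int(round(hop * sr)), 1)
    smoothed = ndimage.uniform_filter1d(x.astype(np.float64) ** 2, size=win_n, mode="constant")
    idx = np.arange(0, len(x), hop_n)
    rms = np.sqrt(np.maximum(smoothed[idx], 0.0))
    return idx / sr, rms


def segment_speech_pause(rec: Recording, config: SegmentationConfig | None = None) -> SegmentSet:
    """Split a denoised, normalized recording into speech and pause zones."""
    cfg = config or SegmentationConfig()
    duration = rec.duration
    times, rms = _rms_track(rec.samples, rec.sample_rate, cfg.rms_window, cfg.rms_hop)
    if rms.size == 0 or rms.max() <= 0:
        return SegmentSet([], [], duration)
    floor = np.percentile(rms, cfg.noise_percentile)
    peak = np.percentile(rms, cfg.peak_percentile)
    if peak <= floor * 1.5:
        # no dynamic range: either all silence or one continuous sound
        if peak > 1e-6:
            return SegmentSet([(0.0, duration)], [], duration)
        return SegmentSet([], [], duration)
    enter = floor + cfg.enter_frac * (peak - floor)
    exit_ = floor + cfg.exit_frac * (peak - floor)

    speech: list[tuple[float, float]] = []
    in_speech = False
    start = 0.0
    for t, v in zip(times, rms):
        if not in_speech and v >= enter:
            in_speech = True
            start = t
        elif in_speech and v < exit_:
            in_speech = False
            speech.append((start, t))
    if in_speech:
        speech.append((start, float(duration)))

    # bridge sub-min pauses
    merged: list[tuple[float, float]] = []
    for s, e in speech:
        if merged and s - merged[-1][1] < cfg.min_pause:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    # a sub-min blip is a lone plosive burst: merge it forward across its
    # voicing gap so burst and vowel form one syllable interval
    with_blips: list[tuple[float, float]] = []
    i = 0
    while i < len(merged):
        s, e = merged[i]
        if (
            e - s < cfg.min_speech
            and i + 1 < len(merged)
            and merged[i + 1][0] - e <= cfg.blip_merge_gap
        ):
            merged[i + 1] = (s, merged[i + 1][1])
        else:
            with_blips.append((s, e))
        i += 1
    merged = [(s, e) for s, e in with_blips if e - s >= cfg.min_speech]

    pauses = [
        (e0, s1)
        for (_, e0), (s1, _) in zip(merged[:-1], merged[1:])
        if s1 - e0 > 0
    ]
    return SegmentSet(merged, pauses, duration)


def _periodicity(window: np.ndarray, sr: int, f0_min: float, f0_max: float) -> float:
    """Max normalized autocorrelation over the lag band for f0 in [f0_min, f0_max]."""
    n = len(window)
    x = window - window.mean()
    power = float(np.dot(x, x))
    if power < 1e-12:
        return 0.0
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    lag_lo = max(int(sr / f0_max), 1)
    lag_hi = min(int(sr / f0_min) + 1, n - 1)
    if lag_hi <= lag_lo:
        return 0.0
    return float(np.max(ac[lag_lo:lag_hi]) / ac[0])


def measure_vot(
    rec: Recording,
    segments: SegmentSet,
    config: VOTConfig | None = None,
) -> VOTSeries:
    """Per-repetition VOT: burst onset (speech-interval start) to voicing onset.

    Repetitions where no voicing is detected, or where the measured gap
    exceeds the ceiling, are dropped from ``vots`` but still counted in
    ``n_attempted``.
    """
    cfg = config or VOTConfig()
    sr = rec.sample_rate
    x = rec.samples
    vots: list[float] = []
    win_n = int(round(cfg.window * sr))
    step_n = max(int(round(cfg.step * sr)), 1)
    for s, e in segments.speech_intervals:
        s_i = int(round(s * sr))
        e_i = min(int(round(e * sr)), len(x))
        scan_end = min(e_i, s_i + int(round((cfg.ceiling + 0.06) * sr)))
        voiced_at: int | None = None
        for w0 in range(s_i, max(scan_end - win_n, s_i) + 1, step_n):
            if _periodicity(x[w0 : w0 + win_n], sr, cfg.f0_min, cfg.f0_max) >= cfg.voicing_threshold:
                voiced_at = w0
                break
        if voiced_at is None:
            continue
        onset = _refine_voicing_onset(x, sr, s_i, voiced_at, e_i, cfg)
        if onset is None:
            continue
        vot = (onset - s_i) / sr
        if 0.0 <= vot < cfg.ceiling:
            vots.append(vot)
    return VOTSeries(np.array(vots), n_attempted=len(segments.speech_intervals))


def _refine_voicing_onset(
    x: np.ndarray, sr: int, s_i: int, voiced_at: int, e_i: int, cfg: VOTConfig
) -> int | None:
    """Locate the vowel's amplitude rise near the first voiced window.

    The coarse periodicity scan localizes voicing to within a window length;
    the refinement finds the first sustained half-amplitude crossing of the
    smoothed envelope and backs off by the attack compensation.
    """
    # centred RMS over ~one glottal period so the track does not ripple at f0
    smooth_n = max(int(0.008 * sr), 2)
    lo = max(s_i, voiced_at - int(0.025 * sr))
    hi = min(e_i, voiced_at + int(round(cfg.window * sr)) + int(0.02 * sr))
    if hi - lo < smooth_n + 2:
        return None
    env = np.sqrt(ndimage.uniform_filter1d(x[lo:hi] ** 2, size=smooth_n, mode="nearest"))
    vowel_span = x[voiced_at : min(e_i, voiced_at + int(0.06 * sr))]
    if vowel_span.size < smooth_n:
        return None
    steady = np.percentile(
        np.sqrt(ndimage.uniform_filter1d(vowel_span**2, size=smooth_n)), 90
    )
    if steady <= 0:
        return None
    thresh = 0.5 * steady
    # must outlast a burst (~10 ms) plus the RMS smoothing spread
    sustain_n = int(0.022 * sr)
    above = env >= thresh
    # indices that stay above threshold for the sustain span
    run = ndimage.uniform_filter1d(above.astype(float), size=sustain_n, origin=-(sustain_n // 2))
    ok = above & (run > 0.95)
    # candidate rising edges, each verified as periodic (a plosive burst can
    # pass the amplitude test but is not voiced)
    edges = np.nonzero(ok & ~np.concatenate([[False], ok[:-1]]))[0]
    win_n = int(round(cfg.window * sr))
    for idx in edges:
        cand = lo + int(idx)
        if _periodicity(x[cand : cand + win_n], sr, cfg.f0_min, cfg.f0_max) >= cfg.voicing_threshold:
            onset = cand - int(round(cfg.attack_compensation * sr))
            return max(onset, s_i)
    return None


def timing_features(segments: SegmentSet, vots: VOTSeries) -> dict[str, float]:
    """Syllable, pause and voice-onset feature group (10 of the 19 features).

    Undefined entries — empty interval sets, zero denominators (including a
    zero total pause for the speech-to-pause ratio) — are NaN.
    """
    nan = float("nan")
    out = {k: nan for k in (
        "articulation_rate", "syllable_duration_mean", "syllable_duration_cov",
        "speech_percent", "speech_to_pause_ratio", "pause_mean", "pause_cov",
        "pause_percent", "vot_mean", "vot_cov",
    )}
    dur = segments.total_duration
    speech_lens = np.array([e - s for s, e in segments.speech_intervals])
    pause_lens = np.array([e - s for s, e in segments.pause_intervals])
    if speech_lens.size:
        total_speech = speech_lens.sum()
        out["articulation_rate"] = len(speech_lens) / total_speech
        out["syllable_duration_mean"] = float(speech_lens.mean())
        if speech_lens.size >= 2 and speech_lens.mean() > 0:
            out["syllable_duration_cov"] = float(np.std(speech_lens, ddof=1) / speech_lens.mean())
        if dur > 0:
            out["speech_percent"] = 100.0 * total_speech / dur
    if pause_lens.size:
        total_pause = pause_lens.sum()
        out["pause_mean"] = float(pause_lens.mean())
        if pause_lens.size >= 2 and pause_lens.mean() > 0:
            out["pause_cov"] = float(np.std(pause_lens, ddof=1) / pause_lens.mean())
        if dur > 0:
            out["pause_percent"] = 100.0 * total_pause / dur
        if speech_lens.size and total_pause > 0:
            out["speech_to_pause_ratio"] = float(speech_lens.sum() / total_pause)
    if len(vots.vots):
        out["vot_mean"] = float(vots.vots.mean())
        if len(vots.vots) >= 2 and vots.vots.mean() > 0:
            out["vot_cov"] = float(np.std(vots.vots, ddof=1) / vots.vots.mean())
    return out
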