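"""Recording ingestion, screening, denoising and normalization.

Recordings arrive as single-channel WAV at whatever rate the participant's
hardware produced (8-48 kHz).  The preprocessing stage mirrors the study
protocol: 8-kHz recordings are excluded outright (distorted quality),
recordings of negligible length or containing no utterance are excluded, the
rest are denoised with non-stationary spectral gating and peak-normalized.
After screening, everything is resampled to one internal analysis rate
(16 kHz) so downstream frame/hop parameters are uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .types import Recording

log = logging.getLogger(__name__)

#: Internal analysis rate applied after screening.
ANALYSIS_RATE = 16000
#: A 10-s protocol recording below this length cannot contain a usable trial.
MIN_DURATION = 2.0
#: Active-speech fraction below this floor counts as "no utterance".
UTTERANCE_FLOOR = 0.02


@dataclass(frozen=True)
class ScreeningOutcome:
    admitted: bool
    reason: str  # ok | rate_8khz | negligible_length | no_utterance

    def __post_init__(self) -> None:
        if (self.reason == "ok") != self.admitted:
            raise ValueError("reason must be 'ok' iff admitted")


@dataclass
class DenoiseConfig:
    """Spectral-gating parameters.

    The per-band noise floor is tracked as a running low percentile of the
    short-time magnitude over a sliding window, so the gate adapts to
    non-stationary ambient noise.  Bins below ``floor * (1 + margin)`` are
    attenuated towards ``gain_floor`` through a soft sigmoid mask.
    """

    frame: float = 0.032
    hop: float = 0.008
    floor_window: float = 1.5       # s, sliding noise-tracking window
    floor_percentile: float = 20.0
    margin_db: float = 6.0          # gate threshold above the tracked floor
    gain_floor: float = 0.08        # residual gain for gated bins
    softness_db: float = 3.0        # sigmoid transition width


def read_wav(path: str | Path, test_label: str = "pa", participant_id: str = "") -> Recording:
    """Read a RIFF WAV (PCM 8/16/24/32-bit or float) as a mono Recording.

    Multi-channel input is averaged to mono.  Raises ``IOError`` for an
    unreadable container, which callers count separately from screening
    rejections.
    """
    try:
        sr, data = wavfile.read(str(path))
    except Exception as exc:  # corrupt container -> distinct I/O failure
        raise IOError(f"unreadable WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.integer):
        x = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return Recording(x, int(sr), test_label=test_label, participant_id=participant_id)


def active_fraction(rec: Recording, rel_threshold: float = 0.1) -> float:
    """Fraction of 10-ms frames whose RMS exceeds ``rel_threshold`` x peak RMS."""
    hop = max(int(0.010 * rec.sample_rate), 1)
    n = (len(rec.samples) // hop) * hop
    if n == 0:
        return 0.0
    frames = rec.samples[:n].reshape(-1, hop)
    rms = np.sqrt((frames**2).mean(axis=1))
    peak = rms.max()
    if peak <= 0:
        return 0.0
    floor = np.percentile(rms, 15)
    # require headroom over the noise floor, not just over zero
    return float(np.mean(rms > np.maximum(rel_threshold * peak, 3.0 * floor)))


def screen_recording(
    rec: Recording,
    min_duration: float = MIN_DURATION,
    utterance_check: bool = True,
    utterance_floor: float = UTTERANCE_FLOOR,
) -> ScreeningOutcome:
    """Admission screening applied before any analysis.

    Rejects 8-kHz recordings, recordings shorter than ``min_duration``
    seconds, and (when ``utterance_check``) recordings whose denoised
    active-speech fraction falls below ``utterance_floor``.
    """
    if rec.sample_rate == 8000:
        return ScreeningOutcome(False, "rate_8khz")
    if rec.duration < min_duration:
        return ScreeningOutcome(False, "negligible_length")
    if utterance_check:
        if active_fraction(denoise(rec)) < utterance_floor:
            return ScreeningOutcome(False, "no_utterance")
    return ScreeningOutcome(True, "ok")


def _tracked_floor(mag_db: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    """Per-band noise floor over a sliding window of short-time frames.

    The low percentile is evaluated on half-overlapping blocks of
    ``floor_window`` length and linearly interpolated between block centres,
    which tracks non-stationary noise at a fraction of the cost of a rolling
    percentile.
    """
    n_bands, n_frames = mag_db.shape
    win = max(int(round(cfg.floor_window / cfg.hop)), 4)
    step = max(win // 2, 1)
    starts = np.arange(0, max(n_frames - win, 0) + 1, step)
    if len(starts) == 0:
        starts = np.array([0])
    centres = np.minimum(starts + win / 2, n_frames - 1)
    blocks = np.stack(
        [np.percentile(mag_db[:, s : s + win], cfg.floor_percentile, axis=1) for s in starts],
        axis=1,
    )
    if blocks.shape[1] == 1:
        return np.repeat(blocks, n_frames, axis=1)
    frames = np.arange(n_frames)
    out = np.empty_like(mag_db)
    for b in range(n_bands):
        out[b] = np.interp(frames, centres, blocks[b])
    return out


def denoise(rec: Recording, config: DenoiseConfig | None = None) -> Recording:
    """Non-stationary spectral-gating noise reduction.

    Deterministic; preserves length and sample rate; an all-silent input
    passes through unchanged.
    """
    cfg = config or DenoiseConfig()
    x = rec.samples
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        return rec.with_samples(x.copy())
    nperseg = max(int(round(cfg.frame * rec.sample_rate)), 16)
    hop_n = max(int(round(cfg.hop * rec.sample_rate)), 1)
    win = signal.get_window("hann", nperseg)
    sft = signal.ShortTimeFFT(win, hop=hop_n, fs=rec.sample_rate, fft_mode="onesided")
    S = sft.stft(x)
    mag_db = 20.0 * np.log10(np.abs(S) + 1e-12)
    from scipy.ndimage import uniform_filter

    floor_db = _tracked_floor(mag_db, cfg)
    over = mag_db - (floor_db + cfg.margin_db)
    gain = cfg.gain_floor + (1 - cfg.gain_floor) / (1 + np.exp(-over / cfg.softness_db))
    gain = uniform_filter(gain, size=(3, 3), mode="nearest")
    y = sft.istft(S * gain, k1=len(x))
    y = np.real(y[: len(x)])
    if len(y) < len(x):
        y = np.pad(y, (0, len(x) - len(y)))
    return rec.with_samples(y)


def normalize(rec: Recording) -> Recording:
    """Scale so the peak absolute amplitude is exactly 1.

    Raises ``ValueError("silent recording")`` on all-zero input.
    """
    peak = float(np.max(np.abs(rec.samples))) if len(rec.samples) else 0.0
    if peak == 0:
        raise ValueError("silent recording")
    return rec.with_samples(rec.samples / peak)


def resample(rec: Recording, target_rate: int = ANALYSIS_RATE) -> Recording:
    """Polyphase resampling to the internal analysis rate."""
    if rec.sample_rate == target_rate:
        return rec
    from math import gcd

    g = gcd(rec.sample_rate, target_rate)
    y = signal.resample_poly(rec.samples, target_rate // g, rec.sample_rate // g)
    out = Recording(y, target_rate, rec.test_label, rec.participant_id)
    return out


def preprocess_recording(
    rec: Recording,
    denoise_config: DenoiseConfig | None = None,
    do_denoise: bool = True,
) -> Recording:
    """screen-passed recording -> resampled, denoised, peak-normalized."""
    out = resample(rec)
    if do_denoise:
        out = denoise(out, denoise_config)
    return normalize(out)
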