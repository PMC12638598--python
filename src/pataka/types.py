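"""Core containers shared across the acquisition and analysis stages.

A :class:`Recording` is a mono waveform plus the metadata needed to route it
through the pipeline (which DDK syllable it is, who produced it).  A
:class:`TimingManifest` is the ground-truth event record emitted by the
synthesizer: where each syllable begins, where voicing begins, and how the
active span tiles into syllable and pause zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

TEST_LABELS = ("pa", "ta", "ka")


@dataclass
class Recording:
    """A single-channel DDK recording.

    Parameters
    ----------
    samples : np.ndarray
        Mono float waveform (dimensionless amplitude).
    sample_rate : int
        Sampling rate in Hz; ingestion admits 8000-48000.
    test_label : str
        One of ``"pa"``, ``"ta"``, ``"ka"``.
    participant_id : str
        Opaque participant identifier.
    """

    samples: np.ndarray
    sample_rate: int
    test_label: str = "pa"
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be mono (1-D)")
        if not (8000 <= self.sample_rate <= 48000):
            raise ValueError(f"sample_rate {self.sample_rate} outside [8000, 48000] Hz")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording contains non-finite samples")
        if self.test_label not in TEST_LABELS:
            raise ValueError(f"test_label must be one of {TEST_LABELS}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass
class TimingManifest:
    """Ground-truth event times for one synthesized recording (seconds).

    ``onset_times`` mark the commencement of each syllable repetition;
    ``voice_onset_times`` mark where the voiced vowel begins (so
    ``voice_onset_times - onset_times`` is the true per-repetition VOT).
    Syllable intervals cover active speech; pause intervals are the gaps
    between the end of one utterance and the start of the next repetition.
    """

    onset_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    voice_onset_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    syllable_intervals: list[tuple[float, float]] = field(default_factory=list)
    pause_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=np.float64)
        self.voice_onset_times = np.asarray(self.voice_onset_times, dtype=np.float64)
        if len(self.onset_times) != len(self.voice_onset_times):
            raise ValueError("one voice onset per syllable onset required")
        if len(self.onset_times) > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ValueError("onset_times must be strictly increasing")
        if np.any(self.voice_onset_times < self.onset_times):
            raise ValueError("voice onsets cannot precede syllable onsets")
        for start, end in list(self.syllable_intervals) + list(self.pause_intervals):
            if end <= start:
                raise ValueError("intervals must have end > start")

    @property
    def n_repetitions(self) -> int:
        return len(self.onset_times)

    @property
    def iois(self) -> np.ndarray:
        """True inter-onset intervals (empty when fewer than two onsets)."""
        return np.diff(self.onset_times)

    @property
    def vots(self) -> np.ndarray:
        return self.voice_onset_times - self.onset_times

    def total_speech(self) -> float:
        return float(sum(e - s for s, e in self.syllable_intervals))

    def total_pause(self) -> float:
        return float(sum(e - s for s, e in self.pause_intervals))


def intervals_total(intervals: Sequence[tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in intervals))
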