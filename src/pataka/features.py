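"""Feature assembly: the 19-feature vector, the cohort table, and the
pairwise-correlation exclusion constraint used by model selection.

The 19 motor-speech features fall into six groups — onset, inter-onset
interval, syllable, pause, voice onset, and energy — and are merged with the
cohort covariates (age, sex, education, psychiatric diagnosis, HADS anxiety
and depression) and the three count outcomes.  Features whose pairwise
Pearson correlation exceeds 0.6 in magnitude in ALL THREE DDK tests are
barred from co-occurring in any single model (collinearity control for the
exhaustive subset search).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .onsets import OnsetSeries, detect_recording_onsets, onset_ioi_features
from .segments import SegmentSet, VOTSeries, measure_vot, segment_speech_pause, timing_features
from .types import Recording, TEST_LABELS

log = logging.getLogger(__name__)

#: The 19 motor-speech features, in reporting order.
FEATURE_NAMES = (
    "onset_count", "onset_rate",
    "ioi_mean", "ioi_sd", "inverse_min_ioi", "decrement_on_ioi",
    "inverse_ioi_mean", "inverse_ioi_cov",
    "articulation_rate", "syllable_duration_mean", "syllable_duration_cov",
    "speech_percent", "speech_to_pause_ratio",
    "pause_mean", "pause_cov", "pause_percent",
    "vot_mean", "vot_cov",
    "onset_strength_cov",
)

#: Cohort covariates forming the null model block.
NULL_COVARIATES = (
    "age", "sex_male", "education", "psychiatric",
    "hads_anxiety", "hads_depression",
)

OUTCOMES = ("episodic_memory_errors", "executive_strategy", "working_memory_errors")


def extract_features(rec: Recording) -> dict[str, float]:
    """All 19 features from a preprocessed (denoised, normalized) recording."""
    onsets = detect_recording_onsets(rec)
    out = onset_ioi_features(onsets, rec.duration)
    segments = segment_speech_pause(rec)
    vots = measure_vot(rec, segments)
    out.update(timing_features(segments, vots))
    return {name: out[name] for name in FEATURE_NAMES}


def manifest_features(manifest, total_duration: float, strengths: np.ndarray | None = None) -> dict[str, float]:
    """Ground-truth features computed directly from a timing manifest.

    Used by the synthetic-cohort generator (features by construction) and by
    round-trip tests.  ``strengths`` supplies per-onset envelope strengths;
    when omitted the energy feature is NaN.
    """
    n = manifest.n_repetitions
    if strengths is None:
        strengths = np.ones(n)
    if n:
        strengths = np.asarray(strengths, dtype=float)
        strengths = strengths / strengths.max()
    onsets = OnsetSeries(manifest.onset_times, strengths[:n])
    out = onset_ioi_features(onsets, total_duration)
    segs = SegmentSet(list(manifest.syllable_intervals), list(manifest.pause_intervals), total_duration)
    vots = VOTSeries(manifest.vots, n_attempted=n)
    out.update(timing_features(segs, vots))
    return {name: out[name] for name in FEATURE_NAMES}


@dataclass
class CohortTable:
    """Per-participant covariates, outcomes, and per-test feature vectors.

    ``participants`` is indexed by participant id and carries ``group``
    (HC/SCI), the null covariates and the three count outcomes.  ``features``
    maps each test label to a DataFrame of the 19 features indexed by
    participant id; a row of NaNs means no usable recording for that test.
    ``truth`` (optional) records the generating coefficients for synthetic
    cohorts.
    """

    participants: pd.DataFrame
    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.participants.index.has_duplicates:
            dupes = self.participants.index[self.participants.index.duplicated()].unique()
            raise ValueError(f"duplicate participant ids: {list(dupes)}")
        for out in OUTCOMES:
            if out in self.participants:
                vals = self.participants[out]
                if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"outcome {out} must be non-negative integer counts")

    def analysis_frame(self, test_label: str, group: str | None = None) -> pd.DataFrame:
        """Covariates + outcomes + that test's features, optionally one group."""
        df = self.participants.join(self.features[test_label], how="left")
        if group is not None:
            df = df[df["group"] == group]
        return df

    def to_csv_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index_label="participant_id")
        for label, df in self.features.items():
            df.to_csv(outdir / f"features_{label}.csv", index_label="participant_id")

    @classmethod
    def from_csv_dir(cls, indir: str | Path) -> "CohortTable":
        indir = Path(indir)
        participants = pd.read_csv(indir / "participants.csv", index_col="participant_id")
        features = {}
        for label in TEST_LABELS:
            path = indir / f"features_{label}.csv"
            if path.exists():
                features[label] = pd.read_csv(path, index_col="participant_id")
        return cls(participants, features)


def build_feature_table(
    recordings: dict[str, dict[str, dict[str, float]]],
    cohort: pd.DataFrame,
) -> CohortTable:
    """Attach per-test feature rows to a cohort of participants.

    ``recordings`` maps test label -> participant id -> feature dict.
    Participants with no usable recording for a test carry NaN for that test.
    Feature rows referencing unknown participants fail with the offending ids.
    """
    known = set(cohort.index)
    tables: dict[str, pd.DataFrame] = {}
    for label in TEST_LABELS:
        rows = recordings.get(label, {})
        ids = list(rows)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate participant id in {label} recordings")
        unknown = sorted(set(ids) - known)
        if unknown:
            raise ValueError(f"feature rows for unknown participants: {unknown}")
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
        tables[label] = df.reindex(cohort.index)
    return CohortTable(cohort.copy(), tables)


def correlation_matrix(
    table: CohortTable,
    test_label: str,
    group: str | None = None,
    include_outcomes: bool = False,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among the 19 features.

    Requires at least 3 complete cases overall.  Constant columns produce NaN
    rows/columns (their correlations are undefined).
    """
    df = table.analysis_frame(test_label, group)
    cols = list(FEATURE_NAMES) + (list(OUTCOMES) if include_outcomes else [])
    sub = df[[c for c in cols if c in df]]
    if sub.dropna(how="all").shape[0] < 3:
        raise ValueError("need at least 3 cases for a correlation matrix")
    corr = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class ForbiddenPairSet:
    """Unordered feature pairs barred from co-occurring in one model."""

    pairs: frozenset[frozenset[str]] = frozenset()

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a, b)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def allows(self, subset) -> bool:
        return not any(frozenset(p) <= set(subset) for p in self.pairs)

    def as_tuples(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.pairs)


def forbidden_pairs(
    matrices: dict[str, pd.DataFrame],
    threshold: float = 0.6,
) -> ForbiddenPairSet:
    """Pairs whose |r| strictly exceeds ``threshold`` in ALL supplied tests.

    An undefined (NaN) correlation in any matrix counts as not exceeding the
    threshold — the pair stays selectable — and is logged.
    """
    names = [n for n in FEATURE_NAMES if all(n in m.index for m in matrices.values())]
    banned: set[frozenset[str]] = set()
    for a, b in combinations(names, 2):
        rs = [m.loc[a, b] for m in matrices.values()]
        if any(np.isnan(r) for r in rs):
            log.info("undefined correlation for (%s, %s); pair stays selectable", a, b)
            continue
        if all(abs(r) > threshold for r in rs):
            banned.add(frozenset((a, b)))
    return ForbiddenPairSet(frozenset(banned))
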