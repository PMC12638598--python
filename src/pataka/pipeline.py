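"""End-to-end orchestration: simulate -> screen/denoise -> extract ->
assemble -> select -> classify, with reproducible CSV reports.

A run executes the full study design on a synthetic cohort: all 18
(group x outcome x DDK test) AICc selection runs and the 3 per-test ROC
comparisons, writing

* ``selection_report.csv`` — one row per selection run (the Table-3 shape:
  ΔAICc, significance, R²_N null/best/Δ, n),
* ``appearance_rates.csv`` — long-format per-feature candidate-set
  appearance rates for the significant runs (the Fig-4 shape),
* ``roc_report.csv`` — per-test AUCs and DeLong p,
* ``exclusions.log`` — one structured line per excluded recording,
* ``config.json`` — the exact configuration snapshot.

With ``synthesize_audio=True`` each (participant, test) recording is rendered
to audio, screened, denoised, normalized, and its features extracted by the
acoustic pipeline; otherwise the generator's ground-truth features are used
directly (fast path for statistical work).  A fixed seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .features import (
    FEATURE_NAMES, NULL_COVARIATES, OUTCOMES, CohortTable,
    correlation_matrix, extract_features, forbidden_pairs,
)
from .models import OUTCOME_FAMILY, exhaustive_selection
from .roc import compare_models
from .synth import CohortSpec, simulate_cohort, synthesize_ddk_recording
from .types import TEST_LABELS

log = logging.getLogger(__name__)

#: Default candidate features for the exhaustive stage.  A cross-section of
#: the six feature groups, small enough that the 18 runs stay desk-scale
#: (2^7 = 128 subsets before forbidden-pair pruning); the full 19 can be
#: requested explicitly.
DEFAULT_SELECTION_FEATURES = (
    "onset_count", "ioi_mean", "ioi_sd", "decrement_on_ioi",
    "speech_to_pause_ratio", "vot_mean", "onset_strength_cov",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 200
    group_fraction_sci: float = 0.3
    feature_effects: dict = field(default_factory=lambda: {
        "episodic_memory_errors": {"ioi_sd": 0.25, "ioi_mean": 0.15},
        "executive_strategy": {"ioi_mean": 0.2},
        "working_memory_errors": {"speech_to_pause_ratio": -0.2},
    })
    missing_recording_rate: float = 0.05
    synthesize_audio: bool = True
    denoise: bool = True
    min_duration: float = 2.0
    utterance_floor: float = 0.02
    correlation_threshold: float = 0.6
    selection_features: tuple = DEFAULT_SELECTION_FEATURES
    max_features: int = 19
    correlation_group: str | None = None   # None = pooled; or "HC"/"SCI"
    out_dir: str = "pataka_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selection_features"] = list(self.selection_features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "selection_features" in d:
            d["selection_features"] = tuple(d["selection_features"])
        return cls(**d)


def _extract_all(table: CohortTable, cfg: PipelineConfig, exclusions: list[str]) -> CohortTable:
    """Replace ground-truth features with acoustically extracted ones."""
    specs = table.truth["train_specs"]
    missing = table.truth["missing"]
    new_tables = {}
    for label in TEST_LABELS:
        rows = {}
        for pid in table.participants.index:
            if missing.loc[pid, label]:
                exclusions.append(f"{pid}\t{label}\tmissing_recording")
                continue
            rec, _ = synthesize_ddk_recording(specs[(pid, label)], label, pid)
            # cheap screens first; the utterance check reuses the one denoise pass
            outcome = pp.screen_recording(
                rec, min_duration=cfg.min_duration, utterance_check=False,
            )
            if not outcome.admitted:
                exclusions.append(f"{pid}\t{label}\t{outcome.reason}")
                continue
            clean = pp.resample(rec)
            if cfg.denoise:
                clean = pp.denoise(clean)
            if pp.active_fraction(clean) < cfg.utterance_floor:
                exclusions.append(f"{pid}\t{label}\tno_utterance")
                continue
            rows[pid] = extract_features(pp.normalize(clean))
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
        new_tables[label] = df.reindex(table.participants.index)
    return CohortTable(table.participants, new_tables, truth=table.truth)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report frames and writes CSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))

    spec = CohortSpec(
        n_participants=config.n_participants,
        group_fraction_sci=config.group_fraction_sci,
        feature_effects=config.feature_effects,
        missing_recording_rate=config.missing_recording_rate,
        seed=config.seed,
    )
    table = simulate_cohort(spec)
    exclusions: list[str] = []
    if config.synthesize_audio:
        table = _extract_all(table, config, exclusions)
    else:
        missing = table.truth["missing"]
        for label in TEST_LABELS:
            for pid in table.participants.index[missing[label]]:
                exclusions.append(f"{pid}\t{label}\tmissing_recording")
    table.to_csv_dir(out / "cohort")

    matrices = {
        label: correlation_matrix(table, label, group=config.correlation_group)
        for label in TEST_LABELS
    }
    for label, m in matrices.items():
        m.to_csv(out / f"correlations_{label}.csv")
    forbidden = forbidden_pairs(matrices, threshold=config.correlation_threshold)

    features = [f for f in config.selection_features]
    sel_rows, rate_rows = [], []
    for group in ("HC", "SCI"):
        for outcome in OUTCOMES:
            for label in TEST_LABELS:
                df = table.analysis_frame(label, group)
                try:
                    res = exhaustive_selection(
                        df, outcome, features, forbidden=forbidden,
                        family=OUTCOME_FAMILY[outcome], max_features=config.max_features,
                    )
                except (ValueError, RuntimeError) as exc:
                    # a cell with too few complete cases stays in the report
                    log.warning("selection failed for %s/%s/%s: %s", group, outcome, label, exc)
                    sel_rows.append({
                        "group": group, "outcome": outcome, "test": label,
                        "family": OUTCOME_FAMILY[outcome], "n": int(df.dropna().shape[0]),
                        "delta_aicc": np.nan, "significant": False,
                        "r2n_null": np.nan, "r2n_best": np.nan, "delta_r2n": np.nan,
                        "best_subset": "",
                    })
                    continue
                sel_rows.append({
                    "group": group, "outcome": outcome, "test": label,
                    "family": res.family, "n": res.n,
                    "delta_aicc": round(res.delta_aicc, 6),
                    "significant": res.significant,
                    "r2n_null": round(res.r2n_null, 6),
                    "r2n_best": round(res.r2n_best, 6),
                    "delta_r2n": round(res.delta_r2n, 6),
                    "best_subset": "+".join(sorted(res.best_subset)),
                })
                for feat, rate in sorted(res.appearance_rates.items()):
                    rate_rows.append({
                        "group": group, "outcome": outcome, "test": label,
                        "feature": feat, "appearance_rate": round(rate, 6),
                    })

    roc_rows = []
    for label in TEST_LABELS:
        df = table.analysis_frame(label)
        cmp = compare_models(df, "group", list(NULL_COVARIATES), list(FEATURE_NAMES))
        roc_rows.append({
            "test": label,
            "auc_null": round(cmp.auc_null, 6), "auc_full": round(cmp.auc_full, 6),
            "delong_statistic": round(cmp.delong_statistic, 6),
            "p_value": round(cmp.p_value, 8),
            "n_sci": cmp.n_cases, "n_hc": cmp.n_controls,
        })

    selection_report = pd.DataFrame(sel_rows)
    appearance_report = pd.DataFrame(
        rate_rows, columns=["group", "outcome", "test", "feature", "appearance_rate"]
    )
    roc_report = pd.DataFrame(roc_rows)
    selection_report.to_csv(out / "selection_report.csv", index=False)
    appearance_report.to_csv(out / "appearance_rates.csv", index=False)
    roc_report.to_csv(out / "roc_report.csv", index=False)
    (out / "exclusions.log").write_text(
        "".join(f"{line}\n" for line in exclusions)
    )
    return {
        "selection": selection_report,
        "appearance": appearance_report,
        "roc": roc_report,
        "forbidden_pairs": forbidden,
        "table": table,
        "exclusions": exclusions,
    }
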