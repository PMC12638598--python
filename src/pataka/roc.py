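"""HC-vs-SCI classification and paired ROC comparison.

The supplementary analysis asks whether motor-speech features improve
discrimination of self-reported subjective cognitive impairment from healthy
cognition beyond the demographic/clinical covariates.  Per DDK test, two
logistic regressions are fitted on the same participants — null covariates
only, and null covariates plus all 19 features — and their apparent
(in-sample) ROC curves are compared with the DeLong paired-AUC test, which
estimates the variance of the AUC difference from per-observation placement
values, so the correlation between the two curves is accounted for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

log = logging.getLogger(__name__)


@dataclass
class ROCComparison:
    auc_null: float
    auc_full: float
    delong_statistic: float
    p_value: float
    n_cases: int
    n_controls: int


def fit_logistic(df: pd.DataFrame, outcome: str, predictors: list[str]) -> np.ndarray:
    """ML logistic fit; returns in-sample predicted probabilities.

    Quasi-separation produces a warning but the terminal iterate's scores are
    still returned (their ranking, which is all ROC uses, is well defined).
    """
    y = df[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    if not res.converged:
        log.warning("logistic fit did not fully converge (possible separation); "
                    "using terminal iterate")
    return np.asarray(res.fittedvalues)


def auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Mann-Whitney AUC with half credit for ties, plus ROC curve points.

    Returns ``(auc, fpr, tpr)``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    value = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(value), fpr, tpr


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per case) and V01 (per control)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank-based placements handle ties with half credit
    order = np.concatenate([pos, neg])
    ranks = stats.rankdata(order)
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks[:m] - ranks_pos) / n          # P(score_case > score_control)
    v01 = 1.0 - (ranks[m:] - ranks_neg) / m
    theta = v10.mean()
    return v10, v01, float(theta)


def delong_compare(
    scores_null: np.ndarray,
    scores_full: np.ndarray,
    labels: np.ndarray,
) -> ROCComparison:
    """Paired DeLong test of AUC equality for two models on the same cases.

    Two-sided p from the normal reference; identical score vectors (zero
    variance of the difference) give statistic 0 and p = 1.
    """
    scores_null = np.asarray(scores_null, float)
    scores_full = np.asarray(scores_full, float)
    labels = np.asarray(labels)
    if scores_null.shape != scores_full.shape or len(labels) != len(scores_null):
        raise ValueError("both score vectors must cover the same participants")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((scores_null, scores_full)):
        v10[i], v01[i], aucs[i] = _placements(s, labels)
    s10 = np.cov(v10)     # 2x2 covariance of case placements
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[1] - aucs[0]
    if var_diff <= 1e-16:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return ROCComparison(
        auc_null=float(aucs[0]), auc_full=float(aucs[1]),
        delong_statistic=float(z), p_value=p, n_cases=m, n_controls=n,
    )


def compare_models(
    df: pd.DataFrame,
    group_col: str,
    null_covariates: list[str],
    features: list[str],
    positive: str = "SCI",
) -> ROCComparison:
    """Null-vs-(null + all features) paired ROC comparison on complete cases."""
    used = null_covariates + features
    cases = df.dropna(subset=used + [group_col])
    labels = (cases[group_col] == positive).astype(int).to_numpy()
    cases = cases.assign(_label=labels)
    s_null = fit_logistic(cases, "_label", null_covariates)
    s_full = fit_logistic(cases, "_label", used)
    return delong_compare(s_null, s_full, labels)
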