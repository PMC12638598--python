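"""Count-GLM model selection: does adding motor-speech features beat the
null covariate model?

For each (group, outcome, DDK test) the analysis fits the null model (age,
sex, education, psychiatric flag, HADS anxiety/depression) and the null model
plus every subset of candidate features that contains no forbidden
(collinear) pair — no interaction terms.  Outcome families are count GLMs
with a log link: Poisson for the executive-strategy score, negative binomial
(NB2, dispersion estimated by maximum likelihood) for the episodic- and
working-memory error counts.  Models are ranked by the small-sample-corrected
Akaike criterion

    AIC  = 2k - 2 logL
    AICc = AIC + 2k(k+1) / (n - k - 1)

with k counting the intercept, the slopes and (for NB) the dispersion
parameter.  The feature set "significantly" improves fit when
``AICc_null - AICc_best > 2``.  Nagelkerke's pseudo-R² is reported as the
variance-explained estimate, and the candidate set (models within 2 AICc of
the best among those beating the null by > 2) yields per-feature appearance
rates.

The complete-case set is fixed per selection run across all subsets (rows
missing any candidate feature are dropped), so every AICc is computed on the
same n and the values are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .features import NULL_COVARIATES, ForbiddenPairSet

log = logging.getLogger(__name__)

FAMILIES = ("poisson", "negative_binomial")

#: family used for each outcome (overdispersed error counts -> NB)
OUTCOME_FAMILY = {
    "episodic_memory_errors": "negative_binomial",
    "executive_strategy": "poisson",
    "working_memory_errors": "negative_binomial",
}


@dataclass
class CountModelFit:
    family: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    dispersion: float | None      # NB size theta (= 1/alpha); None for Poisson
    log_likelihood: float
    k: int
    n: int
    aicc: float
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.log_likelihood


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC; requires ``n > k + 1``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    aic = 2 * k - 2 * log_likelihood
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    return X


def fit_count_glm(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    family: str,
) -> CountModelFit:
    """Maximum-likelihood log-link count GLM on complete cases of ``df``.

    ``df`` must already be restricted to the analysis cases (no NaNs in the
    used columns).  Non-convergence or numerical failure returns a fit
    flagged ``converged=False`` which selection excludes from ranking.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    y = df[outcome].to_numpy(float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("outcome must be non-negative integer counts")
    X = _design(df, predictors)
    n, p = X.shape
    k = p + (1 if family == "negative_binomial" else 0)
    if n < k + 2:
        raise ValueError(f"too few complete cases (n={n}) for k={k}")
    names = ["intercept"] + list(predictors)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "poisson":
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-10)
                llf = float(res.llf)
                params = dict(zip(names, res.params))
                disp = None
                conv = bool(res.converged)
            else:
                pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
                llf, params, disp, conv = _fit_negative_binomial(y, X, names, pois)
        if not np.isfinite(llf):
            raise FloatingPointError("non-finite log-likelihood")
    except Exception as exc:  # separation / non-convergence
        log.warning("count GLM failed (%s ~ %s, %s): %s", outcome, predictors, family, exc)
        return CountModelFit(family, tuple(predictors), {}, None, -np.inf, k, n,
                             np.inf, converged=False)
    return CountModelFit(
        family, tuple(predictors), params, disp, llf, k, n, aicc(llf, k, n), converged=conv
    )


def _fit_negative_binomial(y, X, names, poisson_res):
    """NB2 maximum likelihood with a boundary fallback.

    When the data are equidispersed the dispersion MLE sits at the boundary
    alpha -> 0, where the NB likelihood degenerates to the Poisson one and
    Newton steps fail; in that case the Poisson fit supplies the supremum
    log-likelihood and the dispersion is reported as infinite.
    """
    mod = NegativeBinomial(y, X, loglike_method="nb2")
    start = np.append(np.asarray(poisson_res.params), 0.1)
    res = None
    for method in ("newton", "bfgs"):
        try:
            cand = mod.fit(start_params=start, method=method, maxiter=200, disp=0)
            if np.isfinite(cand.llf) and cand.params[-1] > 0:
                res = cand
                break
        except Exception:
            continue
    p_llf = float(poisson_res.llf)
    if res is None or res.llf <= p_llf + 1e-8 or res.params[-1] < 1e-6:
        # boundary case: alpha -> 0, no real improvement over equidispersion
        params = dict(zip(names, poisson_res.params))
        return p_llf, params, np.inf, bool(poisson_res.converged)
    params = dict(zip(names, res.params[:-1]))
    alpha = float(res.params[-1])
    disp = 1.0 / alpha if alpha > 0 else np.inf
    conv = bool(res.mle_retvals.get("converged", True))
    return float(res.llf), params, disp, conv


def nagelkerke_r2(fit: CountModelFit, null_fit: CountModelFit) -> float:
    """Nagelkerke pseudo-R² in percent.

    R²_CS = 1 - exp((2/n)(logL0 - logL1)); R²_N = R²_CS / (1 - exp((2/n) logL0)).
    A value below zero (possible only if the fits are not nested ML fits on
    the same cases) is reported as-is with a warning.
    """
    if fit.n != null_fit.n:
        raise ValueError("fits must be computed on the same cases")
    n = fit.n
    ll1, ll0 = fit.log_likelihood, null_fit.log_likelihood
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    denom = 1.0 - np.exp((2.0 / n) * ll0)
    value = 100.0 * r2_cs / denom
    if value < 0:
        log.warning("negative Nagelkerke R² (%.3g): logL1 < logL0", value)
    return float(value)


@dataclass
class SelectionResult:
    """Outcome of one exhaustive AICc subset search."""

    outcome: str
    family: str
    null_fit: CountModelFit
    fits: dict[frozenset, CountModelFit]          # feature subset -> fit
    best_subset: frozenset
    delta_aicc: float                             # AICc_null - AICc_best
    significant: bool                             # delta_aicc > 2
    r2n_null: float
    r2n_best: float
    delta_r2n: float
    candidate_set: list[frozenset] = field(default_factory=list)
    appearance_rates: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def ranking(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(sorted(s)) or "(null)", "aicc": f.aicc,
             "k": f.k, "log_likelihood": f.log_likelihood}
            for s, f in self.fits.items()
        ]
        return pd.DataFrame(rows).sort_values("aicc", ignore_index=True)


def _admissible_subsets(features: list[str], forbidden: ForbiddenPairSet):
    for r in range(len(features) + 1):
        for combo in combinations(features, r):
            if forbidden.allows(combo):
                yield frozenset(combo)


def exhaustive_selection(
    df: pd.DataFrame,
    outcome: str,
    features: list[str],
    forbidden: ForbiddenPairSet | None = None,
    family: str | None = None,
    null_covariates: list[str] | None = None,
    max_features: int = 19,
) -> SelectionResult:
    """Evaluate the null model and every admissible feature subset by AICc.

    ``df`` carries the covariates, outcome, and feature columns for one
    (group, test) analysis; rows missing the outcome, any null covariate or
    any candidate feature are dropped once, so all fits share the same n.
    """
    forbidden = forbidden or ForbiddenPairSet()
    family = family or OUTCOME_FAMILY[outcome]
    null_covariates = list(NULL_COVARIATES if null_covariates is None else null_covariates)
    if len(features) > max_features:
        raise ValueError(f"{len(features)} features exceeds the cap of {max_features}")
    used = [outcome] + null_covariates + list(features)
    cases = df.dropna(subset=used)
    n = len(cases)

    null_fit = fit_count_glm(cases, outcome, null_covariates, family)
    if not null_fit.converged:
        raise RuntimeError(f"null model failed to converge for {outcome}")
    # intercept-only baseline: the reference against which R²_N is reported
    base_fit = fit_count_glm(cases, outcome, [], family)

    fits: dict[frozenset, CountModelFit] = {}
    for subset in _admissible_subsets(sorted(features), forbidden):
        if not subset:
            fits[subset] = null_fit
            continue
        preds = null_covariates + sorted(subset)
        try:
            fits[subset] = fit_count_glm(cases, outcome, preds, family)
        except ValueError as exc:
            # subset too large for the case count: unrankable, not fatal
            log.warning("subset %s unrankable for %s: %s", sorted(subset), outcome, exc)
            k_sub = len(preds) + 1 + (1 if family == "negative_binomial" else 0)
            fits[subset] = CountModelFit(family, tuple(preds), {}, None, -np.inf,
                                         k_sub, n, np.inf, converged=False)

    ranked = [(s, f) for s, f in fits.items() if f.converged]
    if all(s == frozenset() for s, _ in ranked):
        log.warning("all feature models failed to converge for %s; null reported as best", outcome)
    best_subset, best_fit = min(ranked, key=lambda item: (item[1].aicc, len(item[0])))
    delta = null_fit.aicc - best_fit.aicc
    significant = bool(delta > 2.0) and len(best_subset) > 0

    r2n_null = nagelkerke_r2(null_fit, base_fit)
    r2n_best = nagelkerke_r2(best_fit, base_fit)

    candidate_set: list[frozenset] = []
    if significant:
        for s, f in ranked:
            if not s:
                continue
            if null_fit.aicc - f.aicc > 2.0 and f.aicc - best_fit.aicc < 2.0:
                candidate_set.append(s)
    rates = appearance_rates_from_candidates(candidate_set, features)
    return SelectionResult(
        outcome=outcome, family=family, null_fit=null_fit, fits=fits,
        best_subset=best_subset, delta_aicc=float(delta), significant=significant,
        r2n_null=r2n_null, r2n_best=r2n_best, delta_r2n=r2n_best - r2n_null,
        candidate_set=candidate_set, appearance_rates=rates, n=n,
    )


def appearance_rates_from_candidates(
    candidate_set: list[frozenset], features: list[str]
) -> dict[str, float]:
    if not candidate_set:
        return {}
    return {
        f: sum(f in s for s in candidate_set) / len(candidate_set)
        for f in features
    }


def appearance_rates(result: SelectionResult) -> dict[str, float]:
    """Fraction of candidate-set models containing each feature.

    Empty for a non-significant result.
    """
    if not result.significant:
        return {}
    return dict(result.appearance_rates)
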