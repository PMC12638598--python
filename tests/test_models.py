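"""Count GLM fitting, AICc, Nagelkerke R², and exhaustive subset selection.

The independent oracle used here maximizes the Poisson / negative-binomial
log-likelihoods directly with scipy.optimize, without touching the package's
fitting path.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from pataka import aicc, appearance_rates, exhaustive_selection, fit_count_glm, nagelkerke_r2
from pataka.features import ForbiddenPairSet


# ------------------------------------------------------------------ oracles
def poisson_loglik(beta, y, X):
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def oracle_poisson_fit(y, X):
    """Direct likelihood maximization, independent of the package path."""
    beta0 = np.zeros(X.shape[1]); beta0[0] = np.log(max(y.mean(), 0.1))
    res = minimize(lambda b: -poisson_loglik(b, y, X), beta0, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x, poisson_loglik(res.x, y, X)


def nb2_loglik(params, y, X):
    beta, alpha = params[:-1], params[-1]
    if alpha <= 0:
        return -np.inf
    mu = np.exp(X @ beta)
    size = 1.0 / alpha
    return float(np.sum(
        gammaln(y + size) - gammaln(size) - gammaln(y + 1)
        + size * np.log(size / (size + mu)) + y * np.log(mu / (size + mu))
    ))


def _sim_poisson(n=400, beta=(1.0, 0.3), seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.poisson(np.exp(beta[0] + beta[1] * x))
    return pd.DataFrame({"y": y, "x": x})


class TestFitCountGlm:
    def test_intercept_only_poisson_recovers_sample_mean(self):
        df = pd.DataFrame({"y": [1, 2, 3]})
        fit = fit_count_glm(df, "y", [], "poisson")
        assert np.exp(fit.coefficients["intercept"]) == pytest.approx(2.0, abs=1e-8)

    def test_slope_recovery_poisson(self):
        df = _sim_poisson(n=2000, seed=1)
        fit = fit_count_glm(df, "y", ["x"], "poisson")
        assert fit.coefficients["x"] == pytest.approx(0.30, abs=0.05)

    def test_poisson_llf_matches_oracle(self):
        df = _sim_poisson(seed=2)
        fit = fit_count_glm(df, "y", ["x"], "poisson")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        _, ll = oracle_poisson_fit(df["y"].to_numpy(float), X)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6)

    def test_nb_on_poisson_data_has_small_alpha(self):
        df = _sim_poisson(n=3000, seed=3)
        fit = fit_count_glm(df, "y", ["x"], "negative_binomial")
        assert fit.dispersion > 20  # theta -> infinity == Poisson limit

    def test_nb_llf_at_least_poisson_llf(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        mu = np.exp(1.0 + 0.3 * x)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        df = pd.DataFrame({"y": y, "x": x})
        nb = fit_count_glm(df, "y", ["x"], "negative_binomial")
        po = fit_count_glm(df, "y", ["x"], "poisson")
        assert nb.log_likelihood >= po.log_likelihood
        # NB llf agrees with the hand-written likelihood at its own params
        X = np.column_stack([np.ones(len(df)), x])
        params = np.array([nb.coefficients["intercept"], nb.coefficients["x"],
                           1.0 / nb.dispersion])
        assert nb2_loglik(params, y, X) == pytest.approx(nb.log_likelihood, abs=1e-6)

    def test_k_counts_nb_dispersion(self):
        df = _sim_poisson(seed=5)
        po = fit_count_glm(df, "y", ["x"], "poisson")
        nb = fit_count_glm(df, "y", ["x"], "negative_binomial")
        assert po.k == 2 and nb.k == 3

    def test_non_integer_outcome_rejected(self):
        df = pd.DataFrame({"y": [0.5, 1.2, 2.0]})
        with pytest.raises(ValueError):
            fit_count_glm(df, "y", [], "poisson")


class TestAicc:
    def test_hand_evaluated_formula(self):
        # AIC = 2*1 - 2*(-4.326) = 10.652; correction 2*1*2/(3-1-1) = 4
        assert aicc(-4.326, 1, 3) == pytest.approx(14.652, abs=1e-9)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(-100.0, 3, 10**9) == pytest.approx(2 * 3 + 200.0, abs=1e-6)

    def test_penalty_monotone_in_k(self):
        assert aicc(-50.0, 3, 100) > aicc(-50.0, 2, 100)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-10.0, 5, 6)

    def test_aicc_at_least_aic(self):
        fit = fit_count_glm(_sim_poisson(seed=6), "y", ["x"], "poisson")
        assert fit.aicc >= fit.aic


class TestNagelkerke:
    def test_zero_when_no_improvement(self):
        fit = fit_count_glm(_sim_poisson(seed=7), "y", [], "poisson")
        assert nagelkerke_r2(fit, fit) == pytest.approx(0.0, abs=1e-12)

    def test_saturated_binary_fit_is_100(self):
        # closed-form: logL1 = 0 for a perfect fit; formula collapses to 100
        n = 20
        ll0 = n * np.log(0.5)
        r2_cs = 1 - np.exp((2 / n) * (ll0 - 0.0))
        assert 100 * r2_cs / (1 - np.exp((2 / n) * ll0)) == pytest.approx(100.0)

    def test_matches_independent_oracle(self):
        df = _sim_poisson(n=20, seed=8)
        X0 = np.ones((len(df), 1))
        X1 = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["y"].to_numpy(float)
        _, ll0 = oracle_poisson_fit(y, X0)
        _, ll1 = oracle_poisson_fit(y, X1)
        n = len(df)
        expected = 100 * (1 - np.exp((2 / n) * (ll0 - ll1))) / (1 - np.exp((2 / n) * ll0))
        fit0 = fit_count_glm(df, "y", [], "poisson")
        fit1 = fit_count_glm(df, "y", ["x"], "poisson")
        assert nagelkerke_r2(fit1, fit0) == pytest.approx(expected, abs=1e-8)


def _selection_frame(n=300, seed=9, n_features=3, effect=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.standard_normal((n, n_features)),
                      columns=[f"f{i}" for i in range(n_features)])
    df["age"] = rng.normal(67, 7, n)
    eta = 1.0 + 0.01 * (df["age"] - 67) + effect * df["f0"]
    df["y"] = rng.poisson(np.exp(eta))
    return df


class TestExhaustiveSelection:
    def test_forbidden_pair_constrains_enumeration(self):
        df = _selection_frame()
        fp = ForbiddenPairSet(frozenset({frozenset(("f0", "f1"))}))
        res = exhaustive_selection(df, "y", ["f0", "f1", "f2"], forbidden=fp,
                                   family="poisson", null_covariates=["age"])
        subsets = set(res.fits)
        expected = {frozenset(), frozenset({"f0"}), frozenset({"f1"}), frozenset({"f2"}),
                    frozenset({"f0", "f2"}), frozenset({"f1", "f2"})}
        assert subsets == expected

    def test_result_invariant_to_feature_order(self):
        df = _selection_frame(seed=10)
        a = exhaustive_selection(df, "y", ["f0", "f1", "f2"], family="poisson",
                                 null_covariates=["age"])
        b = exhaustive_selection(df, "y", ["f2", "f0", "f1"], family="poisson",
                                 null_covariates=["age"])
        assert a.best_subset == b.best_subset
        assert a.delta_aicc == pytest.approx(b.delta_aicc, abs=1e-10)

    def test_planted_effect_detected(self):
        df = _selection_frame(n=800, seed=11, effect=0.3)
        res = exhaustive_selection(df, "y", ["f0", "f1", "f2"], family="poisson",
                                   null_covariates=["age"])
        assert res.significant
        assert "f0" in res.best_subset
        assert res.appearance_rates["f0"] == 1.0

    def test_nested_loglik_monotone(self):
        df = _selection_frame(seed=12)
        res = exhaustive_selection(df, "y", ["f0", "f1"], family="poisson",
                                   null_covariates=["age"])
        ll = {s: f.log_likelihood for s, f in res.fits.items()}
        for s, l in ll.items():
            for t, m in ll.items():
                if s < t:
                    assert m >= l - 1e-6

    def test_candidate_set_empty_iff_not_significant(self):
        df = _selection_frame(seed=13, effect=0.0)
        res = exhaustive_selection(df, "y", ["f0", "f1"], family="poisson",
                                   null_covariates=["age"])
        assert res.significant == bool(res.candidate_set)
        assert appearance_rates(res) == ({} if not res.significant else res.appearance_rates)

    def test_fixed_complete_cases_across_subsets(self):
        df = _selection_frame(seed=14)
        df.loc[:20, "f1"] = np.nan
        res = exhaustive_selection(df, "y", ["f0", "f1"], family="poisson",
                                   null_covariates=["age"])
        ns = {f.n for f in res.fits.values()}
        assert ns == {len(df) - 21}

    def test_feature_cap_enforced(self):
        df = _selection_frame()
        with pytest.raises(ValueError, match="cap"):
            exhaustive_selection(df, "y", ["f0", "f1", "f2"], family="poisson",
                                 null_covariates=["age"], max_features=2)


class TestAppearanceRates:
    def test_counting(self):
        from pataka.models import appearance_rates_from_candidates

        rates = appearance_rates_from_candidates(
            [frozenset({"A"}), frozenset({"A", "B"})], ["A", "B", "C"]
        )
        assert rates == {"A": 1.0, "B": 0.5, "C": 0.0}
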