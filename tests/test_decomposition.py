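"""Dissimilarity index and Shapley decomposition: worked values, axiom
checks, the permutation oracle and the specification ladder."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bmineq import (ConfigurationError, EstimationError, FactorSet,
                    SyntheticConfig, bic, decomposition_pvalues,
                    dissimilarity_index, fit_outcome_model,
                    generate_population, shapley_decompose,
                    specification_factors, specification_ladder)


class TestOutcomeModel:
    def test_empty_factor_set_returns_prevalence(self, responders_weighted):
        t = responders_weighted
        p, ll, k = fit_outcome_model(t, (), "excess_weight")
        assert k == 1
        np.testing.assert_allclose(p, t["excess_weight"].mean(), atol=1e-12)

    def test_single_binary_factor_is_saturated(self, responders_weighted):
        t = responders_weighted
        p, _, _ = fit_outcome_model(t, ("limiting_illness",), "excess_weight")
        for lv in (0, 1):
            mask = t["limiting_illness"] == lv
            np.testing.assert_allclose(p[mask.to_numpy()],
                                       t.loc[mask, "excess_weight"].mean(),
                                       atol=1e-7)

    def test_nesting_never_decreases_loglik(self, responders_weighted):
        t = responders_weighted
        _, ll1, _ = fit_outcome_model(t, ("imd_quintile",), "excess_weight")
        _, ll2, _ = fit_outcome_model(t, ("imd_quintile", "age_group"), "excess_weight")
        assert ll2 >= ll1 - 1e-6

    def test_matches_statsmodels_glm(self, responders_weighted):
        # independent reference fit of the same weighted logistic model
        t = responders_weighted.head(3000)
        w = np.random.default_rng(3).uniform(0.5, 2.0, len(t))
        factors = ("imd_quintile", "gender", "age_group")
        p, ll, k = fit_outcome_model(t, factors, "excess_weight", weights=w)
        X = pd.get_dummies(t[list(factors)].astype("category"), drop_first=True,
                           dtype=float)
        X = sm.add_constant(X)
        ref = sm.GLM(t["excess_weight"].to_numpy(), X,
                     family=sm.families.Binomial(), var_weights=w).fit()
        np.testing.assert_allclose(p, ref.fittedvalues, atol=1e-6)
        assert k == X.shape[1]


class TestDissimilarityIndex:
    def test_equal_probabilities_zero(self):
        assert dissimilarity_index(np.full(5, 0.3), np.ones(5)) == 0.0

    def test_two_group_hand_value(self):
        p = np.array([0.2, 0.6])
        assert dissimilarity_index(p, np.ones(2)) == pytest.approx(0.25)

    def test_upper_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.random(30)
            w = rng.uniform(0.2, 3.0, 30)
            pbar = np.sum(w * p) / w.sum()
            assert dissimilarity_index(p, w) < 1 - pbar + 1e-12

    def test_zero_prevalence_rejected(self):
        with pytest.raises(EstimationError):
            dissimilarity_index(np.zeros(3), np.ones(3))


class TestBIC:
    def test_worked_value(self):
        assert bic(-100.0, 3, 1000) == pytest.approx(3 * math.log(1000) + 200)

    def test_zero_params(self):
        assert bic(-50.0, 0, 10) == 100.0

    def test_noise_factor_usually_raises_bic(self):
        worse = 0
        for k in range(20):
            cfg = SyntheticConfig.hse_default(
                n_individuals=2000, seed=300 + k, quota_distortion=None,
                bmi_effects={"imd_quintile": 0.5 * np.arange(5)})
            t = generate_population(cfg)
            _, ll1, k1 = fit_outcome_model(t, ("imd_quintile",), "excess_weight")
            _, ll2, k2 = fit_outcome_model(t, ("imd_quintile", "marital_status"),
                                           "excess_weight")
            # marital status has a (near-)null BMI effect in this config
            worse += bic(ll2, k2, len(t)) > bic(ll1, k1, len(t))
        assert worse >= 14


def _permutation_shapley(table, factors, outcome, w):
    """Oracle: average marginal DI contribution over all m! orderings."""
    di = {}
    for size in range(len(factors) + 1):
        for s in itertools.combinations(factors, size):
            p, _, _ = fit_outcome_model(table, s, outcome, weights=w)
            di[frozenset(s)] = dissimilarity_index(p, w) if s else 0.0
    vals = {f: 0.0 for f in factors}
    perms = list(itertools.permutations(factors))
    for perm in perms:
        seen = frozenset()
        for f in perm:
            vals[f] += di[seen | {f}] - di[seen]
            seen = seen | {f}
    return {f: v / len(perms) for f, v in vals.items()}


class TestShapley:
    def test_single_factor_equals_full_di(self, responders_weighted):
        t = responders_weighted
        res = shapley_decompose(t, ("imd_quintile",), "excess_weight")
        assert res.shapley_values["imd_quintile"] == pytest.approx(res.di, abs=1e-12)

    def test_efficiency_sum_equals_di(self, responders_weighted):
        res = shapley_decompose(responders_weighted,
                                ("imd_quintile", "gender", "age_group"),
                                "excess_weight")
        assert sum(res.shapley_values.values()) == pytest.approx(res.di, abs=1e-8)
        assert sum(res.contrib_percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_exchangeable_copies_get_equal_values(self, responders_weighted):
        t = responders_weighted.copy()
        t["education"] = t["imd_quintile"]  # identical copy under another name
        res = shapley_decompose(t, ("imd_quintile", "education", "gender"),
                                "excess_weight")
        assert res.shapley_values["imd_quintile"] == pytest.approx(
            res.shapley_values["education"], abs=1e-10)

    def test_matches_permutation_oracle_m4(self, responders_weighted):
        t = responders_weighted.head(2500)
        factors = ("imd_quintile", "gender", "age_group", "limiting_illness")
        w = np.ones(len(t))
        res = shapley_decompose(t, factors, "excess_weight", weights=w)
        oracle = _permutation_shapley(t, factors, "excess_weight", w)
        for f in factors:
            assert res.shapley_values[f] == pytest.approx(oracle[f], abs=1e-10)

    def test_single_level_factor_rejected(self, responders_weighted):
        t = responders_weighted.copy()
        t["urbanicity"] = 1
        with pytest.raises(EstimationError, match="urbanicity"):
            shapley_decompose(t, ("imd_quintile", "urbanicity"), "excess_weight")

    def test_too_many_factors_refused(self, responders_weighted):
        fake = tuple(f"f{i}" for i in range(13))
        with pytest.raises(ConfigurationError, match="12"):
            shapley_decompose(responders_weighted, fake, "excess_weight")

    def test_duplicate_factors_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            FactorSet(("gender", "gender"))


class TestPvalues:
    def test_dominant_factor_significant_noise_factor_not(self):
        cfg = SyntheticConfig.hse_default(n_individuals=4000, seed=77,
                                          quota_distortion=None)
        t = generate_population(cfg)
        ps, ses = decomposition_pvalues(
            t, ("imd_quintile", "age_group", "marital_status"), "excess_weight",
            reps=100, seed=5)
        assert ps["imd_quintile"] < 0.01
        assert ps["age_group"] < 0.01
        assert ps["marital_status"] > ps["imd_quintile"]

    def test_minimum_reps_enforced(self, responders_weighted):
        with pytest.raises(ConfigurationError):
            decomposition_pvalues(responders_weighted, ("gender",),
                                  "excess_weight", reps=50)


class TestLadder:
    def test_specifications_are_nested(self):
        specs = specification_factors("occupation")
        assert set(specs[1].factors) < set(specs[2].factors) < set(specs[3].factors)
        assert "occupation" in specs[1].factors
        assert set(specs[3].factors) >= {"imd_quintile", "education", "occupation"}

    def test_missing_covariate_named(self, responders_weighted):
        t = responders_weighted.drop(columns=["urbanicity"])
        with pytest.raises(ConfigurationError, match="urbanicity"):
            specification_ladder(t, "excess_weight", "imd_quintile")

    def test_illness_dominates_when_it_drives_outcome(self):
        cfg = SyntheticConfig.hse_default(
            n_individuals=5000, seed=31, quota_distortion=None,
            bmi_effects={"limiting_illness": np.array([0.0, 5.0]),
                         "imd_quintile": 0.2 * np.arange(5)})
        t = generate_population(cfg)
        results, bic_df = specification_ladder(t, "excess_weight", "imd_quintile")
        r2 = results[2]
        spec1_factors = results[1].factors
        illness = r2.contrib_percent["limiting_illness"]
        assert all(illness > r2.contrib_percent[f] for f in spec1_factors)
        assert list(bic_df["specification"]) == [1, 2, 3]
        # richer specifications spread the fitted probabilities further
        assert results[3].di >= results[1].di - 1e-6
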