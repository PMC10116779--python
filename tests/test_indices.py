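"""Fractional ranks and concentration indices: worked values, invariants
(hypothesis) and inference calibration cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmineq import (ConfigurationError, EstimationError, RankedVector,
                    SyntheticConfig, cci_inference, erreygers_cci,
                    estimate_index, generate_population, ground_truth,
                    wagstaff_ci, weighted_cov, weighted_fractional_rank)


class TestRanks:
    def test_five_equal_singletons(self):
        r = weighted_fractional_rank(np.array([5, 4, 3, 2, 1]), np.ones(5))
        np.testing.assert_allclose(r, [0.1, 0.3, 0.5, 0.7, 0.9])

    def test_single_category_all_half(self):
        r = weighted_fractional_rank(np.array([2, 2, 2]), np.ones(3))
        np.testing.assert_allclose(r, 0.5)

    def test_weighted_three_categories(self):
        levels = np.array([3, 2, 1])
        w = np.array([0.25, 0.50, 0.25])
        np.testing.assert_allclose(weighted_fractional_rank(levels, w),
                                   [0.125, 0.5, 0.875])

    def test_unknown_level_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            weighted_fractional_rank(np.array([1, 9]), np.ones(2), order=[2, 1])

    def test_weighted_mean_rank_is_half(self):
        rng = np.random.default_rng(0)
        levels = rng.integers(1, 6, 200)
        w = rng.uniform(0.1, 3.0, 200)
        r = weighted_fractional_rank(levels, w)
        assert np.sum(w * r) / w.sum() == pytest.approx(0.5, abs=1e-12)


class TestCovariance:
    def test_constant_outcome_zero(self):
        assert weighted_cov(np.ones(4), np.linspace(0.1, 0.9, 4), np.ones(4)) == 0.0

    def test_hand_value(self):
        assert weighted_cov(np.array([1.0, 0.0]), np.array([0.25, 0.75]),
                            np.ones(2)) == pytest.approx(-0.125)

    def test_reduces_to_unweighted(self):
        rng = np.random.default_rng(1)
        y, r = rng.random(50), rng.random(50)
        expected = np.cov(y, r, bias=True)[0, 1]
        assert weighted_cov(y, r, np.full(50, 2.5)) == pytest.approx(expected, rel=1e-12)

    def test_too_few_records(self):
        with pytest.raises(EstimationError):
            weighted_cov(np.array([1.0]), np.array([0.5]), np.array([1.0]))


def _binary_vector(y, levels, w=None):
    n = len(y)
    w = np.ones(n) if w is None else np.asarray(w, float)
    return RankedVector.from_levels(np.asarray(y, float), np.asarray(levels), w)


class TestErreygers:
    def test_constant_outcome_is_zero(self):
        v = _binary_vector([1, 1, 1, 1], [4, 3, 2, 1])
        assert erreygers_cci(v).value == 0.0

    def test_perfect_pro_deprived_concentration_is_minus_one(self):
        v = _binary_vector([1, 1, 0, 0], [2, 2, 1, 1])
        assert erreygers_cci(v).value == pytest.approx(-1.0, abs=1e-14)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            RankedVector(y=np.zeros(2), w=np.ones(2), r=np.array([0.25, 0.75]),
                         a=1.0, b=1.0)

    def test_wagstaff_same_sign_and_binary_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            levels = rng.integers(1, 6, 300)
            y = (rng.random(300) < 0.2 + 0.1 * levels).astype(float)
            if y.std() == 0:
                continue
            w = rng.uniform(0.5, 2.0, 300)
            v = _binary_vector(y, levels, w)
            e = erreygers_cci(v).value
            wag = wagstaff_ci(v).value
            mu = v.mu
            assert e == pytest.approx(4 * mu * (1 - mu) * wag, abs=1e-12)
            assert np.sign(e) == np.sign(wag) or e == 0

    def test_wagstaff_undefined_at_bound(self):
        v = _binary_vector([0, 0, 0], [3, 2, 1])
        with pytest.raises(EstimationError):
            wagstaff_ci(v)


@st.composite
def _ranked_instance(draw):
    n = draw(st.integers(3, 40))
    levels = draw(st.lists(st.integers(1, 6), min_size=n, max_size=n))
    y = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    w = draw(st.lists(st.floats(0.25, 4.0, allow_nan=False), min_size=n, max_size=n))
    return np.array(y, float), np.array(levels), np.array(w)


class TestInvariants:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(_ranked_instance())
    def test_mirror_symmetry(self, inst):
        # reversing the deprivation order flips the index sign exactly
        y, levels, w = inst
        v1 = RankedVector.from_levels(y, levels, w, order=[6, 5, 4, 3, 2, 1])
        v2 = RankedVector.from_levels(y, levels, w, order=[1, 2, 3, 4, 5, 6])
        assert erreygers_cci(v1).value == pytest.approx(-erreygers_cci(v2).value,
                                                        abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(_ranked_instance(), st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    def test_affine_invariance_of_erreygers(self, inst, alpha, beta):
        y, levels, w = inst
        v1 = RankedVector.from_levels(y, levels, w, bounds=(0.0, 1.0))
        v2 = RankedVector.from_levels(alpha * y + beta, levels, w,
                                      bounds=(beta, alpha + beta))
        assert erreygers_cci(v1).value == pytest.approx(erreygers_cci(v2).value,
                                                        rel=1e-9, abs=1e-11)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(_ranked_instance())
    def test_weight_replication_equals_doubling(self, inst):
        y, levels, w = inst
        w2 = w.copy()
        w2[0] *= 2.0
        y_dup = np.concatenate([y, [y[0]]])
        levels_dup = np.concatenate([levels, [levels[0]]])
        w_dup = np.concatenate([w, [w[0]]])
        v_doubled = RankedVector.from_levels(y, levels, w2)
        v_dup = RankedVector.from_levels(y_dup, levels_dup, w_dup)
        assert erreygers_cci(v_doubled).value == pytest.approx(
            erreygers_cci(v_dup).value, abs=1e-12)


class TestInference:
    def test_bootstrap_close_to_delta_se(self):
        cfg = SyntheticConfig.hse_default(n_individuals=5000, seed=17,
                                          quota_distortion=None)
        t = generate_population(cfg)
        v = RankedVector.from_levels(t["excess_weight"].to_numpy(),
                                     t["imd_quintile"].to_numpy(),
                                     np.ones(len(t)))
        se_b, _ = cci_inference(v, reps=1000, seed=11)
        se_d, _ = cci_inference(v, method="delta")
        assert abs(se_b - se_d) / se_d < 0.15

    def test_power_against_strong_gradient(self):
        # logistic IMD gradient with true Erreygers index around -0.3
        bg = {"intercept": -1.8, "effects": {"imd_quintile": 0.9 * np.arange(5)}}
        cfg0 = SyntheticConfig(n_individuals=2000, seed=0, binary_gradient=bg)
        truth = ground_truth(cfg0).cci[("excess_weight", "imd_quintile")]
        assert truth < -0.25
        hits = 0
        for k in range(30):
            t = generate_population(SyntheticConfig(n_individuals=2000, seed=100 + k,
                                                    binary_gradient=bg))
            est = estimate_index(t["excess_weight"].to_numpy(),
                                 t["imd_quintile"].to_numpy(), np.ones(len(t)),
                                 reps=200, seed=np.random.SeedSequence([4, k]))
            hits += est.p_value < 0.05
        assert hits / 30 > 0.95

    def test_small_rep_warning_and_degenerate_error(self):
        rng = np.random.default_rng(2)
        levels = rng.integers(1, 6, 100)
        y = (rng.random(100) < 0.5).astype(float)
        v = RankedVector.from_levels(y, levels, np.ones(100))
        with pytest.warns(UserWarning, match="50"):
            cci_inference(v, reps=40, seed=0)
        v_const = RankedVector.from_levels(np.ones(100), levels, np.ones(100))
        with pytest.raises(EstimationError):
            cci_inference(v_const, reps=100, seed=0)

    def test_inference_requires_minimum_n(self):
        v = _binary_vector([1, 0, 1, 0], [2, 1, 2, 1])
        with pytest.raises(EstimationError, match="30"):
            cci_inference(v)
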