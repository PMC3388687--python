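"""Concordance, R-squared, Hosmer-Lemeshow, VIF and split-half checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutric import c_index, compare_models, hosmer_lemeshow, logistic_r2, split_half_cv, vif


def brute_force_c(score, outcome):
    score = np.asarray(score, float)
    outcome = np.asarray(outcome, int)
    cases = score[outcome == 1]
    controls = score[outcome == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (cases.size * controls.size)


class TestCIndex:
    def test_perfect_separation(self):
        assert c_index([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert c_index([2, 2, 2, 2], [1, 0, 1, 0]) == 0.5

    def test_small_pair_enumeration(self):
        # cases {3,1}, controls {2,0}: three of four pairs concordant
        assert c_index([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    @given(st.integers(0, 10**6), st.integers(10, 200))
    @settings(max_examples=60, deadline=None)
    def test_equals_brute_force_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        score = rng.integers(0, 8, n).astype(float)  # plenty of ties
        outcome = rng.integers(0, 2, n)
        if outcome.min() == outcome.max():
            outcome[0] = 1 - outcome[0]
        assert c_index(score, outcome) == pytest.approx(
            brute_force_c(score, outcome), abs=1e-12
        )

    def test_agrees_with_roc_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        score = rng.normal(size=500)
        outcome = (rng.random(500) < 1 / (1 + np.exp(-score))).astype(int)
        assert c_index(score, outcome) == pytest.approx(
            roc_auc_score(outcome, score), abs=1e-12
        )

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            c_index([1, 2, 3], [1, 1, 1])


class TestLogisticR2:
    def test_null_model_gives_zero(self):
        assert logistic_r2(-100.0, -100.0, 200) == (0.0, 0.0)

    def test_direct_formula_evaluation(self):
        cs, nk = logistic_r2(-100.0, -80.0, 200)
        assert cs == pytest.approx(1 - np.exp(-0.2), abs=1e-12)
        assert nk == pytest.approx((1 - np.exp(-0.2)) / (1 - np.exp(-1.0)), abs=1e-12)

    def test_saturated_balanced_model_rescales_to_one(self):
        n = 1000
        ll_null = n * np.log(0.5)
        assert logistic_r2(ll_null, 0.0, n)[1] == pytest.approx(1.0)

    def test_monotone_in_model_loglik(self):
        values = [logistic_r2(-500.0, l1, 800) for l1 in (-480, -450, -400)]
        assert values == sorted(values)


class TestHosmerLemeshow:
    def test_tied_probabilities_reduce_group_count(self):
        p = np.repeat([0.1, 0.1, 0.3, 0.5, 0.7], 40)
        y = (np.random.default_rng(0).random(200) < p).astype(int)
        res = hosmer_lemeshow(p, y, g=10)
        assert res.groups.shape[0] == 4
        assert res.df == res.groups.shape[0] - 2

    def test_expected_deaths_sum_to_predicted_total(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.9, 500)
        y = (rng.random(500) < p).astype(int)
        res = hosmer_lemeshow(p, y)
        assert res.groups["expected"].sum() == pytest.approx(p.sum())

    def test_systematically_halved_predictions_rejected(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(-0.5 + x)))
        y = (rng.random(2000) < p).astype(int)
        res = hosmer_lemeshow(p / 2, y)
        assert res.p < 0.001

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5, 0.5, 0.5], [0, 1, 0, 1], g=2)


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        assert np.allclose(vif(X), 1.0, atol=0.05)

    def test_duplicated_column_flags_infinity(self):
        X = pd.DataFrame({"a": np.arange(50.0), "b": np.arange(50.0)})
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(X)
        assert np.isinf(out).all()

    def test_bivariate_closed_form(self):
        """Correlation 0.6 gives VIF = 1/(1-0.36) exactly."""
        n = 4000
        rng = np.random.default_rng(6)
        a = rng.normal(size=n)
        e = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        e = e - e.mean() - a * (e @ a) / (a @ a)  # exactly orthogonal to a
        e = e / e.std()
        b = 0.6 * a + np.sqrt(1 - 0.36) * e  # sample correlation exactly 0.6
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1.5625, abs=1e-6)


class TestSplitHalf:
    def test_partition_deterministic_and_balanced(self, default_frame):
        y = default_frame["mort28"].to_numpy()
        r1 = split_half_cv(default_frame, y, seed=3)
        r2 = split_half_cv(default_frame, y, seed=3)
        assert np.array_equal(r1.half_indices[0], r2.half_indices[0])
        assert {len(h) for h in r1.half_indices} == {299}
        assert set(r1.half_indices[0]) | set(r1.half_indices[1]) == set(range(598))

    def test_out_of_sample_discrimination_is_reported(self, big_frame):
        y = big_frame["mort28"].to_numpy()
        res = split_half_cv(big_frame, y, seed=5)
        for c_in, c_out in zip(res.in_sample_c, res.out_of_sample_c):
            assert 0.6 < c_out <= c_in + 0.05  # stable on a large cohort


class TestCompareModels:
    def test_uninformative_outcome_gives_chance_discrimination(self):
        rng = np.random.default_rng(8)
        n = 2000
        frame = pd.DataFrame(
            {
                "age": rng.uniform(20, 90, n),
                "apache2": rng.integers(0, 40, n),
                "sofa": rng.integers(0, 18, n),
                "n_comorbid": rng.integers(0, 6, n),
                "days_hosp_to_icu": rng.uniform(0, 10, n),
                "il6": rng.lognormal(4, 1, n),
            }
        )
        y = rng.integers(0, 2, n)
        score = rng.integers(0, 11, n)
        out = compare_models(frame, y, score)
        assert np.all(np.abs(out["c_index"] - 0.5) < 0.05)

    def test_deterministic_age_outcome_saturates_age_models(self, default_frame):
        y = (default_frame["age"] > default_frame["age"].median()).astype(int)
        score = default_frame["age"].rank()
        out = compare_models(default_frame, y, score).set_index("model")
        assert out.loc["age_apache_sofa", "c_index"] > 0.99
        assert out.loc["all_six_variables", "c_index"] > 0.99
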