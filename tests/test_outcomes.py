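"""Spearman correlations, adequacy arithmetic, MV-duration fit and the
intake x score interaction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutric import adequacy, interaction_test, mv_duration_model, spearman
from tests.test_cohort import make_record


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_rank_formula_hand_computation(self):
        rho, _, n = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)
        assert n == 4

    def test_pairwise_complete_n_reported(self):
        x = [1.0, 2, 3, np.nan, 5, 6]
        y = [2.0, 1, 4, 5, np.nan, 7]
        assert spearman(x, y)[2] == 4

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestAdequacy:
    def test_final_partial_day_excluded(self):
        rec = make_record(
            icu_days=4.0,
            energy_prescribed=2000.0,
            energy_received_daily=[1000.0, 1500.0, 2000.0, 500.0],
        )
        out = adequacy(rec)
        assert out.counted_days == 3
        assert out.pct_received == pytest.approx(75.0)

    def test_day_14_is_included(self):
        rec = make_record(
            icu_days=14.0, energy_prescribed=2000.0, energy_received_daily=[1000.0] * 14
        )
        out = adequacy(rec)
        assert out.counted_days == 14
        assert out.pct_received == pytest.approx(50.0)

    def test_long_stays_count_all_fourteen_collected_days(self):
        rec = make_record(
            icu_days=20.0, energy_prescribed=1000.0, energy_received_daily=[800.0] * 14
        )
        assert adequacy(rec).counted_days == 14

    def test_short_stay_is_ineligible(self):
        rec = make_record(icu_days=2.0, energy_received_daily=[1200.0] * 2)
        out = adequacy(rec)
        assert not out.eligible and "3 days" in out.reason

    def test_late_mv_start_is_ineligible(self):
        rec = make_record(mv_start_within_48h=0)
        out = adequacy(rec)
        assert not out.eligible and "48" in out.reason

    def test_single_day_stay_has_no_countable_days(self):
        rec = make_record(icu_days=1.0, energy_received_daily=[900.0])
        out = adequacy(rec)
        assert out.pct_received is None and not out.eligible

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_rescaling(self, factor):
        base = make_record(
            icu_days=5.0,
            energy_prescribed=1500.0,
            energy_received_daily=[1000.0, 1200.0, 900.0, 1500.0, 400.0],
        )
        scaled = make_record(
            icu_days=5.0,
            energy_prescribed=1500.0 * factor,
            energy_received_daily=[v * factor for v in base.energy_received_daily],
        )
        assert adequacy(scaled).pct_received == pytest.approx(
            adequacy(base).pct_received
        )

    def test_cap_option(self):
        rec = make_record(
            icu_days=3.0, energy_prescribed=1000.0, energy_received_daily=[1500.0] * 3
        )
        assert adequacy(rec).pct_received == pytest.approx(150.0)
        assert adequacy(rec, cap=100).pct_received == 100.0


class TestMvDuration:
    def test_exact_linear_data_has_zero_lack_of_fit(self):
        score = np.repeat(np.arange(6), 10)
        mv = 2.0 + 1.5 * score
        res = mv_duration_model(score, mv, survivors_only=False)
        assert res.slope == pytest.approx(1.5)
        assert res.lack_of_fit_f is None or res.lack_of_fit_f == pytest.approx(0.0)

    def test_quadratic_mean_detected(self):
        rng = np.random.default_rng(9)
        score = rng.integers(0, 11, 400)
        mv = 1.0 + 0.25 * score**2 + rng.normal(0, 2, 400)
        res = mv_duration_model(score, mv, survivors_only=False)
        assert res.lack_of_fit_p < 0.01

    def test_strong_association_on_survivors(self, big_frame):
        from nutric.calculator import score_cohort

        scores, _ = score_cohort(big_frame)
        y = big_frame["mort28"].to_numpy()[scores.index]
        res = mv_duration_model(
            scores.to_numpy(float), big_frame["mv_days"].to_numpy()[scores.index], y
        )
        assert res.slope > 0 and res.slope_p < 1e-4

    def test_no_replicates_flags_lack_of_fit_unavailable(self):
        score = np.array([0.0, 1, 2, 3])
        mv = np.array([1.0, 2, 4, 9])
        res = mv_duration_model(score, mv, survivors_only=False)
        assert res.lack_of_fit_f is None


class TestInteraction:
    @staticmethod
    def simulate(n, gamma_int, seed, gamma_a=0.0):
        rng = np.random.default_rng(seed)
        score = rng.integers(0, 11, n).astype(float)
        intake = 100 * rng.beta(5, 2.2, n)
        lin = -2.0 + 0.3 * score + (intake - 70) * (gamma_a + gamma_int * score)
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        return intake, score, y

    def test_lrt_zero_when_product_uninformative(self):
        """With a constant score the product column adds nothing."""
        rng = np.random.default_rng(12)
        n = 300
        intake = 100 * rng.beta(5, 2.2, n)
        score = np.full(n, 5.0)
        y = (rng.random(n) < 0.3).astype(int)
        res = interaction_test(intake, score, y)
        assert res.lrt_statistic == pytest.approx(0.0, abs=1e-6)

    def test_lrt_nonnegative_and_curves_bounded(self):
        intake, score, y = self.simulate(400, -0.02, seed=13, gamma_a=0.08)
        res = interaction_test(intake, score, y)
        assert res.lrt_statistic >= 0
        assert res.curves["predicted"].between(0, 1).all()
        assert (res.curves["lower"] <= res.curves["predicted"]).all()
        assert (res.curves["upper"] >= res.curves["predicted"]).all()
        assert set(res.curves["score_group"]) == {"0-5", "6-10"}

    def test_strong_interaction_detected(self):
        intake, score, y = self.simulate(2000, -0.02, seed=14, gamma_a=0.08)
        res = interaction_test(intake, score, y)
        assert res.lrt_p < 0.001
        assert res.coef["intake_x_score"] < 0

    def test_lrt_close_to_wald_at_large_n(self):
        import statsmodels.api as sm

        intake, score, y = self.simulate(20_000, -0.003, seed=15, gamma_a=0.012)
        res = interaction_test(intake, score, y)
        X = np.column_stack([np.ones_like(intake), intake, score, intake * score])
        fit = sm.Logit(y, X).fit(disp=0)
        wald = (fit.params[3] / fit.bse[3]) ** 2
        assert res.lrt_statistic == pytest.approx(wald, rel=0.1)

    def test_small_subset_warns(self):
        intake, score, y = self.simulate(25, 0.0, seed=16)
        if len(set(y)) < 2:
            y[0] = 1 - y[0]
        with pytest.warns(UserWarning, match="only"):
            interaction_test(intake, score, y)
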