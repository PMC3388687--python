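"""Single-predictor fits, point assignment, collapsing and selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutric.derivation import (
    CategoryFit,
    DerivationError,
    PointTable,
    ScoreDeriver,
    assign_points,
    collapse_and_round,
    fit_category_logit,
    select_variables,
    snap_convenient,
    total_score,
)
from nutric.prep import CategorizedVariable, quintile_bin


def counts_to_data(counts):
    """Expand (deaths, survivors) per category into index/outcome vectors."""
    idx, y = [], []
    for c, (d, s) in enumerate(counts):
        idx += [c] * (d + s)
        y += [1] * d + [0] * s
    return np.array(idx), np.array(y)


class TestCategoryLogit:
    @pytest.mark.parametrize(
        "counts, cat, expected",
        [
            ([(10, 90), (20, 80)], 1, math.log((20 / 80) / (10 / 90))),
            ([(10, 90), (50, 50)], 1, math.log(9.0)),
        ],
    )
    def test_known_count_configurations(self, counts, cat, expected):
        idx, y = counts_to_data(counts)
        fit = fit_category_logit(idx, y)
        assert fit.logits[cat] == pytest.approx(expected, abs=1e-6)

    def test_equal_death_fractions_give_null_fit(self):
        idx, y = counts_to_data([(20, 80), (10, 40)])
        fit = fit_category_logit(idx, y)
        np.testing.assert_allclose(fit.logits, 0.0, atol=1e-6)
        assert fit.overall_p == pytest.approx(1.0, abs=1e-6)

    @given(
        st.lists(
            st.tuples(st.integers(1, 60), st.integers(1, 60)),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_ml_fit_equals_closed_form_count_logits(self, counts):
        """Saturated categorical MLE == count log-odds-ratio, <= 1e-6."""
        idx, y = counts_to_data(counts)
        fit = fit_category_logit(idx, y)
        d0, s0 = counts[0]
        for c, (d, s) in enumerate(counts):
            expected = math.log(d / s) - math.log(d0 / s0)
            assert fit.logits[c] == pytest.approx(expected, abs=1e-6)

    def test_zero_cell_reported_as_infinite_with_flag(self):
        idx, y = counts_to_data([(10, 90), (0, 50), (20, 30)])
        fit = fit_category_logit(idx, y)
        assert fit.sparse[1] and not fit.sparse[0]
        assert fit.logits[1] == -np.inf

    def test_empty_category_is_error(self):
        with pytest.raises(DerivationError):
            fit_category_logit([0, 0, 2, 2], [0, 1, 0, 1])


class TestAssignPoints:
    @pytest.mark.parametrize(
        "logits, expected",
        [
            ([0.0, 0.49, 1.6], [0, 0, 2]),
            ([0.3, 0.0, -0.2], [1, 0, 0]),  # re-referenced to the minimum
            ([1.0, 1.0, 1.0], [0, 0, 0]),
            ([0.0, 0.5, 1.5], [0, 1, 2]),  # .5 rounds away from zero
        ],
    )
    def test_rounding_and_rereferencing(self, logits, expected):
        fit = CategoryFit(
            "x", np.array(logits), np.zeros(len(logits)), 0.05, 0, 0,
            np.ones((len(logits), 2)), np.zeros(len(logits), bool), len(logits),
        )
        assert assign_points(fit).tolist() == expected

    def test_infinite_logit_rejected(self):
        fit = CategoryFit(
            "x", np.array([0.0, np.inf]), np.zeros(2), 0.05, 0, 0,
            np.ones((2, 2)), np.array([False, True]), 2,
        )
        with pytest.raises(DerivationError):
            assign_points(fit)


class TestSnapAndCollapse:
    @pytest.mark.parametrize(
        "x, expected",
        [(19.8, 20.0), (27.9, 28.0), (397.0, 400.0), (803.0, 800.0),
         (14.7, 15.0), (49.5, 49.0), (2.0, 2.0), (0.97, 0.97)],
    )
    def test_snap_to_convenient_values(self, x, expected):
        assert snap_convenient(x) == expected

    def test_collapse_merges_equal_points_and_snaps_edges(self):
        """Severity-score-like quintiles with points (0,0,1,1,2)."""
        var = CategorizedVariable(
            "apache2", "quintile", np.array([14.7, 19.8, 24.2, 27.9]),
            np.arange(5), 5,
        )
        entries = collapse_and_round(var, np.array([0, 0, 1, 1, 2]))
        assert [(e.lo, e.hi, e.points) for e in entries] == [
            (-np.inf, 20.0, 0), (20.0, 28.0, 1), (28.0, np.inf, 2)
        ]
        assert entries[1].lo_exact == 19.8 and entries[1].hi_exact == 27.9

    def test_all_equal_points_collapse_to_single_category(self):
        var = CategorizedVariable("x", "quintile", np.array([1.0, 2, 3, 4]), np.arange(5), 5)
        entries = collapse_and_round(var, np.array([1, 1, 1, 1, 1]))
        assert len(entries) == 1
        assert (entries[0].lo, entries[0].hi) == (-np.inf, np.inf)

    def test_biomarker_style_edges_snap_to_round_hundreds(self):
        var = CategorizedVariable("il6", "quintile", np.array([397.0, 803.0]), np.arange(3), 3)
        entries = collapse_and_round(var, np.array([0, 1, 2]))
        assert [e.lo for e in entries] == [-np.inf, 400.0, 800.0]

    def test_snap_falls_back_when_it_would_reorder(self):
        var = CategorizedVariable("x", "quintile", np.array([396.0, 404.0]), np.arange(3), 3)
        with pytest.warns(UserWarning, match="keeping exact"):
            entries = collapse_and_round(var, np.array([0, 1, 2]))
        # both would snap to 400; one must keep its exact value
        los = [e.lo for e in entries[1:]]
        assert los[0] < los[1]


class TestTotalScore:
    def test_exhaustive_enumeration_oracle(self):
        """Totals equal the brute-force sum over all category combinations."""
        from itertools import product

        from nutric.calculator import NUTRIC_TABLE, _BANDS

        reps = {
            var: [(c[0] - 1 if i == 0 else (c[i - 1] + c[i]) / 2 if i < len(c) else c[-1] + 1)
                  for i in range(len(p))]
            for var, c, p in _BANDS
        }
        for combo in product(*(range(len(p)) for _, _, p in _BANDS)):
            record = {
                var: reps[var][combo[j]] for j, (var, _, _) in enumerate(_BANDS)
            }
            record = {k: max(v, 0.0) for k, v in record.items()}
            expected = sum(p[combo[j]] for j, (_, _, p) in enumerate(_BANDS))
            assert total_score(NUTRIC_TABLE, record) == expected

    def test_missing_variable_names_the_culprit(self):
        from nutric.calculator import NUTRIC_TABLE

        with pytest.raises(DerivationError, match="sofa"):
            total_score(NUTRIC_TABLE, {"age": 60.0, "apache2": 20.0})

    @given(st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_every_variable(self, seed):
        """Raising one variable's category never lowers the total."""
        from nutric.calculator import NUTRIC_TABLE, _BANDS

        rng = np.random.default_rng(seed)
        rec = {
            "age": rng.uniform(18, 95), "apache2": rng.uniform(0, 40),
            "sofa": rng.uniform(0, 20), "n_comorbid": rng.integers(0, 6),
            "days_hosp_to_icu": rng.uniform(0, 10), "il6": rng.uniform(1, 2000),
        }
        base = total_score(NUTRIC_TABLE, rec)
        var = rng.choice([v for v, _, _ in _BANDS])
        bumped = dict(rec)
        bumped[var] = rec[var] * 2 + 10
        assert total_score(NUTRIC_TABLE, bumped) >= base


class TestSelection:
    def test_all_zero_point_candidate_excluded(self, big_frame):
        y = big_frame["mort28"].to_numpy()
        rng = np.random.default_rng(5)
        cats = {
            "apache2": quintile_bin(big_frame["apache2"].to_numpy(float), "apache2"),
            "flat": quintile_bin(rng.normal(size=len(big_frame)), "flat"),
        }
        res = select_variables(cats, y, p_threshold=1.1)  # force past phase-1 p rule
        assert res.excluded.get("flat") == "all categories assigned 0 points"

    def test_deriver_is_sklearn_compatible(self, big_frame):
        from sklearn.base import clone

        model = ScoreDeriver(improvement_tol=0.002)
        assert clone(model).improvement_tol == 0.002
        model.fit(big_frame, big_frame["mort28"])
        assert set(model.included_) | set(model.excluded_) == set(
            model.get_params()["quintile_vars"]
        ) | {"n_comorbid", "bmi", "oral_intake_pct", "weight_loss_pct"}
        scores = model.predict(big_frame, missing_policy="zero")
        lo, hi = model.table_.total_range
        assert scores.min() >= lo and scores.max() <= hi

    def test_empty_selection_raises(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        cats = {"noise": quintile_bin(rng.normal(size=400), "noise")}
        with pytest.raises(DerivationError):
            select_variables(cats, y, p_threshold=1e-6)
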