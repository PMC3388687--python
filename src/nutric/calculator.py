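"""Scoring with the fixed, published NUTRIC point table.

The NUTRIC score sums integer points over six admission variables —
age, APACHE II, SOFA, number of comorbidities, days from hospital to
ICU admission, and serum IL-6 — giving a total of 0..10. In settings
without IL-6 the marker is simply dropped and the total runs 0..9.

All bands are half-open ``[a, b)``: a value equal to an upper cut-point
belongs to the next band. In particular APACHE II = 28 scores 3 points;
published renderings of the table vary on this boundary, so it is worth
stating: this package assigns the boundary to the higher-risk band,
consistently with the ``a-< b`` notation of the other rows. "1+" days
from hospital to ICU means any fractional stay of at least 1.0 day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .derivation import PointTable, PointEntry

__all__ = ["NutricInputs", "NUTRIC_TABLE", "nutric_score", "score_cohort", "NutricScorer"]

# (variable, interior cut-points, points per band); bands are [a, b).
_BANDS: list[tuple[str, list[float], list[int]]] = [
    ("age", [50.0, 75.0], [0, 1, 2]),
    ("apache2", [15.0, 20.0, 28.0], [0, 1, 2, 3]),
    ("sofa", [6.0, 10.0], [0, 1, 2]),
    ("n_comorbid", [2.0], [0, 1]),
    ("days_hosp_to_icu", [1.0], [0, 1]),
    ("il6", [400.0], [0, 1]),
]


def _published_table() -> PointTable:
    entries = []
    for var, cuts, pts in _BANDS:
        edges = [-np.inf, *cuts, np.inf]
        for i, p in enumerate(pts):
            entries.append(PointEntry(var, edges[i], edges[i + 1], p))
    return PointTable(entries)


#: The published scoring table as a :class:`~nutric.derivation.PointTable`.
NUTRIC_TABLE: PointTable = _published_table()


@dataclass(frozen=True)
class NutricInputs:
    """Admission variables entering the fixed score; IL-6 is optional."""

    age: float
    apache2: int
    sofa: int
    n_comorbid: int
    days_hosp_to_icu: float
    il6: float | None = None


def _band_points(value: float, cuts: list[float], pts: list[int]) -> int:
    return pts[int(np.searchsorted(cuts, value, side="right"))]


def nutric_score(inputs: NutricInputs, *, with_il6: bool = True) -> int:
    """Total NUTRIC score, 0..10 (0..9 when IL-6 is dropped)."""
    total = 0
    for var, cuts, pts in _BANDS:
        if var == "il6":
            if not with_il6 or inputs.il6 is None:
                continue
            value = inputs.il6
        else:
            value = getattr(inputs, var)
        if value < 0:
            raise ValueError(f"{var} must be non-negative, got {value}")
        total += _band_points(float(value), cuts, pts)
    return total


class NutricScorer(BaseEstimator, TransformerMixin):
    """Apply the fixed published point table to a cohort.

    A stateless transformer: ``fit`` only validates columns, and
    ``transform`` maps a cohort frame to an integer score per patient.

    Parameters
    ----------
    with_il6 : bool, default True
        Include the IL-6 row. Without it the maximum total is 9.

    Attributes
    ----------
    feature_names_in_ : list of str
        Columns consumed from the input frame.
    """

    def __init__(self, with_il6: bool = True):
        self.with_il6 = with_il6

    def _required(self) -> list[str]:
        names = [v for v, _, _ in _BANDS]
        return names if self.with_il6 else [n for n in names if n != "il6"]

    def fit(self, X: pd.DataFrame, y=None) -> "NutricScorer":
        missing = [c for c in self._required() if c not in X.columns]
        if missing:
            raise ValueError(f"cohort frame lacks required columns: {missing}")
        self.feature_names_in_ = self._required()
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "feature_names_in_"):
            self.fit(X)
        total = np.zeros(len(X), dtype=int)
        for var, cuts, pts in _BANDS:
            if var == "il6" and not self.with_il6:
                continue
            values = np.asarray(X[var], dtype=float)
            if np.any(values[~np.isnan(values)] < 0):
                raise ValueError(f"negative values in '{var}'")
            pts_arr = np.asarray(pts)[np.searchsorted(cuts, values, side="right")]
            if var == "il6":
                pts_arr = np.where(np.isnan(values), 0, pts_arr)
            elif np.any(np.isnan(values)):
                raise ValueError(f"missing values in required column '{var}'")
            total += pts_arr
        return total


def score_cohort(
    cohort: pd.DataFrame, *, with_il6: bool = True
) -> tuple[pd.Series, pd.Series]:
    """Score every scoreable patient; skip and report the rest.

    Returns ``(scores, distribution)`` where ``scores`` is indexed like
    the input (rows with missing required fields dropped) and
    ``distribution`` counts patients per score value.
    """
    required = [v for v, _, _ in _BANDS if v != "il6"]
    ok = cohort[required].notna().all(axis=1)
    scorer = NutricScorer(with_il6=with_il6).fit(cohort.loc[ok])
    scores = pd.Series(
        scorer.transform(cohort.loc[ok]), index=cohort.index[ok], name="nutric_score"
    )
    distribution = scores.value_counts().sort_index()
    return scores, distribution
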