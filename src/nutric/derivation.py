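"""Derivation of an integer-points mortality risk score.

The procedure mirrors the classic points-from-logits recipe: each
categorized candidate is fit alone as a saturated categorical predictor
in a logistic regression on 28-day mortality; the fitted per-category
log odds ratios, re-referenced to the lowest-risk category, are rounded
to whole numbers to give points; adjacent equal-point categories are
collapsed and the surviving cut-points rounded to convenient values;
candidates are excluded when weakly associated with mortality
(likelihood-ratio p > 0.2), when all their categories earn 0 points, or
when dropping them does not hurt the total score's discrimination. The
total score is the sum of points across retained variables.

Because each single-predictor model is saturated, its maximum-likelihood
logits coincide with the closed-form count log odds
``log(d_k/s_k) - log(d_ref/s_ref)`` — a property the test suite uses as
an independent oracle against the iterative fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .prep import (
    MISSING,
    CategorizedVariable,
    dichotomize_bmi,
    dichotomize_oral_intake,
    dichotomize_weight_loss,
    integer_bin,
    interval_label,
    quintile_bin,
)

__all__ = [
    "CategoryFit",
    "PointEntry",
    "PointTable",
    "DerivationResult",
    "DerivationError",
    "fit_category_logit",
    "assign_points",
    "collapse_and_round",
    "select_variables",
    "total_score",
    "snap_convenient",
    "ScoreDeriver",
]


class DerivationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# single-predictor categorical logistic fit
# ---------------------------------------------------------------------------


@dataclass
class CategoryFit:
    """Per-category log odds ratios of one candidate vs its first category."""

    variable: str
    logits: np.ndarray  # length k, logits[0] == 0 (raw reference)
    se: np.ndarray
    overall_p: float
    loglik: float
    loglik_null: float
    counts: np.ndarray  # k x 2 array of (deaths, survivors)
    sparse: np.ndarray  # per-category flag: a zero cell in an outcome
    k: int


def _binomial_loglik(counts: np.ndarray) -> tuple[float, float]:
    """Saturated and intercept-only log-likelihood from category counts."""
    d, s = counts[:, 0].astype(float), counts[:, 1].astype(float)
    n = d + s
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.nansum(
            np.where(d > 0, d * np.log(d / n), 0.0)
            + np.where(s > 0, s * np.log(s / n), 0.0)
        )
    D, N = d.sum(), n.sum()
    null = D * math.log(D / N) + (N - D) * math.log(1 - D / N) if 0 < D < N else 0.0
    return float(sat), float(null)


def fit_category_logit(category_index, mort28, variable: str = "x") -> CategoryFit:
    """Fit one categorized candidate against 28-day mortality.

    Maximum-likelihood logistic regression on category dummies, category
    0 as raw reference. Categories containing only deaths or only
    survivors have no finite MLE; their logits are reported as +/-inf
    with a sparse flag, and the likelihood is evaluated at its supremum
    (the saturated count-based value). The overall p-value is the
    likelihood-ratio test against the intercept-only model.
    """
    idx = np.asarray(category_index, dtype=int)
    y = np.asarray(mort28, dtype=float)
    keep = idx >= 0
    idx, y = idx[keep], y[keep]
    k = int(idx.max()) + 1 if idx.size else 0
    if k < 2:
        raise DerivationError(f"{variable}: needs >= 2 categories")
    counts = np.zeros((k, 2))
    for c in range(k):
        sel = idx == c
        counts[c] = [y[sel].sum(), sel.sum() - y[sel].sum()]
    if np.any(counts.sum(axis=1) == 0):
        raise DerivationError(f"{variable}: empty category")
    sparse = (counts[:, 0] == 0) | (counts[:, 1] == 0)

    loglik, loglik_null = _binomial_loglik(counts)
    if sparse.any():
        # MLE on the boundary: report closed-form logits with infinities.
        with np.errstate(divide="ignore"):
            raw = np.log(counts[:, 0]) - np.log(counts[:, 1])
        logits = raw - raw[0]
        se = np.full(k, np.nan)
        se[0] = 0.0
    else:
        X = np.column_stack(
            [np.ones(idx.size)] + [(idx == c).astype(float) for c in range(1, k)]
        )
        res = sm.Logit(y, X).fit(disp=0, method="newton")
        logits = np.concatenate([[0.0], res.params[1:]])
        se = np.concatenate([[0.0], res.bse[1:]])
        loglik = float(res.llf)
    lrt = max(0.0, 2 * (loglik - loglik_null))
    overall_p = float(stats.chi2.sf(lrt, df=k - 1))
    return CategoryFit(
        variable, logits, se, overall_p, loglik, loglik_null, counts, sparse, k
    )


def assign_points(fit: CategoryFit) -> np.ndarray:
    """Integer points per category: re-reference to the lowest-risk
    (minimum-logit) category, then round half-away-from-zero."""
    if not np.all(np.isfinite(fit.logits)):
        raise DerivationError(
            f"{fit.variable}: infinite logit; merge sparse categories first"
        )
    rel = fit.logits - fit.logits.min()
    return np.floor(rel + 0.5).astype(int)  # rel >= 0, so this is half-away


def merge_sparse_categories(
    var: CategorizedVariable, mort28
) -> CategorizedVariable:
    """Merge categories with a zero outcome cell into a neighbour.

    A category holding only deaths or only survivors is pooled with its
    lower neighbour (upper for the first category) until every category
    carries both outcomes or only two categories remain.
    """
    y = np.asarray(mort28, dtype=float)
    cur = var
    while cur.k > 2:
        fitc = _category_counts(cur.category_index, y, cur.k)
        bad = np.flatnonzero((fitc[:, 0] == 0) | (fitc[:, 1] == 0))
        if bad.size == 0:
            break
        c = int(bad[0])
        drop = c - 1 if c > 0 else 0  # boundary index removed
        boundaries = np.delete(cur.boundaries, drop)
        idx = cur.category_index.copy()
        obs = idx >= 0
        idx[obs & (idx > drop)] -= 1
        cur = CategorizedVariable(
            name=cur.name,
            kind=cur.kind,
            boundaries=boundaries,
            category_index=idx,
            k=cur.k - 1,
        )
    return cur


def _category_counts(idx: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((k, 2))
    for c in range(k):
        sel = idx == c
        out[c] = [y[sel].sum(), sel.sum() - y[sel].sum()]
    return out


# ---------------------------------------------------------------------------
# point table
# ---------------------------------------------------------------------------


def snap_convenient(x: float) -> float:
    """Nearest value with at most two significant decimal digits.

    Equidistant candidates resolve toward the smaller magnitude, so 49.5
    snaps to 49. Values already on the grid (e.g. 2, 28, 400) are fixed
    points.
    """
    if x == 0 or not math.isfinite(x):
        return x
    a = abs(x)
    step = 10.0 ** (math.floor(math.log10(a)) - 1)
    lo = math.floor(a / step) * step
    hi = lo + step
    snapped = lo if a - lo <= hi - a else hi
    return math.copysign(snapped, x)


@dataclass(frozen=True)
class PointEntry:
    """One row of a scoring table: points for ``variable`` in [lo, hi)."""

    variable: str
    lo: float
    hi: float
    points: int
    lo_exact: float | None = None
    hi_exact: float | None = None
    label: str | None = None

    @property
    def display(self) -> str:
        return self.label if self.label else interval_label(self.lo, self.hi)


@dataclass
class PointTable:
    """An assembled integer-points scoring table."""

    entries: list[PointEntry] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.variable not in seen:
                seen.append(e.variable)
        return seen

    def entries_for(self, variable: str) -> list[PointEntry]:
        return sorted(
            (e for e in self.entries if e.variable == variable), key=lambda e: e.lo
        )

    def points_for(self, variable: str, value: float) -> int:
        for e in self.entries_for(variable):
            if e.lo <= value < e.hi:
                return e.points
        raise DerivationError(f"{variable}={value} matches no table row")

    @property
    def total_range(self) -> tuple[int, int]:
        lo = sum(min(e.points for e in self.entries_for(v)) for v in self.variables)
        hi = sum(max(e.points for e in self.entries_for(v)) for v in self.variables)
        return lo, hi

    def score(self, values, *, missing_policy: str = "error") -> int:
        """Total score for one patient (mapping or object with fields)."""
        total = 0
        for v in self.variables:
            if isinstance(values, dict):
                x = values.get(v)
            else:
                x = getattr(values, v, None)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                if missing_policy == "zero":
                    continue
                raise DerivationError(f"missing value for score variable '{v}'")
            total += self.points_for(v, float(x))
        return total

    def score_frame(self, X: pd.DataFrame, *, missing_policy: str = "error") -> np.ndarray:
        total = np.zeros(len(X), dtype=int)
        for v in self.variables:
            if v not in X.columns:
                raise DerivationError(f"missing column for score variable '{v}'")
            vals = np.asarray(X[v], dtype=float)
            nan = np.isnan(vals)
            if nan.any() and missing_policy != "zero":
                raise DerivationError(f"missing values in score variable '{v}'")
            ent = self.entries_for(v)
            edges = [e.lo for e in ent[1:]]
            pts = np.asarray([e.points for e in ent])
            contrib = pts[np.searchsorted(edges, vals, side="right")]
            total += np.where(nan, 0, contrib)
        return total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": e.variable,
                    "range": e.display,
                    "lo": e.lo,
                    "hi": e.hi,
                    "points": e.points,
                    "lo_exact": e.lo_exact,
                    "hi_exact": e.hi_exact,
                }
                for e in self.entries
            ]
        )

    def report(self) -> str:
        lines = ["Variable                  Range           Points"]
        for v in self.variables:
            for i, e in enumerate(self.entries_for(v)):
                name = v if i == 0 else ""
                lines.append(f"{name:<25} {e.display:<15} {e.points}")
        lo, hi = self.total_range
        lines.append(f"Total score range: {lo}-{hi}")
        return "\n".join(lines)


def collapse_and_round(
    var: CategorizedVariable, points: np.ndarray, *, snap: bool = True
) -> list[PointEntry]:
    """Merge adjacent equal-point categories and round the surviving
    cut-points to convenient values.

    Snapping is skipped for any cut-point where it would reorder or
    collide with a neighbouring boundary (the exact value is kept with a
    warning); exact boundaries are always retained in the entry metadata.
    """
    points = np.asarray(points, dtype=int)
    if points.size != var.k:
        raise DerivationError(f"{var.name}: points/category mismatch")
    # group runs of equal points
    groups: list[tuple[int, int]] = []  # [start, stop) category ranges
    start = 0
    for i in range(1, var.k):
        if points[i] != points[i - 1]:
            groups.append((start, i))
            start = i
    groups.append((start, var.k))

    edges = [-np.inf, *var.boundaries.tolist(), np.inf]
    exact = [edges[a] for a, _ in groups[1:]]  # interior retained boundaries
    if snap and var.kind != "dichotomous":
        snapped = [snap_convenient(b) for b in exact]
        final = list(snapped)
        for i, s in enumerate(snapped):
            lo_ok = s > (final[i - 1] if i > 0 else -np.inf)
            hi_ok = s < (exact[i + 1] if i + 1 < len(exact) else np.inf)
            if not (lo_ok and hi_ok):
                warnings.warn(
                    f"{var.name}: snapping boundary {exact[i]:g} would merge "
                    "distinct-point categories; keeping exact value",
                    stacklevel=2,
                )
                final[i] = exact[i]
    else:
        final = list(exact)

    lows = [-np.inf, *final]
    highs = [*final, np.inf]
    lo_exact = [-np.inf, *exact]
    hi_exact = [*exact, np.inf]
    entries = []
    for g, (a, b) in enumerate(groups):
        label = None
        if var.kind in ("dichotomous", "integer"):
            label = "/".join(var.labels[a:b])
        entries.append(
            PointEntry(
                var.name,
                lows[g],
                highs[g],
                int(points[a]),
                lo_exact=lo_exact[g],
                hi_exact=hi_exact[g],
                label=label,
            )
        )
    return entries


def total_score(table: PointTable, record, *, missing_policy: str = "error") -> int:
    """Sum of per-variable points for one patient."""
    return table.score(record, missing_policy=missing_policy)


# ---------------------------------------------------------------------------
# variable selection and the fitted deriver
# ---------------------------------------------------------------------------


@dataclass
class DerivationResult:
    fits: dict[str, CategoryFit]
    points: dict[str, np.ndarray]
    included: list[str]
    excluded: dict[str, str]  # variable -> reason
    table: PointTable
    categorized: dict[str, CategorizedVariable]


def _points_matrix(
    categorized: dict[str, CategorizedVariable], points: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Per-patient point contribution per variable; missing scores 0."""
    out = {}
    for name, var in categorized.items():
        idx = var.category_index
        contrib = np.where(idx >= 0, points[name][np.clip(idx, 0, None)], 0)
        out[name] = contrib
    return out


def select_variables(
    categorized: dict[str, CategorizedVariable],
    mort28,
    *,
    p_threshold: float = 0.2,
    improvement_tol: float = 0.001,
    snap: bool = True,
) -> DerivationResult:
    """Two-phase candidate selection.

    Phase 1 drops candidates with likelihood-ratio p > ``p_threshold``
    or with every category at 0 points. Phase 2 is a greedy backward
    pass, weakest candidate (largest p) first: a variable is dropped
    when including it raises the total score's c-index by no more than
    ``improvement_tol``.
    """
    from .validation import c_index  # local import; validation also uses us

    y = np.asarray(mort28, dtype=float)
    if not categorized:
        raise DerivationError("no candidate variables")
    fits: dict[str, CategoryFit] = {}
    points: dict[str, np.ndarray] = {}
    merged: dict[str, CategorizedVariable] = {}
    excluded: dict[str, str] = {}
    for name, var in categorized.items():
        var = merge_sparse_categories(var, y)
        merged[name] = var
        fit = fit_category_logit(var.category_index, y, name)
        fits[name] = fit
        points[name] = assign_points(fit)

    survivors = []
    for name in categorized:
        if fits[name].overall_p > p_threshold:
            excluded[name] = "overall significance > 0.2"
        elif np.all(points[name] == 0):
            excluded[name] = "all categories assigned 0 points"
        else:
            survivors.append(name)

    contrib = _points_matrix(merged, points)
    included = list(survivors)
    for name in sorted(survivors, key=lambda v: fits[v].overall_p, reverse=True):
        with_v = sum(contrib[v] for v in included)
        without = [v for v in included if v != name]
        without_v = (
            sum(contrib[v] for v in without)
            if without
            else np.zeros_like(y)
        )
        gain = c_index(with_v, y) - c_index(without_v, y)
        if gain <= improvement_tol:
            included = without
            excluded[name] = "no discrimination improvement"
    if not included:
        raise DerivationError("all candidate variables were excluded")

    entries: list[PointEntry] = []
    for name in categorized:  # preserve candidate order in the table
        if name in included:
            entries.extend(collapse_and_round(merged[name], points[name], snap=snap))
    return DerivationResult(fits, points, included, excluded, PointTable(entries), merged)


#: Candidate roles used by :class:`ScoreDeriver` on a standard cohort frame.
DEFAULT_QUINTILE_VARS = ("age", "apache2", "sofa", "days_hosp_to_icu", "il6", "crp", "pct")
DEFAULT_INTEGER_VARS = ("n_comorbid",)
DEFAULT_DICHOTOMOUS_VARS = ("bmi", "oral_intake_pct", "weight_loss_pct")


class ScoreDeriver(BaseEstimator):
    """Derive an integer-points mortality score from a cohort frame.

    A scikit-learn style estimator: ``fit(X, y)`` runs categorization,
    single-predictor fits, point assignment, collapsing and two-phase
    selection; ``predict(X)`` returns the total score per patient from
    the derived table.

    Parameters
    ----------
    quintile_vars, integer_vars, dichotomous_vars : sequences of str
        Candidate columns and how each is categorized. Dichotomous
        candidates must be among the three study rules (BMI, oral
        intake, weight loss); unknown names raise at fit time.
    sensitivity : bool, default False
        Recode missing oral intake / weight loss as at-risk.
    p_threshold : float, default 0.2
        Phase-1 exclusion level for the per-variable likelihood-ratio p.
    improvement_tol : float, default 0.001
        Minimum c-index gain a variable must contribute to survive the
        phase-2 backward pass.
    snap_boundaries : bool, default True
        Round retained cut-points to convenient (two significant digit)
        values.

    Attributes
    ----------
    result_ : DerivationResult
    table_ : PointTable
    included_, excluded_ : selection outcome
    """

    _DICHOT_RULES = {
        "bmi": lambda v, s: dichotomize_bmi(v),
        "oral_intake_pct": lambda v, s: dichotomize_oral_intake(v, sensitivity=s),
        "weight_loss_pct": lambda v, s: dichotomize_weight_loss(v, sensitivity=s),
    }

    def __init__(
        self,
        quintile_vars=DEFAULT_QUINTILE_VARS,
        integer_vars=DEFAULT_INTEGER_VARS,
        dichotomous_vars=DEFAULT_DICHOTOMOUS_VARS,
        sensitivity: bool = False,
        p_threshold: float = 0.2,
        improvement_tol: float = 0.001,
        snap_boundaries: bool = True,
    ):
        self.quintile_vars = quintile_vars
        self.integer_vars = integer_vars
        self.dichotomous_vars = dichotomous_vars
        self.sensitivity = sensitivity
        self.p_threshold = p_threshold
        self.improvement_tol = improvement_tol
        self.snap_boundaries = snap_boundaries

    def _categorize(self, X: pd.DataFrame) -> dict[str, CategorizedVariable]:
        cats: dict[str, CategorizedVariable] = {}
        for v in self.quintile_vars:
            cats[v] = quintile_bin(np.asarray(X[v], dtype=float), name=v)
        for v in self.integer_vars:
            cats[v] = integer_bin(np.asarray(X[v], dtype=float), name=v)
        for v in self.dichotomous_vars:
            if v not in self._DICHOT_RULES:
                raise DerivationError(f"no dichotomization rule for '{v}'")
            cats[v] = self._DICHOT_RULES[v](
                np.asarray(X[v], dtype=float), self.sensitivity
            )
        return cats

    def fit(self, X: pd.DataFrame, y) -> "ScoreDeriver":
        y = np.asarray(y, dtype=float)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        cats = self._categorize(X)
        self.result_ = select_variables(
            cats,
            y,
            p_threshold=self.p_threshold,
            improvement_tol=self.improvement_tol,
            snap=self.snap_boundaries,
        )
        self.table_ = self.result_.table
        self.included_ = self.result_.included
        self.excluded_ = self.result_.excluded
        return self

    def _recode(self, X: pd.DataFrame) -> pd.DataFrame:
        """Map raw dichotomous columns to their 0/1 at-risk coding."""
        X = X.copy()
        for v in self.included_:
            if v in self._DICHOT_RULES:
                cat = self._DICHOT_RULES[v](
                    np.asarray(X[v], dtype=float), self.sensitivity
                )
                X[v] = cat.category_index.astype(float)
        return X

    def predict(self, X: pd.DataFrame, *, missing_policy: str = "error") -> np.ndarray:
        if not hasattr(self, "table_"):
            raise DerivationError("ScoreDeriver is not fitted")
        return self.table_.score_frame(self._recode(X), missing_policy=missing_policy)

    def manifest(self) -> pd.DataFrame:
        """Categorization manifest: variable, boundaries, category counts."""
        return pd.DataFrame(
            [v.manifest_row() for v in self.result_.categorized.values()]
        )
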