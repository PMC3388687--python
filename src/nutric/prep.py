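"""Candidate-variable preparation: categorization and group contrasts.

Continuous candidates are cut into quintiles at the empirical
20/40/60/80th percentiles (linear-interpolation percentiles, the
default "type 7" convention). Sparse candidates are dichotomized with
the study's rules: BMI < 20 vs other, any weight loss vs none/unknown,
reduced (< 100%) oral intake vs full/unknown — each with a sensitivity
mode that recodes *missing* as the at-risk category. Comorbidity count
stays as integer categories 0..5.

All intervals are half-open ``[a, b)``; a value equal to a cut-point
falls in the upper category, and ties straddling a cut-point therefore
all land on one side. Missing values are carried as category index -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CategorizedVariable",
    "CategorizationError",
    "quintile_bin",
    "integer_bin",
    "dichotomize_bmi",
    "dichotomize_oral_intake",
    "dichotomize_weight_loss",
    "compare_groups",
    "GroupComparison",
]

MISSING = -1


class CategorizationError(ValueError):
    pass


@dataclass
class CategorizedVariable:
    """A predictor cut into ordered categories.

    ``boundaries`` are the interior cut-points; category ``i`` is the
    half-open interval ``[boundaries[i-1], boundaries[i])`` with the
    first category open below and the last closed above by +inf.
    ``category_index`` is -1 where the raw value was missing.
    """

    name: str
    kind: str  # "quintile" | "dichotomous" | "integer"
    boundaries: np.ndarray
    category_index: np.ndarray
    k: int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.category_index = np.asarray(self.category_index, dtype=int)
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise CategorizationError(
                f"{self.name}: boundaries must be strictly increasing"
            )
        if not self.labels:
            self.labels = [interval_label(lo, hi) for lo, hi in self.intervals()]

    def intervals(self) -> list[tuple[float, float]]:
        edges = [-np.inf, *self.boundaries.tolist(), np.inf]
        return [(edges[i], edges[i + 1]) for i in range(self.k)]

    def counts(self) -> np.ndarray:
        """Patients per category, ignoring missing."""
        idx = self.category_index[self.category_index >= 0]
        return np.bincount(idx, minlength=self.k)

    def manifest_row(self) -> dict:
        return {
            "variable": self.name,
            "kind": self.kind,
            "boundaries": ";".join(f"{b:g}" for b in self.boundaries),
            "counts": ";".join(str(c) for c in self.counts()),
            "n_missing": int(np.sum(self.category_index == MISSING)),
        }


def interval_label(lo: float, hi: float) -> str:
    if np.isinf(lo) and np.isinf(hi):
        return "ALL"
    if np.isinf(lo):
        return f"< {hi:g}"
    if np.isinf(hi):
        return f">= {lo:g}"
    return f"{lo:g}-< {hi:g}"


def _assign(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(boundaries, values, side="right")
    return np.where(np.isnan(values), MISSING, idx).astype(int)


def quintile_bin(values, name: str = "x") -> CategorizedVariable:
    """Cut a continuous vector into five equal-sized groups.

    Cut-points sit at the empirical 20/40/60/80th percentiles of the
    non-missing values; heavy ties that collapse adjacent cut-points
    reduce the number of categories accordingly.
    """
    values = np.asarray(values, dtype=float)
    observed = values[~np.isnan(values)]
    if np.unique(observed).size < 5:
        raise CategorizationError(
            f"{name}: fewer than 5 distinct values; dichotomize instead"
        )
    cuts = np.unique(np.percentile(observed, [20, 40, 60, 80]))
    return CategorizedVariable(
        name=name,
        kind="quintile",
        boundaries=cuts,
        category_index=_assign(values, cuts),
        k=cuts.size + 1,
    )


def integer_bin(values, name: str = "x") -> CategorizedVariable:
    """One category per distinct small-integer value (comorbidity count)."""
    values = np.asarray(values, dtype=float)
    observed = np.unique(values[~np.isnan(values)])
    if observed.size < 2:
        raise CategorizationError(f"{name}: needs >= 2 distinct values")
    cuts = observed[1:]  # category i == i-th observed value
    return CategorizedVariable(
        name=name,
        kind="integer",
        boundaries=cuts,
        category_index=_assign(values, cuts),
        k=observed.size,
        labels=[f"{v:g}" for v in observed],
    )


def _dichotomy(
    name: str, at_risk: np.ndarray, labels: list[str]
) -> CategorizedVariable:
    # category 0 = not at risk, 1 = at risk; never missing by construction
    return CategorizedVariable(
        name=name,
        kind="dichotomous",
        boundaries=np.array([0.5]),
        category_index=at_risk.astype(int),
        k=2,
        labels=labels,
    )


def dichotomize_bmi(bmi, name: str = "bmi") -> CategorizedVariable:
    """BMI < 20 vs other; an unrecorded BMI counts as "other"."""
    bmi = np.asarray(bmi, dtype=float)
    low = (~np.isnan(bmi)) & (bmi < 20)
    return _dichotomy(name, low, ["other", "< 20"])


def dichotomize_oral_intake(
    pct, *, sensitivity: bool = False, name: str = "oral_intake_pct"
) -> CategorizedVariable:
    """Reported < 100% oral intake vs full-or-unknown.

    In sensitivity mode, missing histories are assumed to hide a reduced
    intake and join the at-risk category.
    """
    pct = np.asarray(pct, dtype=float)
    observed = ~np.isnan(pct)
    if np.any((pct[observed] < 0) | (pct[observed] > 100)):
        raise CategorizationError(f"{name}: values must lie in [0, 100]")
    reduced = observed & (pct < 100)
    if sensitivity:
        reduced = reduced | ~observed
    return _dichotomy(name, reduced, ["full_or_unknown", "reduced"])


def dichotomize_weight_loss(
    pct, *, sensitivity: bool = False, name: str = "weight_loss_pct"
) -> CategorizedVariable:
    """Any reported weight loss vs none-or-unknown (zero is non-loss)."""
    pct = np.asarray(pct, dtype=float)
    observed = ~np.isnan(pct)
    if np.any(pct[observed] < 0):
        raise CategorizationError(f"{name}: values must be >= 0")
    loss = observed & (pct > 0)
    if sensitivity:
        loss = loss | ~observed
    return _dichotomy(name, loss, ["none_or_unknown", "any_loss"])


@dataclass
class GroupComparison:
    statistic: float
    p: float
    test: str
    summary: pd.DataFrame


def compare_groups(variable, group, *, categorical: bool = False) -> GroupComparison:
    """Contrast a candidate variable between two outcome groups.

    Categorical variables get a Pearson chi-square without continuity
    correction plus per-group counts and percentages; continuous
    variables get a two-sided Wilcoxon rank-sum (normal approximation,
    average ranks for ties) plus per-group medians and IQRs. Missing
    values are dropped pairwise.
    """
    variable = np.asarray(variable, dtype=float)
    group = np.asarray(group, dtype=int)
    keep = ~np.isnan(variable)
    variable, group = variable[keep], group[keep]
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    a, b = variable[group == levels[0]], variable[group == levels[1]]

    if categorical:
        table = pd.crosstab(variable, group)
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        summary = table.copy().astype(float)
        summary = 100 * summary / summary.sum(axis=0)
        summary = pd.concat(
            {"count": table, "pct": summary.round(1)}, axis=1
        )
        return GroupComparison(float(chi2), float(p), "chi-square", summary)

    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    rows = []
    for label, x in zip(levels, (a, b)):
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append({"group": label, "n": x.size, "median": med, "q1": q1, "q3": q3})
    return GroupComparison(
        float(res.statistic), float(res.pvalue), "wilcoxon-rank-sum", pd.DataFrame(rows)
    )
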