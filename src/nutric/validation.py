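"""Discrimination, calibration, collinearity and split-sample stability.

Discrimination is the c-index (area under the ROC curve): the
probability a randomly chosen 28-day non-survivor scores above a
randomly chosen survivor, ties credited one half. Conventional reading:
>= 0.90 excellent, 0.70-0.89 adequate, < 0.70 poor. Explained variation
is summarised by the Cox-Snell generalized R^2 and its max-rescaled
(Nagelkerke) version; calibration by observed-vs-modelled mortality per
score value and the Hosmer-Lemeshow chi-square over groups of predicted
risk; stability by independently re-deriving the score on a random half
of the cohort and scoring the held-out half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "c_index",
    "logistic_r2",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
    "split_half_cv",
    "SplitHalfResult",
    "vif",
    "compare_models",
    "ValidationReport",
    "validate_score",
]


def c_index(score, outcome) -> float:
    """Concordance between a score and a binary outcome.

    Equivalent to all-pairs counting with half credit for ties, computed
    through average ranks (Mann-Whitney U).
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    n1 = int(outcome.sum())
    n0 = outcome.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-index needs both outcome classes")
    ranks = stats.rankdata(score)
    u = ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def logistic_r2(loglik_null: float, loglik_model: float, n: int) -> tuple[float, float]:
    """Cox-Snell generalized R^2 and its max-rescaled (Nagelkerke) form."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-9:
        raise ValueError("model log-likelihood below null log-likelihood")
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(cs), float(cs / denom) if denom > 0 else 0.0


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p: float
    groups: pd.DataFrame  # group, n, observed, expected


def hosmer_lemeshow(predicted_p, outcome, g: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit over groups of predicted risk.

    Groups are deciles of predicted probability; tied probabilities stay
    together, reducing the group count when necessary (fewer than 3
    groups is an error). The statistic sums
    ``(O_g - E_g)^2 / (E_g (1 - E_g/n_g))`` with ``g - 2`` degrees of
    freedom.
    """
    p = np.asarray(predicted_p, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if p.size < g:
        raise ValueError("need at least g observations")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie in (0, 1)")
    bins = pd.qcut(p, g, duplicates="drop")
    g_eff = bins.categories.size
    if g_eff < 3:
        raise ValueError("fewer than 3 risk groups after tie-merging")
    rows = []
    statistic = 0.0
    for cat in bins.categories:
        sel = bins == cat
        n_g = int(sel.sum())
        if n_g == 0:  # quantile edges can straddle a gap in tied data
            continue
        o_g = int(y[sel].sum())
        e_g = float(p[sel].sum())
        statistic += (o_g - e_g) ** 2 / (e_g * (1 - e_g / n_g))
        rows.append({"group": len(rows) + 1, "n": n_g, "observed": o_g, "expected": e_g})
    groups = pd.DataFrame(rows)
    g_eff = len(rows)
    if g_eff < 3:
        raise ValueError("fewer than 3 risk groups after tie-merging")
    if (groups["expected"] < 5).any():
        warnings.warn("Hosmer-Lemeshow group with expected count < 5", stacklevel=2)
    df = g_eff - 2
    return HosmerLemeshowResult(
        float(statistic), df, float(stats.chi2.sf(statistic, df)), groups
    )


@dataclass
class SplitHalfResult:
    seed: int
    half_indices: tuple[np.ndarray, np.ndarray]
    results: list  # per-half DerivationResult or error string
    in_sample_c: list[float | None]
    out_of_sample_c: list[float | None]


def split_half_cv(X: pd.DataFrame, y, seed: int, deriver=None) -> SplitHalfResult:
    """Derive the score independently in each random half and score the
    held-out half.

    The split is a simple (outcome-unstratified) random 50/50 partition;
    with odd n the halves differ by one. A derivation failure in one
    half is recorded, not fatal.
    """
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 100:
        raise ValueError("split-half derivation needs n >= 100")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = (np.sort(perm[: n // 2]), np.sort(perm[n // 2 :]))
    results, in_c, out_c = [], [], []
    for h, idx in enumerate(halves):
        other = halves[1 - h]
        model = clone_deriver(deriver)
        try:
            model.fit(X.iloc[idx], y[idx])
            results.append(model.result_)
            in_c.append(c_index(model.predict(X.iloc[idx], missing_policy="zero"), y[idx]))
            out_c.append(
                c_index(model.predict(X.iloc[other], missing_policy="zero"), y[other])
            )
        except Exception as exc:  # per-half failure is reported, not raised
            results.append(f"derivation failed: {exc}")
            in_c.append(None)
            out_c.append(None)
    return SplitHalfResult(seed, halves, results, in_c, out_c)


def clone_deriver(deriver):
    from sklearn.base import clone

    from .derivation import ScoreDeriver

    return clone(deriver) if deriver is not None else ScoreDeriver()


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1-R^2) from an OLS of
    each column on the others (with intercept). Exact collinearity is
    reported as +inf."""
    design = design.astype(float)
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if (design.nunique() <= 1).any():
        raise ValueError("VIF undefined for a constant column")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col).to_numpy())
        res = sm.OLS(design[col].to_numpy(), others).fit()
        r2 = res.rsquared
        if r2 >= 1 - 1e-12:
            warnings.warn(f"exact collinearity involving '{col}'", stacklevel=2)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit; separation is flagged, not fixed.

    Returns ``(result, converged)`` where ``result`` exposes
    ``params``, ``predict()``, ``llf`` and ``llnull``. On (quasi-)
    separation Newton's method fails; the IRLS fallback then carries
    diverging coefficients and is reported as non-converged.
    """
    Xc = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
            return res, bool(res.mle_retvals.get("converged", True))
        except Exception:
            glm = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
            glm.llnull = glm.llf - (glm.null_deviance - glm.deviance) / 2.0
            return glm, False


def compare_models(cohort: pd.DataFrame, y, score) -> pd.DataFrame:
    """c-index and R^2 for the score model and reference logistic models.

    Rows: the total score as a single continuous predictor; age + APACHE
    II + SOFA continuous; all six score variables as continuous
    predictors; and the model excluding any acute-inflammation marker.
    Rows with missing values for a model's variables are dropped for
    that model only.
    """
    y = np.asarray(y, dtype=float)
    specs = {
        "score_single_predictor": None,
        "age_apache_sofa": ["age", "apache2", "sofa"],
        "all_six_variables": ["age", "apache2", "sofa", "n_comorbid", "days_hosp_to_icu", "il6"],
        "no_acute_inflammation": ["age", "apache2", "sofa", "n_comorbid", "days_hosp_to_icu"],
    }
    rows = []
    for name, cols in specs.items():
        if cols is None:
            Xm = np.asarray(score, dtype=float).reshape(-1, 1)
            keep = ~np.isnan(Xm[:, 0])
        else:
            Xm = cohort[cols].to_numpy(dtype=float)
            keep = ~np.isnan(Xm).any(axis=1)
        Xk, yk = Xm[keep], y[keep]
        res, converged = _logit_fit(Xk, yk)
        cs, nk = logistic_r2(res.llnull, max(res.llf, res.llnull), yk.size)
        rows.append(
            {
                "model": name,
                "n": int(yk.size),
                "c_index": c_index(res.predict(), yk),
                "r2_generalized": cs,
                "r2_max_rescaled": nk,
                "converged": converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Bundle of discrimination / calibration / stability outputs for a
    scored cohort."""

    n: int
    c_index: float
    r2_generalized: float
    r2_max_rescaled: float
    hl: HosmerLemeshowResult
    calibration: pd.DataFrame  # score, n, observed mortality, model mortality
    vif: pd.Series | None = None
    split: SplitHalfResult | None = None
    model_comparison: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"n = {self.n}",
            f"c-index = {self.c_index:.3f}",
            f"generalized R^2 = {self.r2_generalized:.3f}",
            f"max-rescaled R^2 = {self.r2_max_rescaled:.3f}",
            f"Hosmer-Lemeshow chi2 = {self.hl.statistic:.2f} "
            f"(df {self.hl.df}, p = {self.hl.p:.2f})",
        ]
        if self.split is not None and all(
            c is not None for c in self.split.out_of_sample_c
        ):
            a, b = self.split.out_of_sample_c
            lines.append(f"split-half out-of-sample c-index: A = {a:.3f}, B = {b:.3f}")
        return "\n".join(lines)


def validate_score(
    score,
    outcome,
    *,
    cohort: pd.DataFrame | None = None,
    split_seed: int | None = None,
    vif_columns: tuple[str, ...] = (
        "age",
        "apache2",
        "sofa",
        "n_comorbid",
        "days_hosp_to_icu",
        "il6",
    ),
) -> ValidationReport:
    """Validate a per-patient score against 28-day mortality.

    Fits the calibration logistic model (score as a single continuous
    predictor), then assembles discrimination, R^2, Hosmer-Lemeshow,
    per-score-value calibration, and — when a cohort frame is supplied —
    collinearity of the component variables and a split-half
    cross-validation.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=int)
    res, _ = _logit_fit(score.reshape(-1, 1), y.astype(float))
    p_hat = res.predict()
    cs, nk = logistic_r2(res.llnull, res.llf, y.size)
    calib = (
        pd.DataFrame({"score": score, "observed": y, "model_p": p_hat})
        .groupby("score")
        .agg(n=("observed", "size"), observed=("observed", "mean"), model=("model_p", "mean"))
        .reset_index()
    )
    vif_series = None
    split = None
    if cohort is not None:
        cols = [c for c in vif_columns if c in cohort.columns]
        if len(cols) >= 2:
            complete = cohort[cols].dropna()
            vif_series = vif(complete)
        if split_seed is not None:
            split = split_half_cv(cohort, y, split_seed)
    return ValidationReport(
        n=int(y.size),
        c_index=c_index(score, y),
        r2_generalized=cs,
        r2_max_rescaled=nk,
        hl=hosmer_lemeshow(p_hat, y),
        calibration=calib,
        vif=vif_series,
        split=split,
    )
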