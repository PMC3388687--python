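"""Outcome associations: ventilator-free days, MV duration, nutritional
adequacy and score x adequacy effect modification.

Nutritional adequacy is the percentage of the prescribed daily energy a
patient actually received over the counted ICU days. The final ICU day
is excluded as a partial day — unless it is day 14, the last day of
daily collection. The effect-modification analysis runs on the subset
that started mechanical ventilation within 48 h of ICU admission and
stayed at least 3 days: a logistic model of 28-day mortality on intake,
score and their product (all continuous), with a 1-df likelihood-ratio
test for the product term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import PatientRecord

__all__ = [
    "spearman",
    "AdequacyRecord",
    "adequacy",
    "cohort_adequacy",
    "MvDurationFit",
    "mv_duration_model",
    "InteractionResult",
    "interaction_test",
    "vfd_correlations",
]


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with pairwise-complete missing handling.

    Returns ``(rho, p, n)`` where ``n`` is the number of complete pairs
    actually used (reported because candidate variables differ widely in
    completeness).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), int(x.size)


@dataclass
class AdequacyRecord:
    patient_id: str
    pct_received: float | None
    counted_days: int
    eligible: bool
    reason: str | None = None


def adequacy(
    record: PatientRecord, *, cap: float | None = None
) -> AdequacyRecord:
    """Percent of prescribed energy received over counted ICU days.

    Counted days are the collected ICU days (capped at 14) minus the
    final partial day, unless that final day is day 14. Eligibility for
    the effect-modification subset requires MV start within 48 h and an
    ICU stay of at least 3 days. Adequacy is not capped by default
    (overfeeding is representable); pass ``cap=100`` for a capped
    sensitivity run.
    """
    if record.energy_prescribed <= 0:
        raise ValueError("energy prescription must be positive")
    received = list(record.energy_received_daily)
    counted = received if len(received) == 14 else received[:-1]
    eligible = record.mv_start_within_48h == 1 and record.icu_days >= 3
    if not counted:
        return AdequacyRecord(
            record.patient_id, None, 0, False, "no full ICU days to count"
        )
    pct = 100.0 * float(np.mean(counted)) / record.energy_prescribed
    if cap is not None:
        pct = min(pct, cap)
    reason = None
    if not eligible:
        reason = (
            "ICU stay shorter than 3 days"
            if record.icu_days < 3
            else "MV not started within 48 h"
        )
    return AdequacyRecord(record.patient_id, pct, len(counted), eligible, reason)


def cohort_adequacy(records, *, cap: float | None = None) -> pd.DataFrame:
    rows = [adequacy(r, cap=cap).__dict__ for r in records]
    return pd.DataFrame(rows)


@dataclass
class MvDurationFit:
    slope: float
    intercept: float
    slope_p: float
    n: int
    k: int  # distinct score values
    lack_of_fit_f: float | None
    lack_of_fit_p: float | None
    group_means: pd.DataFrame


def mv_duration_model(score, mv_days, mort28=None, *, survivors_only: bool = True) -> MvDurationFit:
    """OLS of MV days on the score, with a pure-error lack-of-fit test.

    Defaults to the 28-day survivor subset (duration among decedents is
    censored by death). The lack-of-fit F compares the linear model's
    residual sum of squares with the pure error from replicate patients
    at each score value; it is unavailable (flagged ``None``) without
    replicates.
    """
    score = np.asarray(score, dtype=float)
    mv = np.asarray(mv_days, dtype=float)
    if survivors_only:
        if mort28 is None:
            raise ValueError("survivors_only requires mort28")
        keep = np.asarray(mort28, dtype=int) == 0
        score, mv = score[keep], mv[keep]
    if score.size == 0:
        raise ValueError("empty survivor subset")
    uniq = np.unique(score)
    k = uniq.size
    if k < 3:
        raise ValueError("need >= 3 distinct score values")
    res = sm.OLS(mv, sm.add_constant(score)).fit()
    sse_line = float(np.sum(res.resid**2))
    group = pd.DataFrame({"score": score, "mv": mv}).groupby("score")["mv"]
    means = group.agg(["size", "mean"]).reset_index()
    sse_pure = float(((mv - group.transform("mean").to_numpy()) ** 2).sum())
    n = score.size
    if n > k and sse_pure > 0:
        f = ((sse_line - sse_pure) / (k - 2)) / (sse_pure / (n - k))
        lof_p = float(stats.f.sf(f, k - 2, n - k))
    else:
        f, lof_p = None, None
    return MvDurationFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_p=float(res.pvalues[1]),
        n=n,
        k=k,
        lack_of_fit_f=f,
        lack_of_fit_p=lof_p,
        group_means=means,
    )


@dataclass
class InteractionResult:
    coef: pd.Series  # intercept, intake, score, intake_x_score
    lrt_statistic: float
    lrt_p: float
    curves: pd.DataFrame  # intake, predicted p and 95% CI per score group
    n: int
    converged: bool


def _predict_curve(res, intake_grid: np.ndarray, score_value: float, label: str) -> pd.DataFrame:
    X = np.column_stack(
        [
            np.ones_like(intake_grid),
            intake_grid,
            np.full_like(intake_grid, score_value),
            intake_grid * score_value,
        ]
    )
    eta = X @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, res.cov_params(), X))
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))
    return pd.DataFrame(
        {
            "intake_pct": intake_grid,
            "predicted": expit(eta),
            "lower": expit(eta - 1.96 * se),
            "upper": expit(eta + 1.96 * se),
            "score_group": label,
            "score_at": score_value,
        }
    )


def interaction_test(
    adequacy_pct, score, mort28, *, grid_points: int = 41
) -> InteractionResult:
    """Likelihood-ratio test for intake x score effect modification.

    Fits logistic mortality models with and without the product of
    intake and score (both continuous); the LRT statistic is twice the
    log-likelihood gain, referred to chi-square with 1 df. Predicted
    mortality curves with delta-method 95% CIs are evaluated over the
    observed intake range at the median score of the low (0-5) and high
    (6-10) score groups.
    """
    a = np.asarray(adequacy_pct, dtype=float)
    s = np.asarray(score, dtype=float)
    y = np.asarray(mort28, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(s) | np.isnan(y))
    a, s, y = a[keep], s[keep], y[keep]
    if a.size < 30:
        warnings.warn(f"interaction subset has only {a.size} patients", stacklevel=2)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcomes must be present")
    X_red = np.column_stack([np.ones(a.size), a, s])
    X_full = np.column_stack([X_red, a * s])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
        res_full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
    lrt = max(0.0, 2.0 * (res_full.llf - res_red.llf))
    lrt_p = float(stats.chi2.sf(lrt, df=1))
    grid = np.linspace(a.min(), a.max(), grid_points)
    curves = []
    for label, sel in (("0-5", s <= 5), ("6-10", s >= 6)):
        if sel.any():
            curves.append(
                _predict_curve(res_full, grid, float(np.median(s[sel])), label)
            )
    coef = pd.Series(
        res_full.params, index=["intercept", "intake", "score", "intake_x_score"]
    )
    return InteractionResult(
        coef=coef,
        lrt_statistic=float(lrt),
        lrt_p=lrt_p,
        curves=pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
        n=int(a.size),
        converged=bool(res_full.mle_retvals.get("converged", True)),
    )


def vfd_correlations(cohort: pd.DataFrame, vfd, variables=None) -> pd.DataFrame:
    """Spearman correlation of each candidate variable with
    ventilator-free days, with the per-variable complete-pair count."""
    if variables is None:
        variables = [
            "age",
            "apache2",
            "sofa",
            "oral_intake_pct",
            "days_hosp_to_icu",
            "weight_loss_pct",
            "bmi",
            "n_comorbid",
            "crp",
            "pct",
            "il6",
        ]
    rows = []
    for v in variables:
        if v not in cohort.columns:
            continue
        try:
            rho, p, n = spearman(cohort[v], vfd)
        except ValueError:
            rho, p, n = np.nan, np.nan, 0
        rows.append({"variable": v, "spearman": rho, "p": p, "n": n})
    return pd.DataFrame(rows)
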