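"""Replicate simulation studies of the pipeline's operating
characteristics.

These studies back the package's statistical-correctness claims:
integer-point recovery of the derivation chain, type-I error of the
Hosmer-Lemeshow test, of the pure-error lack-of-fit test and of the
intake x score interaction LRT, and retention behaviour of the
two-phase variable selection. Each takes a seed and returns plain
dicts, so they can be re-run identically from the test suite or a
script.

Problem sizes default to cohorts of 5,000 for recovery (category
logit standard errors ~0.1, far from the 0.5 rounding boundary) and to
the reference cohort scale elsewhere.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calculator import score_cohort
from .cohort import cohort_to_frame
from .derivation import (
    ScoreDeriver,
    assign_points,
    collapse_and_round,
    fit_category_logit,
    merge_sparse_categories,
)
from .outcomes import interaction_test, mv_duration_model
from .prep import integer_bin, quintile_bin
from .synthetic import SyntheticConfig, simulate_cohort
from .validation import hosmer_lemeshow

__all__ = [
    "POINT_TARGETS",
    "point_recovery_study",
    "retention_study",
    "hl_type1_study",
    "interaction_type1_study",
    "interaction_power_study",
    "lack_of_fit_type1_study",
]

#: Integer per-category log-odds targets on the quintile (or integer)
#: categories of each score variable, shaped like the published table:
#: three risk levels for age and SOFA, four for APACHE II, two each for
#: comorbidities, pre-ICU days and IL-6.
POINT_TARGETS: dict[str, list[int]] = {
    "age": [0, 1, 1, 1, 2],
    "apache2": [0, 1, 2, 2, 3],
    "sofa": [0, 1, 1, 1, 2],
    "days_hosp_to_icu": [0, 0, 0, 1, 1],
    "il6": [0, 0, 0, 0, 1],
    "n_comorbid": [0, 0, 1, 1, 1, 1],
}


def point_recovery_study(
    n_reps: int = 100, n: int = 5000, seed: int = 0, baseline: float = -1.5
) -> dict:
    """Integer-point recovery of the single-predictor derivation chain.

    Each replicate draws a cohort of admission variables, assigns every
    variable's quintile (or integer) categories the integer log-odds
    targets of :data:`POINT_TARGETS` on top of a ``baseline`` intercept,
    draws mortality from that variable's categorical model, and runs
    binning, sparse-merging, the saturated logistic fit, point
    assignment and collapsing. Success means every variable's rounded
    points equal its targets and the collapsed point levels match the
    published structure. Because a single-predictor fit estimates a
    *marginal* association, the target log-odds are placed on one
    variable at a time; a joint outcome model would attenuate every
    marginal logit below its conditional value (non-collapsibility of
    the odds ratio).
    """
    expected = {k: sorted(set(v)) for k, v in POINT_TARGETS.items()}
    successes = 0
    failures: dict[str, int] = {}
    for r in range(n_reps):
        frame = cohort_to_frame(simulate_cohort(SyntheticConfig(n=n, seed=seed + r)))
        rng = np.random.default_rng([seed + r, 99])
        ok = True
        for var, tgt in POINT_TARGETS.items():
            vals = frame[var].to_numpy(dtype=float)
            cat = (
                integer_bin(vals, var)
                if var == "n_comorbid"
                else quintile_bin(vals, var)
            )
            lin = baseline + np.asarray(tgt)[cat.category_index]
            y = (rng.random(vals.size) < 1.0 / (1.0 + np.exp(-lin))).astype(int)
            cat = merge_sparse_categories(cat, y)
            pts = assign_points(fit_category_logit(cat.category_index, y, var))
            good = (
                cat.k != len(tgt) or np.array_equal(pts, np.asarray(tgt))
            ) and [e.points for e in collapse_and_round(cat, pts)] == expected[var]
            if not good:
                ok = False
                failures[var] = failures.get(var, 0) + 1
        successes += ok
    return {
        "n_reps": n_reps,
        "successes": successes,
        "success_rate": successes / n_reps,
        "failures_by_variable": failures,
    }


def retention_study(
    n_reps: int = 20, n: int = 5000, seed: int = 0, with_noise: bool = True
) -> dict:
    """Variable-selection behaviour on cohorts with the published score
    structure at one log-odds per point.

    Counts replicates where all six true score variables are retained
    and, when ``with_noise``, where an unrelated standard-normal
    candidate is excluded.
    """
    cfg = replace(
        SyntheticConfig(n=n),
        calibration=1.0,
        outcome_intercept=-6.3,
        adequacy_main=0.0,
        adequacy_interaction=0.0,
    )
    six = set(POINT_TARGETS)
    retained = excluded_noise = 0
    for r in range(n_reps):
        frame = cohort_to_frame(simulate_cohort(replace(cfg, seed=seed + r)))
        quintiles = ["age", "apache2", "sofa", "days_hosp_to_icu", "il6"]
        if with_noise:
            frame["noise"] = np.random.default_rng([seed + r, 123]).normal(
                size=len(frame)
            )
            quintiles.append("noise")
        model = ScoreDeriver(quintile_vars=tuple(quintiles)).fit(
            frame, frame["mort28"]
        )
        if six <= set(model.included_):
            retained += 1
        if with_noise and "noise" in model.excluded_:
            excluded_noise += 1
    return {
        "n_reps": n_reps,
        "all_six_retained": retained,
        "noise_excluded": excluded_noise,
    }


def hl_type1_study(
    n_reps: int = 500, n: int = 1000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Hosmer-Lemeshow rejection rate under a correctly specified model.

    Each replicate generates a continuous risk factor, draws outcomes
    from a logistic model on it, refits that model and applies the test
    to the fitted probabilities.
    """
    import statsmodels.api as sm

    rejections = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed + r, 7])
        x = rng.normal(size=n)
        p = 1.0 / (1.0 + np.exp(-(-1.0 + 1.0 * x)))
        y = (rng.random(n) < p).astype(int)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        res = hosmer_lemeshow(fit.predict(), y)
        rejections += res.p < alpha
    return {"n_reps": n_reps, "rejection_rate": rejections / n_reps}


def _interaction_rep(cfg: SyntheticConfig, seed: int):
    frame = cohort_to_frame(simulate_cohort(replace(cfg, seed=seed)))
    scores, _ = score_cohort(frame)
    eligible = (
        (frame["mv_start_within_48h"] == 1)
        & (frame["icu_days"] >= 3)
        & frame.index.isin(scores.index)
    ).to_numpy()
    # adequacy = mean(daily)/prescribed over counted days; computed inline
    # on the frame to avoid rebuilding records per replicate
    pct = []
    for daily, presc in zip(frame["energy_received_daily"], frame["energy_prescribed"]):
        counted = daily if len(daily) == 14 else daily[:-1]
        pct.append(100 * np.mean(counted) / presc if counted else np.nan)
    pct = np.asarray(pct)
    sub = eligible & ~np.isnan(pct)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return interaction_test(
            pct[sub],
            scores.reindex(frame.index).to_numpy(dtype=float)[sub],
            frame["mort28"].to_numpy(dtype=int)[sub],
        )


def interaction_type1_study(
    n_reps: int = 500, n: int = 560, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error of the interaction LRT with a null generating model.

    The generator's intake terms are switched off, cohorts sized so the
    eligible subset is near the reference 211 patients, and the full
    adequacy -> interaction pipeline is run on each replicate.
    """
    cfg = replace(
        SyntheticConfig(n=n), adequacy_main=0.0, adequacy_interaction=0.0
    )
    rejections = 0
    sizes = []
    for r in range(n_reps):
        res = _interaction_rep(cfg, seed + r)
        sizes.append(res.n)
        rejections += res.lrt_p < alpha
    return {
        "n_reps": n_reps,
        "rejection_rate": rejections / n_reps,
        "median_subset_n": float(np.median(sizes)),
    }


def interaction_power_study(n_reps: int = 100, n: int = 560, seed: int = 0) -> dict:
    """Power of the interaction LRT under the generator's default
    negative intake x score coefficient."""
    cfg = SyntheticConfig(n=n)
    pvals = [_interaction_rep(cfg, seed + r).lrt_p for r in range(n_reps)]
    pvals = np.asarray(pvals)
    return {
        "n_reps": n_reps,
        "median_p": float(np.median(pvals)),
        "power_at_0.05": float(np.mean(pvals < 0.05)),
    }


def lack_of_fit_type1_study(
    n_reps: int = 500, n: int = 400, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Pure-error lack-of-fit rejection rate under a truly linear
    score -> MV-days mean."""
    rejections = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed + r, 11])
        score = rng.integers(0, 11, size=n)
        mv = np.clip(2.0 + 1.2 * score + rng.normal(0, 3.5, n), 0, None)
        res = mv_duration_model(score, mv, survivors_only=False)
        rejections += (res.lack_of_fit_p is not None) and res.lack_of_fit_p < alpha
    return {"n_reps": n_reps, "rejection_rate": rejections / n_reps}
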