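"""End-to-end reproducible pipeline: simulate -> prep -> derive ->
validate -> outcome analyses, with a consolidated plain-text/JSON
report bundle.

All randomness flows from the single configured seed; report files
contain no timestamps, so two runs with equal configs are
byte-identical. Stage timings and record counts go to the logger, not
into the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calculator, outcomes, validation
from .cohort import cohort_to_frame, compute_vfd, read_cohort, write_cohort
from .derivation import ScoreDeriver
from .synthetic import SyntheticConfig, simulate_cohort

log = logging.getLogger("nutric")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "nutric_run"
    input_path: str | None = None  # None -> simulate
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    derive: bool = True
    validate: bool = True
    outcomes: bool = True
    score_fixed: bool = True  # score with the packaged published table
    sensitivity: bool = False
    p_threshold: float = 0.2
    improvement_tol: float = 0.001
    cap_adequacy: float | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the consolidated report dict (also written as
    ``report.json``). A stage failure is logged and recorded in the
    report; dependent downstream stages are skipped.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "errors": {}}

    if config.input_path is None:
        cfg = config.synthetic
        if cfg.seed != config.seed:
            from dataclasses import replace

            cfg = replace(cfg, seed=config.seed)
        records = simulate_cohort(cfg)
        write_cohort(records, out / "cohort.csv")
        cfg.to_yaml(out / "cohort.provenance.yaml")
        report["cohort"] = {"source": "synthetic", "n": len(records)}
    else:
        records = read_cohort(config.input_path)
        report["cohort"] = {"source": str(config.input_path), "n": len(records)}
    frame = cohort_to_frame(records)
    y = frame["mort28"].to_numpy(dtype=int)

    scores = None
    if config.score_fixed:
        fixed_scores, dist = calculator.score_cohort(frame)
        scores = fixed_scores.reindex(frame.index)
        dist.rename("count").to_csv(out / "score_distribution.csv")
        report["fixed_score"] = {
            "n_scored": int(fixed_scores.size),
            "distribution": {int(k): int(v) for k, v in dist.items()},
        }

    deriver = None
    if config.derive:
        try:
            deriver = ScoreDeriver(
                sensitivity=config.sensitivity,
                p_threshold=config.p_threshold,
                improvement_tol=config.improvement_tol,
            ).fit(frame, y)
            deriver.manifest().to_csv(out / "categorization_manifest.csv", index=False)
            deriver.table_.to_frame().to_csv(out / "derived_table.csv", index=False)
            (out / "derived_table.txt").write_text(
                deriver.table_.report() + "\n", encoding="utf-8"
            )
            report["derivation"] = {
                "included": deriver.included_,
                "excluded": deriver.excluded_,
                "total_range": list(deriver.table_.total_range),
            }
            scores_derived = deriver.predict(frame, missing_policy="zero")
            report["derivation"]["c_index_in_sample"] = validation.c_index(
                scores_derived, y
            )
        except Exception as exc:
            log.error("derivation failed: %s", exc)
            report["errors"]["derive"] = str(exc)

    if config.validate and scores is not None:
        try:
            rep = validation.validate_score(
                scores.dropna(),
                y[scores.notna()],
                cohort=frame.loc[scores.notna()],
                split_seed=config.seed,
            )
            rep.calibration.to_csv(out / "calibration.csv", index=False)
            report["validation"] = {
                "c_index": rep.c_index,
                "r2_generalized": rep.r2_generalized,
                "r2_max_rescaled": rep.r2_max_rescaled,
                "hl_statistic": rep.hl.statistic,
                "hl_df": rep.hl.df,
                "hl_p": rep.hl.p,
                "vif": None if rep.vif is None else rep.vif.round(3).to_dict(),
                "split_out_of_sample_c": rep.split.out_of_sample_c
                if rep.split is not None
                else None,
            }
            comp = validation.compare_models(frame, y, scores)
            comp.to_csv(out / "model_comparison.csv", index=False)
            report["validation"]["model_comparison"] = comp.to_dict("records")
        except Exception as exc:
            log.error("validation failed: %s", exc)
            report["errors"]["validate"] = str(exc)

    if config.outcomes and scores is not None:
        try:
            vfd = np.array([compute_vfd(r) for r in records])
            outcomes.vfd_correlations(frame, vfd).to_csv(
                out / "vfd_correlations.csv", index=False
            )
            mv = outcomes.mv_duration_model(
                scores.to_numpy(dtype=float), frame["mv_days"], y
            )
            report["mv_duration"] = {
                "slope": mv.slope,
                "slope_p": mv.slope_p,
                "lack_of_fit_f": mv.lack_of_fit_f,
                "lack_of_fit_p": mv.lack_of_fit_p,
                "n_survivors": mv.n,
            }
            adeq = outcomes.cohort_adequacy(records, cap=config.cap_adequacy)
            adeq.to_csv(out / "adequacy.csv", index=False)
            sub = adeq["eligible"].to_numpy()
            inter = outcomes.interaction_test(
                adeq.loc[sub, "pct_received"],
                scores.to_numpy(dtype=float)[sub],
                y[sub],
            )
            inter.curves.to_csv(out / "interaction_curves.csv", index=False)
            report["interaction"] = {
                "n_eligible": inter.n,
                "lrt_statistic": inter.lrt_statistic,
                "lrt_p": inter.lrt_p,
                "coefficients": inter.coef.round(6).to_dict(),
            }
        except Exception as exc:
            log.error("outcome analysis failed: %s", exc)
            report["errors"]["outcomes"] = str(exc)

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
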