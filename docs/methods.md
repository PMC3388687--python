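# Methods

## The scoring model

The NUTRIC score is an additive integer-points risk model for 28-day
mortality in ICU patients. Each included variable contributes the
points of the band its value falls in; the total is the plain sum. The
packaged fixed table is:

| Variable | Band | Points |
|---|---|---|
| Age (y) | < 50 / 50–< 75 / ≥ 75 | 0 / 1 / 2 |
| APACHE II | < 15 / 15–< 20 / 20–< 28 / ≥ 28 | 0 / 1 / 2 / 3 |
| SOFA | < 6 / 6–< 10 / ≥ 10 | 0 / 1 / 2 |
| Comorbidities | 0–1 / ≥ 2 | 0 / 1 |
| Days hospital → ICU | < 1 / ≥ 1 | 0 / 1 |
| IL-6 (pg/mL) | < 400 / ≥ 400 | 0 / 1 |

All bands are half-open `[a, b)`. The APACHE II value 28 therefore
scores 3 points; published renderings of this row are ambiguous
("20-28" next to "≥28"), and this package resolves the overlap with
the same half-open convention used everywhere else. "1+" days means
any fractional pre-ICU stay ≥ 1.0 day. IL-6 is optional: when absent
the row is omitted and the total runs 0–9; dropping IL-6 can never
raise a score.

## Derivation pipeline

1. **Categorization** (`nutric.prep`). Continuous candidates are cut at
   their empirical 20/40/60/80th percentiles (linear-interpolation
   "type 7" percentiles; the convention is not prescribed by the
   procedure and the downstream integer points are insensitive to it on
   non-degenerate data). Ties straddling a cut-point all fall to the
   upper category by the half-open rule. Comorbidity count keeps its
   integer levels 0–5. Sparse nutrition-history candidates are
   dichotomized: BMI < 20 vs other; any reported weight loss vs
   none-or-unknown; reported < 100% oral intake vs full-or-unknown. A
   sensitivity mode recodes *missing* history as at-risk. Missing BMI
   falls in "other" — an implementer's extension flagged in the
   categorization manifest, since the original handling is unstated.
2. **Single-predictor fits** (`nutric.derivation.fit_category_logit`).
   Each categorized candidate is fit alone by maximum likelihood
   (statsmodels Newton IRLS) against mortality. Because the predictor
   is saturated-categorical, the MLE equals the closed-form count log
   odds ratio — the test suite holds the iterative fit to that oracle
   at 1e-6. A category with zero deaths or zero survivors has no
   finite MLE; it is reported as ±inf with a sparse flag, and in the
   pipeline such categories are pooled with their lower neighbour
   (upper for the first category) before refitting. Firth-penalized
   fitting was considered and rejected: pooling mirrors the collapsing
   step and keeps the count oracle exact.
3. **Points** (`assign_points`). Logits are re-referenced so the
   minimum-logit (lowest-risk) category is the reference, then rounded
   half-away-from-zero. Re-referencing guarantees non-negative points.
4. **Collapse and rounding** (`collapse_and_round`). Adjacent
   equal-point categories merge; each surviving interior cut-point is
   snapped to the nearest value with at most two significant decimal
   digits (equidistant candidates resolve toward the smaller
   magnitude), matching the published style of cut-points such as 20,
   28, 75 and 400. Snapping that would reorder or collide boundaries
   falls back to the exact value with a warning; exact boundaries are
   always kept in the table metadata.
5. **Selection** (`select_variables`). Phase 1 removes candidates with
   likelihood-ratio p > 0.2 or all-zero points. Phase 2 is a greedy
   backward pass considering the weakest candidate (largest p) first: a
   variable is dropped when its inclusion raises the total score's
   c-index by ≤ 0.001. The tolerance is deliberately conservative —
   an inflammation marker contributing a c-gain of ~0.007 survives it —
   and is configurable. Whether the original selection was greedy,
   simultaneous or judgment-guided is unknowable from the outside;
   greedy-backward is this package's documented choice, and on
   half-samples it can legitimately produce degenerate tables.

`ScoreDeriver` wraps the chain as a scikit-learn estimator (`fit`,
`predict`, `get_params`/`set_params`, `clone`-compatible), so the
deriver composes with sklearn model selection.

## Validation and outcome analyses

* **c-index**: tie-aware all-pairs concordance computed through average
  ranks (Mann–Whitney U); exactly equals brute-force pair counting.
  Reading: ≥ 0.90 excellent, 0.70–0.89 adequate, < 0.70 poor.
* **R²**: Cox–Snell `1 − exp(2(L₀ − L₁)/n)` and its Nagelkerke
  max-rescaling by `1 − exp(2L₀/n)`.
* **Hosmer–Lemeshow**: deciles of predicted risk with tied
  probabilities kept together (group count shrinks as needed, < 3 is an
  error), statistic `Σ (O−E)²/(E(1−E/n))`, df = g − 2. Groups with
  expected counts < 5 trigger a warning but the test is still reported.
* **Split-half cross-validation**: simple (outcome-unstratified) random
  50/50 partition; the full derivation re-runs independently in each
  half and each half-table is scored on the held-out half. Per-half
  derivation failures are recorded, not fatal.
* **VIF**: `1/(1 − R²)` from OLS of each component variable on the
  rest; exact collinearity reports +inf with a warning.
* **Model comparison**: logistic fits of (i) the total score as a
  single continuous predictor, (ii) age + APACHE II + SOFA, (iii) all
  six component variables, (iv) all components minus inflammation
  markers. Separation is detected (Newton failure), flagged as
  non-converged, and never silently "fixed".
* **MV duration**: OLS of MV days on the score among 28-day survivors,
  with the classical pure-error lack-of-fit F over replicate groups at
  each score value (k − 2 and n − k df).
* **Ventilator-free days**: VFD = 28 − min(MV days, 28) for survivors
  and 0 for 28-day decedents. The zero-for-decedents convention is not
  universal, so it is configurable; the default matches pooled-cohort
  correlation analyses.
* **Nutritional adequacy**: 100 × mean(daily kcal received over counted
  days) / prescribed kcal/day, where counted days are the collected ICU
  days (≤ 14) minus the final partial day unless that day is day 14.
  The prescription is a single baseline value, so mean-over-days and
  total-over-total coincide. Adequacy is not capped by default
  (overfeeding is representable); `cap=100` gives the capped
  sensitivity variant.
* **Effect modification**: on the subset that started MV within 48 h
  and stayed ≥ 3 days, logistic mortality models with and without the
  intake × score product (both continuous) are compared by a 1-df LRT.
  Predicted-mortality curves with delta-method 95% CIs are evaluated at
  the median score of the 0–5 and 6–10 groups, since the model is
  continuous but the conventional display groups scores. Whether the
  original subset analysis used the 6-variable or IL-6-free score is
  unstated; the full score is the default, with the IL-6-free variant a
  flag away.

## Synthetic cohort generator

`SyntheticConfig`/`simulate_cohort` emulate a mixed tertiary-care ICU
population: truncated-normal age (median ≈ 64), discretized-gamma
APACHE II (≈ 21) and SOFA (≈ 7), a mixture of near-zero and lognormal
pre-ICU hospital days (median ≈ 0.4), categorical comorbidity count
(27% with 0–1), lognormal BMI and inflammation markers, ~71% missing
nutrition history (matching the completeness a bedside history
realistically achieves; optionally missing-not-at-random with at-risk
histories harder to obtain), and per-patient Beta(5, 2.2) adequacy of
a normal ~1800 kcal/day prescription with lognormal day-to-day noise.

Mortality is logistic in the *banded* true score at 0.7 log-odds per
point (intercept −4.83, calibrated so the defaults give ≈ 23% 28-day
mortality and a fixed-score c-index near 0.75 — the "adequate" range a
real score of this kind occupies). For patients with a substantive
early ICU course (MV within 48 h and ≥ 3 ICU days — the subset the
interaction analysis targets, ~35–40% of patients) the linear predictor
adds `(adequacy% − 70) × (0.13 − 0.03 × score)`: feeding adequacy is
protective above score ≈ 4 and mildly harmful below, sized so a
single default cohort typically yields an interaction LRT p of order
0.001–0.01 at an eligible n ≈ 211. MV days among all patients follow
`N(1 + 1.2·score, 3.5²)` clipped to [0, 28]; ICU stay is lognormal plus
0.3 × MV days.

Every stream derives deterministically from `(seed, variable-id)`, so
one seed fixes the cohort exactly and adding a variable never perturbs
the others. The generator reproduces marginals and the
predictor→outcome structure only: it does **not** correlate admission
variables with each other (real APACHE II contains age), produce
longitudinal biomarker series, or model censoring of MV duration by
death. Passing tests therefore demonstrate correctness of the
*pipeline*, not that any real cohort would yield the same table —
e.g. single-predictor marginal associations in real data borrow
strength from predictor correlations that the generator omits.

## Simulation studies (`nutric.studies`)

* **Point recovery**: each replicate draws a 5,000-patient cohort of
  predictors, places integer log-odds targets shaped like the published
  table on each variable's own quintile/integer categories (baseline
  intercept −1.5, chosen to balance the outcome cells; per-category
  logit SE ≈ 0.1, far from the 0.5 rounding boundary), draws mortality
  from that single-variable model and runs the full
  binning → fit → points → collapse chain. The targets are placed one
  variable at a time because a single-predictor fit estimates a
  *marginal* association: under a joint outcome model,
  non-collapsibility of the odds ratio attenuates every marginal logit
  ≈ 25% below its conditional value, so integer conditional targets are
  not the estimand the pipeline computes. Recovery succeeds in ≈ 99%
  of replicates.
* **Retention**: on joint-model cohorts at one log-odds per point (with
  the intake modifiers nulled to isolate the score structure), all six
  true variables are retained and an unrelated standard-normal
  candidate is excluded.
* **Type-I error**: Hosmer–Lemeshow under a refitted correctly
  specified model (n = 1,000), the pure-error lack-of-fit F under a
  truly linear mean (n = 400), and the interaction LRT under a null
  generator (eligible n ≈ 211) all reject near the nominal 5% over
  hundreds of replicates. The interaction LRT runs ≈ 6–7% — the
  familiar small-sample inflation of a 1-df LRT with ~50 events.

## Numerical conventions and degenerate inputs

Rounding of logits is half-away-from-zero ("rounded to whole numbers"
does not fix the half case). Logistic fits use Newton/IRLS with a 1e-8
log-likelihood tolerance and a 100-iteration cap. Quintile binning
requires ≥ 5 distinct values and directs sparser variables to
dichotomization. `quintile_bin` deduplicates tied cut-points; empty
Hosmer–Lemeshow quantile groups (possible with heavily tied
predictions) are skipped. The pipeline's report bundle contains no
timestamps, so equal configurations produce byte-identical output.

## Limitations

* The fixed table is a faithful transcription of the published score;
  the derivation pipeline re-derives *a* score from data and on
  small samples (n ≈ 300) legitimately produces noisy, non-monotone or
  degenerate tables — as split-sample derivations of this kind do.
* Cohort sizes in the test suite (598–5,000) and replicate counts
  (100–500) were chosen so the whole suite runs in a few minutes on one
  CPU while keeping Monte-Carlo error well inside the asserted bands.
* The generator's independence assumptions understate real-world
  collinearity; VIFs on synthetic cohorts are near 1, lower than a real
  cohort's (where APACHE II alone can reach ~1.6).
* No multiple imputation: missingness is handled by the recoding rules
  above, as in the original procedure.
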