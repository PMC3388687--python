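"""Synthetic ICU cohort generator.

Generates cohorts with the statistical structure the derivation and
validation pipeline assumes: admission variables with realistic
marginal distributions for a mixed medical-surgical ICU population,
28-day mortality drawn from a logistic model on the banded (true)
risk score with an intake x score interaction, MV duration increasing
in the true score among survivors, and per-patient nutritional
adequacy. It emulates marginals and the predictor-to-outcome structure
only — no attempt is made at realistic joint correlations between the
admission variables, nor at longitudinal biomarker series.

Every draw flows from a single integer seed; each variable uses a
deterministic sub-stream, so adding a variable never perturbs the
others.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .calculator import _BANDS
from .cohort import PatientRecord

__all__ = ["SyntheticConfig", "ConfigError", "simulate_cohort", "simulate_frame", "true_score"]


class ConfigError(ValueError):
    pass


# fixed sub-stream ids: adding a variable must not perturb the others
_STREAMS = {
    "age": 1,
    "apache2": 2,
    "sofa": 3,
    "days_hosp_to_icu": 4,
    "n_comorbid": 5,
    "bmi": 6,
    "il6": 7,
    "crp": 8,
    "pct": 9,
    "oral_intake_pct": 10,
    "weight_loss_pct": 11,
    "adequacy": 12,
    "mortality": 13,
    "mv": 14,
    "icu": 15,
    "energy": 16,
    "missing": 17,
}


@dataclass
class SyntheticConfig:
    """Distributions, outcome coefficients and the seed of a simulated
    cohort.

    The marginal parameters target the admission profile of a mixed
    tertiary-care ICU population (median age ~64, APACHE II ~21,
    SOFA ~7, BMI ~26.5, pre-ICU hospital stay ~0.4 days, ~23% 28-day
    mortality). ``outcome_beta`` maps each score variable to per-band
    log-odds increments; ``None`` uses the published point values times
    ``calibration`` log-odds per point.
    """

    n: int = 598
    seed: int = 0

    # marginals
    age_mean: float = 63.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (18.0, 100.0)
    apache2_shape: float = 7.5
    apache2_scale: float = 3.0
    sofa_shape: float = 9.0
    sofa_scale: float = 0.85
    days_zero_frac: float = 0.5  # admitted to ICU within ~12 h of hospital
    days_zero_max: float = 0.4
    days_ln_mu: float = 0.79  # log-days of the delayed-admission component
    days_ln_sigma: float = 1.0
    comorbid_probs: tuple[float, ...] = (0.10, 0.17, 0.22, 0.26, 0.17, 0.08)
    bmi_ln_mu: float = 3.277  # log kg/m^2
    bmi_ln_sigma: float = 0.22
    il6_ln_mu: float = 4.44  # log pg/mL
    il6_ln_sigma: float = 1.4
    crp_ln_mu: float = 4.70  # log mg/L
    crp_ln_sigma: float = 0.75
    pct_ln_mu: float = 0.34  # log ng/mL
    pct_ln_sigma: float = 1.6

    # missingness (probability the value is unrecorded)
    p_missing_history: float = 0.71  # oral intake / weight loss
    p_missing_bmi: float = 0.05
    p_missing_marker: float = 0.03  # il6 / crp / pct
    missing_mode: str = "mcar"  # or "mnar_worse"

    # mortality model on the banded true score
    outcome_intercept: float = -4.83
    outcome_beta: dict[str, list[float]] | None = None
    calibration: float = 0.7  # log-odds per published point
    adequacy_main: float = 0.13  # per % received, at score 0, exposed subset
    adequacy_interaction: float = -0.03  # per % x point
    adequacy_center: float = 70.0

    # nutrition delivery and MV / ICU stay
    adequacy_beta: tuple[float, float] = (5.0, 2.2)
    daily_noise_sigma: float = 0.2
    energy_mean: float = 1800.0
    energy_sd: float = 250.0
    mv_intercept: float = 1.0
    mv_slope: float = 1.2
    mv_sd: float = 3.5
    mv48_base: float = 0.22
    mv48_slope: float = 0.04
    icu_ln_mu: float = 1.6  # log days
    icu_ln_sigma: float = 0.8

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        probs = [
            self.days_zero_frac,
            self.p_missing_history,
            self.p_missing_bmi,
            self.p_missing_marker,
            *self.comorbid_probs,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(self.comorbid_probs) - 1.0) > 1e-9:
            raise ConfigError("comorbid_probs must sum to 1")
        if any(
            s <= 0
            for s in (
                self.age_sd,
                self.apache2_shape,
                self.apache2_scale,
                self.sofa_shape,
                self.sofa_scale,
                self.days_ln_sigma,
                self.bmi_ln_sigma,
                self.il6_ln_sigma,
            )
        ):
            raise ConfigError("distribution scale parameters must be positive")
        if self.missing_mode not in ("mcar", "mnar_worse"):
            raise ConfigError(f"unknown missing_mode '{self.missing_mode}'")

    def band_betas(self) -> dict[str, np.ndarray]:
        """Per-band mortality log-odds increments for each score variable."""
        if self.outcome_beta is not None:
            return {v: np.asarray(b, dtype=float) for v, b in self.outcome_beta.items()}
        return {
            var: self.calibration * np.asarray(pts, dtype=float)
            for var, _, pts in _BANDS
        }

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("age_range", "comorbid_probs", "adequacy_beta"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def _truncnorm(rng, mean, sd, lo, hi, n):
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def true_score(values: dict[str, np.ndarray]) -> np.ndarray:
    """Banded total score of the generating model (published bands)."""
    total = np.zeros(values["age"].shape, dtype=int)
    for var, cuts, pts in _BANDS:
        total += np.asarray(pts)[np.searchsorted(cuts, values[var], side="right")]
    return total


def _band_contribution(values: dict[str, np.ndarray], betas: dict[str, np.ndarray]) -> np.ndarray:
    lin = np.zeros(values["age"].shape)
    for var, cuts, _ in _BANDS:
        if var in betas:
            lin += betas[var][np.searchsorted(cuts, values[var], side="right")]
    return lin


def simulate_cohort(config: SyntheticConfig) -> list[PatientRecord]:
    """Draw a reproducible cohort of :class:`PatientRecord`."""
    cfg = config
    cfg.validate()
    n = cfg.n

    values: dict[str, np.ndarray] = {}
    values["age"] = _truncnorm(
        _rng(cfg, "age"), cfg.age_mean, cfg.age_sd, *cfg.age_range, n
    )
    values["apache2"] = np.floor(
        _rng(cfg, "apache2").gamma(cfg.apache2_shape, cfg.apache2_scale, size=n)
    ).astype(int)
    values["sofa"] = np.floor(
        _rng(cfg, "sofa").gamma(cfg.sofa_shape, cfg.sofa_scale, size=n)
    ).astype(int)
    rd = _rng(cfg, "days_hosp_to_icu")
    early = rd.random(n) < cfg.days_zero_frac
    values["days_hosp_to_icu"] = np.where(
        early,
        rd.uniform(0, cfg.days_zero_max, size=n),
        rd.lognormal(cfg.days_ln_mu, cfg.days_ln_sigma, size=n),
    )
    values["n_comorbid"] = _rng(cfg, "n_comorbid").choice(
        6, size=n, p=cfg.comorbid_probs
    )
    values["bmi"] = _rng(cfg, "bmi").lognormal(cfg.bmi_ln_mu, cfg.bmi_ln_sigma, n)
    values["il6"] = _rng(cfg, "il6").lognormal(cfg.il6_ln_mu, cfg.il6_ln_sigma, n)
    values["crp"] = _rng(cfg, "crp").lognormal(cfg.crp_ln_mu, cfg.crp_ln_sigma, n)
    values["pct"] = _rng(cfg, "pct").lognormal(cfg.pct_ln_mu, cfg.pct_ln_sigma, n)

    # nutrition history: mostly full intake, the rest concentrated low
    rh = _rng(cfg, "oral_intake_pct")
    u = rh.random(n)
    oral = np.where(
        u < 0.40, 100.0, np.where(u < 0.85, rh.uniform(0, 10, n), rh.uniform(10, 100, n))
    )
    rw = _rng(cfg, "weight_loss_pct")
    wl = np.where(rw.random(n) < 0.76, 0.0, rw.lognormal(np.log(5.0), 0.8, n))

    # nutrition delivery
    ra = _rng(cfg, "adequacy")
    adequacy = ra.beta(*cfg.adequacy_beta, size=n)  # fraction of prescription
    energy = np.clip(
        _rng(cfg, "energy").normal(cfg.energy_mean, cfg.energy_sd, n), 1000, 3200
    )

    score = true_score(values)
    rmv = _rng(cfg, "mv")
    mv_days = np.clip(
        rmv.normal(cfg.mv_intercept + cfg.mv_slope * score, cfg.mv_sd), 0.0, 28.0
    )
    mv48 = (rmv.random(n) < np.clip(cfg.mv48_base + cfg.mv48_slope * score, 0, 0.95)).astype(int)
    ricu = _rng(cfg, "icu")
    icu_days = np.clip(
        ricu.lognormal(cfg.icu_ln_mu, cfg.icu_ln_sigma, n) + 0.3 * mv_days, 0.5, 60.0
    )

    # mortality: logistic in the banded score; nutritional intake modifies
    # the risk only for patients with a substantive early ICU course (the
    # subset the effect-modification analysis targets)
    lin = cfg.outcome_intercept + _band_contribution(values, cfg.band_betas())
    a_pct = 100.0 * adequacy
    exposed = (mv48 == 1) & (np.round(icu_days, 2) >= 3)
    lin += exposed * (a_pct - cfg.adequacy_center) * (
        cfg.adequacy_main + cfg.adequacy_interaction * score
    )
    mort = (_rng(cfg, "mortality").random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(int)

    # missingness
    rm = _rng(cfg, "missing")
    if cfg.missing_mode == "mnar_worse":
        # histories of at-risk patients are harder to obtain
        at_risk = (oral < 100) | (wl > 0)
        p_hist = np.where(at_risk, min(cfg.p_missing_history + 0.1, 1.0),
                          max(cfg.p_missing_history - 0.1, 0.0))
    else:
        p_hist = np.full(n, cfg.p_missing_history)
    hist_missing = rm.random(n) < p_hist
    bmi_missing = rm.random(n) < cfg.p_missing_bmi
    il6_missing = rm.random(n) < cfg.p_missing_marker
    crp_missing = rm.random(n) < cfg.p_missing_marker
    pct_missing = rm.random(n) < cfg.p_missing_marker

    re = _rng(cfg, "energy")  # separate draws for daily noise
    records: list[PatientRecord] = []
    for i in range(n):
        icu_i = float(round(icu_days[i], 2))
        n_days = min(int(np.ceil(icu_i)), 14)
        noise = re.lognormal(
            -0.5 * cfg.daily_noise_sigma**2, cfg.daily_noise_sigma, n_days
        )
        daily = (energy[i] * adequacy[i] * noise).round(1).tolist()
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                age=float(round(values["age"][i], 1)),
                apache2=int(values["apache2"][i]),
                sofa=int(values["sofa"][i]),
                days_hosp_to_icu=float(round(values["days_hosp_to_icu"][i], 2)),
                n_comorbid=int(values["n_comorbid"][i]),
                mort28=int(mort[i]),
                mv_start_within_48h=int(mv48[i]),
                mv_days=float(round(mv_days[i], 1)),
                icu_days=icu_i,
                energy_prescribed=float(round(energy[i], 0)),
                energy_received_daily=daily,
                bmi=None if bmi_missing[i] else float(round(values["bmi"][i], 1)),
                il6=None if il6_missing[i] else max(float(round(values["il6"][i], 1)), 0.1),
                crp=None if crp_missing[i] else max(float(round(values["crp"][i], 1)), 0.1),
                pct=None if pct_missing[i] else max(float(round(values["pct"][i], 2)), 0.01),
                oral_intake_pct=None if hist_missing[i] else float(round(oral[i], 0)),
                weight_loss_pct=None if hist_missing[i] else float(round(wl[i], 1)),
            )
        )
    return records


def simulate_frame(config: SyntheticConfig):
    """Cohort as a DataFrame (convenience wrapper)."""
    from .cohort import cohort_to_frame

    return cohort_to_frame(simulate_cohort(config))
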