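"""Seeded synthetic cohorts with the statistical structure of an elderly
fragility hip fracture population.

The generator emulates the marginal profile of a surgical fragility-fracture
cohort (median age 83 with wide spread, 77.8% female, near-universal
multimorbidity, 46.9% ASA > 2, 29.0% one-year mortality) and induces
dependence between covariates through a single latent frailty variable:
frailer patients are older, sicker, more dependent, more anemic, and die
earlier.  Outcomes follow a logistic model on standardized covariates whose
intercept is auto-calibrated to the target one-year mortality; event times
are Weibull with shape < 1 so the hazard concentrates in the first year,
censored administratively at the maximum follow-up with uniform accrual.

Every draw flows from one ``numpy`` Generator, so a seed fixes the cohort
field-for-field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
from scipy import optimize, stats

from .cohort_io import (
    Cohort,
    FractureType,
    Malignancy,
    MentalStatus,
    Mobility,
    PatientRecord,
    Residence,
    Sex,
)

__all__ = ["CohortSimConfig", "generate_cohort", "generate_calibrated_outcomes"]


_DEFAULT_COMORBIDITY_PREVALENCE: dict[str, float] = {
    "copd": 0.14,
    "pneumonia": 0.09,
    "ischemic_heart_disease": 0.18,
    "prior_mi": 0.05,
    "arrhythmia": 0.13,
    "chf": 0.11,
    "malnutrition": 0.07,
    "electrolyte_disorder": 0.16,
    "renal_disease": 0.12,
    "liver_disease_moderate_severe": 0.02,
    "deficiency_anemia": 0.22,
    "chronic_pulmonary_disease": 0.16,
}

# outcome-model coefficients on standardized covariates (log-odds units)
_DEFAULT_OUTCOME_COEFS: dict[str, float] = {
    "age": 0.9,
    "male": 0.8,
    "asa": 0.5,
    "frailty": 0.6,
    "cognitive_impairment": 0.4,
    "n_comorbidities": 0.35,
    "hemoglobin": -0.3,
    "dependent_mobility": 0.4,
    "institutional_residence": 0.3,
    "malignancy": 0.4,
    "renal_disease": 0.25,
    "chf": 0.25,
    "pneumonia": 0.3,
    "malnutrition": 0.3,
    "nursing_care_certification": 0.2,
    "serum_urea": 0.2,
}


@dataclass
class CohortSimConfig:
    """Study-condition parameters for the synthetic cohort."""

    n: int = 207
    seed: int = 0
    # age: shifted beta on [age_min, age_max]; quantile targets below
    age_min: int = 60
    age_max: int = 100
    age_median: float = 83.0
    # "iqr" preset: 71-95 read as the interquartile range (as printed);
    # "range" preset: 71-95 read as the overall range (quartiles ~78/88)
    age_spread: str = "iqr"
    p_female: float = 0.778
    p_asa_gt2: float = 0.469
    p_cognitive_impairment: float = 0.024
    p_institutional: float = 0.072
    p_dependent_mobility: float = 0.232
    p_two_plus_comorbidities: float = 0.971
    p_confusion: float = 0.09
    p_nursing_certification: float = 0.25
    p_in_hospital_fracture: float = 0.015
    comorbidity_prevalence: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_PREVALENCE)
    )
    # malignancy category probabilities: none, skin, other, metastatic
    p_malignancy: tuple[float, float, float, float] = (0.885, 0.010, 0.080, 0.025)
    # fracture site mix: femoral neck, pertrochanteric, subtrochanteric
    p_fracture: tuple[float, float, float] = (0.46, 0.44, 0.10)
    # latent-frailty loading shared by the frailty-linked covariates
    frailty_rho: float = 0.45
    age_frailty_rho: float = 0.35
    outcome_coefs: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_COEFS)
    )
    target_mortality_1y: float = 0.290
    weibull_shape: float = 0.65      # < 1: hazard concentrated early
    max_followup_months: float = 62.0
    # fractions of deliberately ineligible records (for filter exercises)
    frac_nonsurgical: float = 0.0
    frac_pathological: float = 0.0
    frac_t_above_threshold: float = 0.0
    frac_lost_to_followup: float = 0.0


@lru_cache(maxsize=8)
def _beta_params(q25: float, q50: float, q75: float) -> tuple[float, float]:
    """Fit Beta(a, b) to three target quantiles on (0, 1) by least squares."""

    def loss(logab):
        a, b = np.exp(logab)
        q = stats.beta.ppf([0.25, 0.5, 0.75], a, b)
        return np.sum((q - np.array([q25, q50, q75])) ** 2)

    res = optimize.minimize(loss, x0=np.log([2.0, 2.0]), method="Nelder-Mead")
    a, b = np.exp(res.x)
    return float(a), float(b)


def _latent_indicator(rng, z, p, rho):
    """Bernoulli(p) marginally, loading on latent frailty z with weight rho."""
    u = rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(len(z))
    return u > stats.norm.ppf(1 - p)


def _latent_categorical(rng, z, cum_probs, rho):
    """Ordinal categorical, later categories reached at higher frailty."""
    u = rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(len(z))
    cuts = stats.norm.ppf(np.clip(cum_probs[:-1], 1e-12, 1 - 1e-12))
    return np.searchsorted(cuts, u, side="right")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: CohortSimConfig | None = None) -> Cohort:
    """Draw a reproducible synthetic cohort satisfying all record invariants."""
    cfg = config or CohortSimConfig()
    if cfg.n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < cfg.target_mortality_1y < 1:
        raise ValueError("target mortality must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    z = rng.standard_normal(n)  # latent frailty
    rho = cfg.frailty_rho

    # --- age: beta quantile-matched, positively coupled to frailty
    span = cfg.age_max - cfg.age_min
    if cfg.age_spread == "iqr":
        q25, q75 = 71.0, 95.0
    elif cfg.age_spread == "range":
        q25, q75 = 78.0, 88.0
    else:
        raise ValueError("age_spread must be 'iqr' or 'range'")
    a, b = _beta_params(
        (q25 - cfg.age_min) / span,
        (cfg.age_median - cfg.age_min) / span,
        (q75 - cfg.age_min) / span,
    )
    ra = cfg.age_frailty_rho
    u_age = stats.norm.cdf(ra * z + math.sqrt(1 - ra**2) * rng.standard_normal(n))
    age = np.floor(cfg.age_min + span * stats.beta.ppf(u_age, a, b)).astype(int)
    age = np.clip(age, cfg.age_min, cfg.age_max)

    # --- demographics and frailty-linked covariates
    female = rng.random(n) < cfg.p_female
    p2 = cfg.p_asa_gt2
    asa_cum = np.array([0.05, 1 - p2, 1 - p2 + 0.85 * p2, 1 - 0.02 * p2, 1.0])
    asa = 1 + _latent_categorical(rng, z, asa_cum, rho)
    cognitive = _latent_indicator(rng, z, cfg.p_cognitive_impairment, rho)
    p_inst = cfg.p_institutional
    res_cum = np.array(
        [1 - p_inst - 0.058, 1 - p_inst, 1 - p_inst + 0.70 * p_inst,
         1 - 0.10 * p_inst, 1.0]
    )
    residence_idx = _latent_categorical(rng, z, res_cum, rho)
    residence_levels = [
        Residence.OWN_HOME,
        Residence.SHELTERED_OR_ASSISTED,
        Residence.LONG_TERM_CARE,
        Residence.REHABILITATION,
        Residence.ACUTE_WARD,
    ]
    p_dep = cfg.p_dependent_mobility
    mob_cum = np.array(
        [0.78 * (1 - p_dep), 1 - p_dep, 1 - p_dep + 0.52 * p_dep,
         1 - 0.17 * p_dep, 1.0]
    )
    mobility_idx = _latent_categorical(rng, z, mob_cum, rho)
    mobility_levels = [
        Mobility.NO_AIDS,
        Mobility.ONE_AID,
        Mobility.TWO_AIDS_OR_FRAME,
        Mobility.REQUIRES_ACCOMPANIMENT,
        Mobility.UNABLE_TO_WALK,
    ]
    confusion = _latent_indicator(rng, z, cfg.p_confusion, rho) | cognitive

    two_plus = _latent_indicator(rng, z, cfg.p_two_plus_comorbidities, rho)
    n_comorb = np.where(
        two_plus, 2 + rng.poisson(1.8, n), rng.integers(0, 2, n)
    ).astype(int)

    comorb: dict[str, np.ndarray] = {
        name: _latent_indicator(rng, z, p, rho)
        for name, p in cfg.comorbidity_prevalence.items()
    }
    malig_idx = _latent_categorical(rng, z, np.cumsum(cfg.p_malignancy), rho)
    malig_levels = [Malignancy.NONE, Malignancy.SKIN, Malignancy.OTHER, Malignancy.METASTATIC]

    hemoglobin = np.round(np.clip(12.3 - 0.6 * z + 1.4 * rng.standard_normal(n), 5.0, None), 1)
    urea = np.round(np.exp(1.75 + 0.18 * z + 0.35 * rng.standard_normal(n)), 1)

    age_pts = np.select([age >= 80, age >= 70, age >= 60], [4, 3, 2], default=1)
    cci = (age_pts + rng.poisson(0.9 * np.exp(0.4 * z))).astype(int)

    nursing = _latent_indicator(rng, z, cfg.p_nursing_certification, rho)
    in_hospital = rng.random(n) < cfg.p_in_hospital_fracture

    frac_idx = rng.choice(3, size=n, p=np.asarray(cfg.p_fracture) / sum(cfg.p_fracture))
    frac_levels = [FractureType.FEMORAL_NECK, FractureType.PERTROCHANTERIC,
                   FractureType.SUBTROCHANTERIC]
    fracture = np.array([frac_levels[i] for i in frac_idx], dtype=object)
    pathological = rng.random(n) < cfg.frac_pathological
    fracture[pathological] = FractureType.PATHOLOGICAL

    t_score = np.round(-2.5 - np.abs(rng.normal(0.7, 0.5, n)), 1)
    t_above = rng.random(n) < cfg.frac_t_above_threshold
    t_score[t_above] = np.round(-2.4 + np.abs(rng.normal(0.8, 0.5, t_above.sum())), 1)

    surgical = rng.random(n) >= cfg.frac_nonsurgical
    lost = rng.random(n) < cfg.frac_lost_to_followup

    start = date(2018, 1, 1)
    horizon = (date(2022, 10, 31) - start).days
    admission = [start + timedelta(days=int(d)) for d in rng.integers(0, horizon + 1, n)]

    # --- outcome model: logistic on standardized covariates, calibrated intercept
    dependent = mobility_idx >= 2
    institutional = residence_idx >= 2
    coefs = dict(cfg.outcome_coefs)
    covariates = {
        "age": _standardize(age.astype(float)),
        "male": _standardize((~female).astype(float)),
        "asa": _standardize(asa.astype(float)),
        "frailty": z,
        "cognitive_impairment": _standardize(cognitive.astype(float)),
        "n_comorbidities": _standardize(n_comorb.astype(float)),
        "hemoglobin": _standardize(hemoglobin),
        "dependent_mobility": _standardize(dependent.astype(float)),
        "institutional_residence": _standardize(institutional.astype(float)),
        "malignancy": _standardize(malig_idx.astype(float)),
        "renal_disease": _standardize(comorb["renal_disease"].astype(float)),
        "chf": _standardize(comorb["chf"].astype(float)),
        "pneumonia": _standardize(comorb["pneumonia"].astype(float)),
        "malnutrition": _standardize(comorb["malnutrition"].astype(float)),
        "nursing_care_certification": _standardize(nursing.astype(float)),
        "serum_urea": _standardize(np.log(urea)),
    }
    eta = np.zeros(n)
    for name, beta in coefs.items():
        if name not in covariates:
            raise ValueError(f"unknown outcome coefficient {name!r}")
        eta += beta * covariates[name]

    def mean_mortality(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    lo, hi = -30.0, 30.0
    if not mean_mortality(lo) < cfg.target_mortality_1y < mean_mortality(hi):
        raise ValueError("infeasible mortality calibration target")
    b0 = optimize.brentq(
        lambda b: mean_mortality(b) - cfg.target_mortality_1y, lo, hi, xtol=1e-10
    )
    p1y = 1.0 / (1.0 + np.exp(-(b0 + eta)))

    # --- survival times: Weibull scaled so P(T <= 12 months) = p1y
    k = cfg.weibull_shape
    ONE_YEAR = 12.0
    scale = ONE_YEAR / (-np.log(1 - p1y)) ** (1 / k)
    t_death = scale * (-np.log(rng.random(n))) ** (1 / k)
    censor = rng.uniform(ONE_YEAR, cfg.max_followup_months, n)
    followup = np.minimum(t_death, censor)
    event = t_death <= censor
    dead_1y = t_death <= ONE_YEAR  # censoring starts after 12 months

    records = []
    for i in range(n):
        is_lost = bool(lost[i])
        fu = float(np.round(rng.uniform(0.5, ONE_YEAR) if is_lost else followup[i], 2))
        records.append(
            PatientRecord(
                patient_id=f"SYN{i:05d}",
                age=int(age[i]),
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                residence=residence_levels[residence_idx[i]],
                mobility=mobility_levels[mobility_idx[i]],
                mental_status=(
                    MentalStatus.SLIGHT_CONFUSION if confusion[i] else MentalStatus.ALERT
                ),
                cognitive_impairment=bool(cognitive[i]),
                asa_grade=int(asa[i]),
                hemoglobin=float(hemoglobin[i]),
                serum_urea=float(urea[i]),
                cci=int(cci[i]),
                n_comorbidities=int(n_comorb[i]),
                fracture_type=fracture[i],
                in_hospital_fracture=bool(in_hospital[i]),
                nursing_care_certification=bool(nursing[i]),
                copd=bool(comorb["copd"][i]),
                pneumonia=bool(comorb["pneumonia"][i]),
                ischemic_heart_disease=bool(comorb["ischemic_heart_disease"][i]),
                prior_mi=bool(comorb["prior_mi"][i]),
                arrhythmia=bool(comorb["arrhythmia"][i]),
                chf=bool(comorb["chf"][i]),
                malnutrition=bool(comorb["malnutrition"][i]),
                electrolyte_disorder=bool(comorb["electrolyte_disorder"][i]),
                renal_disease=bool(comorb["renal_disease"][i]),
                liver_disease_moderate_severe=bool(
                    comorb["liver_disease_moderate_severe"][i]
                ),
                deficiency_anemia=bool(comorb["deficiency_anemia"][i]),
                chronic_pulmonary_disease=bool(comorb["chronic_pulmonary_disease"][i]),
                malignancy=malig_levels[malig_idx[i]],
                dxa_t_score=float(t_score[i]),
                treated_surgically=bool(surgical[i]),
                admission_date=admission[i],
                dead_1y=None if is_lost else bool(dead_1y[i]),
                followup_months=fu,
                lost_to_followup=is_lost,
            )
        )
    return Cohort(records=records, provenance=f"synthetic(seed={cfg.seed}, n={n})")


def generate_calibrated_outcomes(predicted, seed: int) -> np.ndarray:
    """Bernoulli outcomes drawn from the supplied probabilities (seeded).

    Test harness for calibration statistics: outcomes generated this way are,
    by construction, perfectly calibrated to ``predicted``.
    """
    p = np.asarray(predicted, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(p.shape) < p).astype(int)
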