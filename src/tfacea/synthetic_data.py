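"""Internally consistent GBD-style synthetic inputs.

The generator emulates the *structure* of Global Burden of Disease 2019
exports for Nigeria — 30 sex x 5-year-band strata, lognormal trans-fat
intake, an illness-death-consistent IHD epidemiology — without attempting to
match the country's actual values. The shapes are the simplest ones matching
the qualitative pattern:

* all-cause mortality: Gompertz, ``acm_base * exp(acm_slope * (age - 20))``,
  with a male excess factor;
* IHD incidence: log-linear in age with a male excess ratio;
* case fatality: constant ``case_fatality_level`` per year;
* prevalence: NOT sampled independently — it is the prevalence implied by
  the incidence and case fatality under the illness-death process, obtained
  by advancing the submodel from age 20, so the disease stage of the
  pipeline is self-consistent by construction;
* IHD mortality: case fatality x prevalence;
* population: exponentially declining with age, split equally by sex;
* intake means: uniform draws within ``intake_mean_range`` per stratum
  (deterministic given the seed), SD = CV x mean.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .data_model import (
    AGE_LOWER_BOUNDS,
    SEXES,
    CurrencyContext,
    PolicyCosts,
    StratifiedInputs,
)
from .disease import DiseaseRates, DiseaseState, step_disease

__all__ = ["SynthConfig", "generate_inputs", "generate_worked_toy"]


class SynthConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    #: Preintervention intake means drawn per stratum from this %E interval.
    intake_mean_range: tuple[float, float] = (0.25, 0.31)
    intake_cv: float = Field(default=0.35, gt=0)
    #: Gompertz all-cause mortality: rate at age 20 and log-slope per year.
    acm_base: float = Field(default=0.003, gt=0)
    acm_slope: float = Field(default=0.07, gt=0)
    acm_sex_ratio: float = Field(default=1.15, gt=0)
    #: Log-linear IHD incidence: rate at age 40, log-slope, male:female ratio.
    inc_at40: float = Field(default=6e-4, ge=0)
    inc_slope: float = Field(default=0.08, gt=0)
    inc_sex_ratio: float = Field(default=1.4, gt=0)
    case_fatality_level: float = Field(default=0.08, ge=0)
    #: Adult population size and exponential decline rate per year of age.
    pop_total: float = Field(default=9e7, gt=0)
    pop_decline: float = Field(default=0.045, gt=0)
    dw_ihd: float = Field(default=0.08, ge=0, le=1)
    other_yld_base: float = Field(default=0.06, ge=0)
    other_yld_slope: float = Field(default=0.001, ge=0)
    rr_per_2e: float = Field(default=1.23, gt=0)
    ln_rr_sd: float = Field(default=0.05, ge=0)
    ihd_incident_cost: float = Field(default=300.0, ge=0)
    ihd_prevalent_cost: float = Field(default=150.0, ge=0)
    nonihd_percap_base: float = Field(default=30.0, ge=0)
    nonihd_percap_slope: float = Field(default=0.015, ge=0)
    usd_to_ngn: float = Field(default=358.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        lo, hi = self.intake_mean_range
        if not (0 <= lo <= hi <= 2):
            raise ValueError("intake mean range must lie within [0, 2] %E")
        return self


def _default_policy() -> PolicyCosts:
    return PolicyCosts(
        gov_components=(
            ("legislation", "oneoff", 100_000.0, 20_000.0),
            ("nafdac_monitoring_enforcement", "annual", 150_000.0, 30_000.0),
            ("son_standards", "annual", 40_000.0, 8_000.0),
            ("cpc_campaigns", "annual", 50_000.0, 10_000.0),
        ),
        industry_products=331,
        industry_cost_per_product=42_500.0,
        industry_annual_frac=0.01,
    )


def _steady_state_prevalence(inc_by_band: np.ndarray, f: float) -> np.ndarray:
    """Prevalence at each band's entry age implied by the illness-death flow.

    Advances the submodel in single years from age 20 with band-constant
    incidence and case fatality; the starting prevalence approximates a
    decade of pre-adult exposure to the age-20 rates.
    """
    i0 = inc_by_band[0]
    p0 = 0.0
    if i0 + f > 0:
        p0 = i0 / (i0 + f) * (1.0 - math.exp(-10.0 * (i0 + f)))
    state = DiseaseState(s=1.0 - p0, c=p0, d=0.0)
    prev = np.zeros(len(AGE_LOWER_BOUNDS))
    for age in range(AGE_LOWER_BOUNDS[0], AGE_LOWER_BOUNDS[-1] + 1):
        band = (age - AGE_LOWER_BOUNDS[0]) // 5
        if age % 5 == 0:
            prev[band] = state.c / (state.s + state.c)
        state = step_disease(state, DiseaseRates(i=inc_by_band[band], f=f))
    return prev


def generate_inputs(cfg: SynthConfig | None = None) -> StratifiedInputs:
    """Generate a validated 30-strata input set, deterministic given the seed."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    ages = np.array(AGE_LOWER_BOUNDS, float)

    rows = []
    for sex in SEXES:
        male = sex == "male"
        acm = cfg.acm_base * np.exp(cfg.acm_slope * (ages - 20.0)) * (cfg.acm_sex_ratio if male else 1.0)
        inc = cfg.inc_at40 * np.exp(cfg.inc_slope * (ages - 40.0)) * (cfg.inc_sex_ratio if male else 1.0)
        f = cfg.case_fatality_level
        prev = _steady_state_prevalence(inc, f)
        if np.any(prev >= 1):
            raise ValueError("config implies IHD prevalence >= 1")
        ihd_mort = f * prev
        if np.any(ihd_mort > acm):
            raise ValueError("config implies IHD mortality exceeding all-cause mortality")
        weights = np.exp(-cfg.pop_decline * (ages - 20.0))
        pop = cfg.pop_total / 2.0 * weights / weights.sum()
        intake_mean = rng.uniform(*cfg.intake_mean_range, size=len(ages))
        for k, age_lo in enumerate(AGE_LOWER_BOUNDS):
            rows.append(
                {
                    "sex": sex,
                    "age_lo": age_lo,
                    "pop": pop[k],
                    "acm": acm[k],
                    "ihd_inc": inc[k],
                    "ihd_prev": prev[k],
                    "ihd_mort": ihd_mort[k],
                    "ihd_yld_rate": cfg.dw_ihd * prev[k],
                    "other_yld_rate": cfg.other_yld_base + cfg.other_yld_slope * (age_lo - 20),
                    "intake_mean": intake_mean[k],
                    "intake_sd": cfg.intake_cv * intake_mean[k],
                    "ihd_incident_min": 0.5 * cfg.ihd_incident_cost,
                    "ihd_incident_mode": cfg.ihd_incident_cost,
                    "ihd_incident_max": 2.0 * cfg.ihd_incident_cost,
                    "ihd_prevalent_min": 0.5 * cfg.ihd_prevalent_cost,
                    "ihd_prevalent_mode": cfg.ihd_prevalent_cost,
                    "ihd_prevalent_max": 2.0 * cfg.ihd_prevalent_cost,
                    "nonihd_percap": cfg.nonihd_percap_base
                    * math.exp(cfg.nonihd_percap_slope * (age_lo - 20)),
                }
            )
    strata = pd.DataFrame(rows).set_index(["sex", "age_lo"]).sort_index()
    rr = pd.DataFrame(
        {"age_lo": list(AGE_LOWER_BOUNDS), "rr_per_2e": cfg.rr_per_2e, "ln_rr_sd": cfg.ln_rr_sd}
    ).set_index("age_lo")
    return StratifiedInputs(
        strata=strata,
        rr=rr,
        policy=_default_policy(),
        currency=CurrencyContext(usd_to_ngn=cfg.usd_to_ngn),
    ).validate()


def generate_worked_toy() -> StratifiedInputs:
    """Tiny fixed 2-stratum input set with hand-checkable round numbers.

    One female and one male cohort entering at age 20 with constant all-cause
    mortality (0.01 and 0.02 per year) and no IHD at all, so the lifetable
    reduces to closed-form geometric survivorship: life expectancy at 20 is
    (1 + e^-m)/2 * (1 - e^-80m)/(1 - e^-m) years. Deterministic, identical
    across calls; used in docs and exact tests.
    """
    rows = []
    for sex, acm in (("female", 0.01), ("male", 0.02)):
        rows.append(
            {
                "sex": sex,
                "age_lo": 20,
                "pop": 1000.0,
                "acm": acm,
                "ihd_inc": 0.0,
                "ihd_prev": 0.0,
                "ihd_mort": 0.0,
                "ihd_yld_rate": 0.0,
                "other_yld_rate": 0.0,
                "intake_mean": 0.25,
                "intake_sd": 0.05,
                "ihd_incident_min": 100.0,
                "ihd_incident_mode": 100.0,
                "ihd_incident_max": 100.0,
                "ihd_prevalent_min": 50.0,
                "ihd_prevalent_mode": 50.0,
                "ihd_prevalent_max": 50.0,
                "nonihd_percap": 10.0,
            }
        )
    strata = pd.DataFrame(rows).set_index(["sex", "age_lo"]).sort_index()
    rr = pd.DataFrame(
        {"age_lo": list(AGE_LOWER_BOUNDS), "rr_per_2e": 1.25, "ln_rr_sd": 0.0}
    ).set_index("age_lo")
    policy = PolicyCosts(
        gov_components=(
            ("legislation", "oneoff", 1000.0, 200.0),
            ("monitoring", "annual", 100.0, 20.0),
        ),
        industry_products=10,
        industry_cost_per_product=100.0,
        industry_annual_frac=0.01,
    )
    return StratifiedInputs(strata=strata, rr=rr, policy=policy).validate(require_full=False)
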