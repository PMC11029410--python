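"""Multiple-cohort proportional multistate lifetable.

Each of the 30 sex x 5-year-band cohorts enters at the lower bound of its
band and is followed in single years of age until age 100. Within a cohort,
two arms share all inputs: the reference arm keeps the observed trans-fat
intake, the intervention arm runs the illness-death submodel with incidence
scaled by (1 - PIF). The lifetable recombines mortality as

    m_arm(a) = acm(a) - ihd_mort_input(a) + ihd_mortality_rate_arm(a),

i.e. the input IHD mortality embedded in all-cause mortality is swapped for
the submodel's arm-specific rate. Survivorship decays exponentially within
each year (l(a+1) = l(a) exp(-m)), person-years are trapezoidal, and each
person-year is weighted down by prevalent disability from IHD and from all
other causes to give health-adjusted life years (HALYs).

Rates are piecewise constant within single years of age, looked up from the
5-year bands by step function; ages 95+ use the last band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AGE_CEILING,
    AGE_LOWER_BOUNDS,
    Scenario,
    StratifiedInputs,
    horizon_years,
)
from .disease import (
    DiseaseRates,
    DiseaseState,
    derive_case_fatality,
    occupancy,
    step_disease,
)

__all__ = [
    "SexBandInputs",
    "ArmTrajectory",
    "CohortTrajectory",
    "band_inputs",
    "band_index",
    "run_cohort",
    "halys_for_year",
    "aggregate_population",
]

ARMS = ("reference", "intervention")


def band_index(age: float) -> int:
    """Index of the 5-year band providing rates at attained age ``age``."""
    return min(max((int(age) - AGE_LOWER_BOUNDS[0]) // 5, 0), len(AGE_LOWER_BOUNDS) - 1)


@dataclass
class SexBandInputs:
    """Per-band numpy views of one sex's inputs (index 0 = ages 20-24)."""

    sex: str
    pop: np.ndarray
    acm: np.ndarray
    ihd_inc: np.ndarray
    ihd_prev: np.ndarray
    ihd_mort: np.ndarray
    case_fatality: np.ndarray
    dw_ihd: np.ndarray
    other_yld: np.ndarray
    nonihd_percap: np.ndarray
    ihd_incident_cost: np.ndarray
    ihd_prevalent_cost: np.ndarray


def band_inputs(inputs: StratifiedInputs, sex: str) -> SexBandInputs:
    """Extract one sex's strata into aligned per-band arrays."""
    # Step-function band lookup: sparse inputs (e.g. the worked toy fixture)
    # clamp to the nearest available band.
    df = inputs.strata.xs(sex, level="sex").reindex(list(AGE_LOWER_BOUNDS)).ffill().bfill()
    if df.isna().any().any():
        raise ValueError(f"sex {sex!r}: no bands available")
    prev = df["ihd_prev"].to_numpy(float)
    mort = df["ihd_mort"].to_numpy(float)
    yld = df["ihd_yld_rate"].to_numpy(float)
    cf = derive_case_fatality(df).to_numpy(float)
    dw = np.where(prev > 0, np.divide(yld, prev, out=np.zeros_like(yld), where=prev > 0), 0.0)
    if np.any((dw < 0) | (dw > 1)):
        raise ValueError(f"sex {sex!r}: implied IHD disability weight outside [0, 1]")
    return SexBandInputs(
        sex=sex,
        pop=df["pop"].to_numpy(float),
        acm=df["acm"].to_numpy(float),
        ihd_inc=df["ihd_inc"].to_numpy(float),
        ihd_prev=prev,
        ihd_mort=mort,
        case_fatality=cf,
        dw_ihd=dw,
        other_yld=df["other_yld_rate"].to_numpy(float),
        nonihd_percap=df["nonihd_percap"].to_numpy(float),
        ihd_incident_cost=df["ihd_incident_mode"].to_numpy(float),
        ihd_prevalent_cost=df["ihd_prevalent_mode"].to_numpy(float),
    )


@dataclass
class ArmTrajectory:
    """Year-by-year lifetable quantities for one arm of one cohort."""

    alive: np.ndarray  # length n_years + 1, numbers alive at each birthday
    person_years: np.ndarray  # length n_years
    deaths: np.ndarray
    ihd_deaths: np.ndarray
    incident_cases: np.ndarray
    prevalent_py: np.ndarray
    halys: np.ndarray


@dataclass
class CohortTrajectory:
    sex: str
    entry_age: int
    ages: np.ndarray  # attained age at the start of each simulated year
    arms: Mapping[str, ArmTrajectory]

    @property
    def n_years(self) -> int:
        return len(self.ages)


def halys_for_year(
    person_years: float,
    ihd_prevalent_py: float,
    other_yld_rate: float,
    dw_ihd: float,
) -> float:
    """Health-adjusted person-years lived in one year.

    person_years * (1 - other_yld_rate) - ihd_prevalent_py * dw_ihd, floored
    at 0; the IHD disability weight dw_ihd is the per-case YLD rate
    (ihd_yld_rate / ihd_prev).
    """
    if not 0.0 <= dw_ihd <= 1.0:
        raise ValueError(f"IHD disability weight {dw_ihd} outside [0, 1]")
    if ihd_prevalent_py < 0 or person_years < ihd_prevalent_py - 1e-9 * max(person_years, 1.0):
        raise ValueError("need person_years >= ihd_prevalent_py >= 0")
    return max(person_years * (1.0 - other_yld_rate) - ihd_prevalent_py * dw_ihd, 0.0)


def run_cohort(
    bi: SexBandInputs,
    entry_age: int,
    pif_by_band: np.ndarray,
    scenario: Scenario | None = None,
) -> CohortTrajectory:
    """Simulate one cohort (both arms) from its entry age to age 100.

    ``pif_by_band`` holds the potential impact fraction applied to the
    intervention arm's incidence in each 5-year band (0 everywhere makes the
    arms bitwise identical).
    """
    n_years = AGE_CEILING - entry_age
    ages = np.arange(entry_age, AGE_CEILING)
    entry_band = band_index(entry_age)
    prev0 = bi.ihd_prev[entry_band]
    arms: dict[str, ArmTrajectory] = {}
    for arm in ARMS:
        alive = np.empty(n_years + 1)
        py = np.empty(n_years)
        deaths = np.empty(n_years)
        ihd_deaths = np.empty(n_years)
        cases = np.empty(n_years)
        prev_py = np.empty(n_years)
        halys = np.empty(n_years)

        state = DiseaseState(s=1.0 - prev0, c=prev0, d=0.0)
        l = float(bi.pop[entry_band])
        alive[0] = l
        for t in range(n_years):
            b = band_index(entry_age + t)
            i = bi.ihd_inc[b]
            if arm == "intervention":
                i *= 1.0 - pif_by_band[b]
                if i < 0:
                    raise ValueError("PIF > 1 drives incidence negative")
            rates = DiseaseRates(i=i, f=bi.case_fatality[b])
            s_bar, c_bar = occupancy(state, rates)
            denom = s_bar + c_bar
            if denom <= 0:
                mu_ihd = 0.0
                inc_rate = 0.0
                prev_frac = 0.0
            else:
                mu_ihd = rates.f * c_bar / denom
                inc_rate = rates.i * s_bar / denom
                prev_frac = c_bar / denom
            m = bi.acm[b] - bi.ihd_mort[b] + mu_ihd
            if m < -1e-12:
                raise ValueError(
                    f"negative total mortality at ({bi.sex}, age {entry_age + t}): "
                    f"acm={bi.acm[b]}, ihd_mort_input={bi.ihd_mort[b]}, model rate={mu_ihd}"
                )
            m = max(m, 0.0)
            l1 = l * math.exp(-m)
            py[t] = (l + l1) / 2.0
            deaths[t] = l - l1
            ihd_deaths[t] = mu_ihd * py[t]
            cases[t] = inc_rate * py[t]
            prev_py[t] = prev_frac * py[t]
            halys[t] = halys_for_year(py[t], prev_py[t], bi.other_yld[b], bi.dw_ihd[b])
            state = step_disease(state, rates)
            l = l1
            alive[t + 1] = l
        arms[arm] = ArmTrajectory(
            alive=alive,
            person_years=py,
            deaths=deaths,
            ihd_deaths=ihd_deaths,
            incident_cases=cases,
            prevalent_py=prev_py,
            halys=halys,
        )
    return CohortTrajectory(sex=bi.sex, entry_age=entry_age, ages=ages, arms=arms)


def _calendar_sum(traj: CohortTrajectory, field: str, arm: str, n_total_years: int) -> np.ndarray:
    """Pad a cohort's per-age series onto the common calendar-year axis.

    All cohorts start in calendar year 0, so age year t is calendar year t.
    """
    out = np.zeros(n_total_years)
    series = getattr(traj.arms[arm], field)
    out[: len(series)] = series
    return out


def aggregate_population(
    trajectories: Sequence[CohortTrajectory],
    horizons: Sequence[str],
    discount_rate: float,
) -> pd.DataFrame:
    """Sum intervention-minus-reference differences over cohorts per horizon.

    Events and deaths are reported as undiscounted counts; HALYs are
    discounted at ``discount_rate`` with exponent 0 in the first simulation
    year. Returns a tidy frame with per-sex and total rows, including the
    reference-arm totals needed for percentage reductions.
    """
    if not trajectories:
        raise ValueError("no cohorts")
    n_total = AGE_CEILING - min(t.entry_age for t in trajectories)
    max_h = max(horizon_years(h, n_total) for h in horizons)
    if max_h > n_total:
        raise ValueError("horizon exceeds simulated span")
    disc = (1.0 + discount_rate) ** -np.arange(n_total)

    sexes = sorted({t.sex for t in trajectories})
    per_sex: dict[str, dict[str, np.ndarray]] = {}
    for sex in sexes:
        trajs = [t for t in trajectories if t.sex == sex]
        acc = {}
        for field in ("incident_cases", "ihd_deaths", "halys"):
            for arm in ARMS:
                acc[f"{field}_{arm}"] = np.sum(
                    [_calendar_sum(t, field, arm, n_total) for t in trajs], axis=0
                )
        per_sex[sex] = acc

    rows = []
    for h in horizons:
        ny = horizon_years(h, n_total)
        by_sex: dict[str, dict[str, float]] = {}
        for sex in sexes:
            agg = lambda key, w=None: float(
                np.sum((per_sex[sex][key][:ny]) * (1.0 if w is None else w[:ny]))
            )
            by_sex[sex] = {
                "ihd_events": agg("incident_cases_intervention") - agg("incident_cases_reference"),
                "ihd_deaths": agg("ihd_deaths_intervention") - agg("ihd_deaths_reference"),
                "halys": agg("halys_intervention", disc) - agg("halys_reference", disc),
                "ref_ihd_events": agg("incident_cases_reference"),
                "ref_ihd_deaths": agg("ihd_deaths_reference"),
            }
        # totals sum the per-sex differences so additivity holds exactly
        by_sex["total"] = {
            k: sum(by_sex[s][k] for s in sexes) for k in next(iter(by_sex.values()))
        }
        for sex in sexes + ["total"]:
            rows.append({"horizon": h, "sex": sex, **by_sex[sex]})
    return pd.DataFrame(rows)
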