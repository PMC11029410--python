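"""Extended-healthcare-perspective cost streams.

Four streams, all in 2019 USD per calendar year:

* IHD healthcare: incident cases x unit cost of acute care, plus prevalent
  case-years x unit cost of annual follow-up care;
* non-IHD healthcare: person-years x per-capita non-IHD expenditure of the
  stratum at the attained age (this is what prices the extra years of life
  the intervention creates);
* government policy implementation: a one-off legislation component in the
  first year plus recurring monitoring/enforcement/campaign components;
* industry reformulation: the full products x per-product cost in the first
  year, plus a recurring annual fraction of that initial outlay.

Net cost = discounted sum of policy costs plus the intervention-minus-
reference difference in total healthcare costs; a negative net cost means
the policy is cost-saving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import PolicyCosts, ScenarioToggles
from .lifetable import ARMS, CohortTrajectory, SexBandInputs, band_index

__all__ = [
    "healthcare_costs_year",
    "trajectory_costs",
    "policy_cost_schedule",
    "discounted_sum",
    "net_cost",
]


def healthcare_costs_year(
    incident_cases: float,
    prevalent_py: float,
    person_years: float,
    ihd_incident_cost: float,
    ihd_prevalent_cost: float,
    nonihd_percap: float,
) -> tuple[float, float]:
    """(IHD, non-IHD) healthcare cost of one cohort-year."""
    ihd = incident_cases * ihd_incident_cost + prevalent_py * ihd_prevalent_cost
    nonihd = person_years * nonihd_percap
    return ihd, nonihd


def trajectory_costs(
    traj: CohortTrajectory, bi: SexBandInputs, n_total_years: int
) -> dict[str, dict[str, np.ndarray]]:
    """Per-calendar-year IHD and non-IHD healthcare costs for both arms."""
    out: dict[str, dict[str, np.ndarray]] = {}
    bands = np.array([band_index(a) for a in traj.ages])
    for arm in ARMS:
        a = traj.arms[arm]
        ihd = a.incident_cases * bi.ihd_incident_cost[bands] + a.prevalent_py * bi.ihd_prevalent_cost[bands]
        nonihd = a.person_years * bi.nonihd_percap[bands]
        pad = lambda x: np.pad(x, (0, n_total_years - len(x)))
        out[arm] = {"ihd": pad(ihd), "nonihd": pad(nonihd)}
    return out


def policy_cost_schedule(
    policy: PolicyCosts,
    horizon_years: int,
    toggles: ScenarioToggles | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(government, industry) cost streams over ``horizon_years`` years.

    Year 1 (index 0) carries the one-off government components and the
    initial industry reformulation outlay; every year (including the first)
    carries the annual government components and the recurring industry
    fraction. Toggles: ``monitoring_scale`` multiplies only the annual
    government stream, ``products_scale`` multiplies the product count, and
    ``no_industry_cost`` zeroes the industry stream.
    """
    if horizon_years < 1:
        raise ValueError("horizon must cover at least one year")
    t = toggles or ScenarioToggles()
    gov = np.full(horizon_years, policy.gov_annual * t.monitoring_scale)
    gov[0] += policy.gov_oneoff
    industry = np.zeros(horizon_years)
    if not t.no_industry_cost:
        initial = policy.industry_initial * t.products_scale
        industry[:] = policy.industry_annual_frac * initial
        industry[0] += initial
    return gov, industry


def discounted_sum(stream: np.ndarray, discount_rate: float, n_years: int | None = None) -> float:
    """Present value with (1+r)^-t and t = 0 for the first simulation year."""
    s = np.asarray(stream, float)
    if n_years is not None:
        s = s[:n_years]
    return float(np.sum(s * (1.0 + discount_rate) ** -np.arange(len(s))))


def net_cost(
    healthcare_delta: np.ndarray,
    gov: np.ndarray,
    industry: np.ndarray,
    discount_rate: float,
    horizon_years: int,
) -> float:
    """Discounted net cost over a horizon.

    ``healthcare_delta`` is the per-year intervention-minus-reference total
    healthcare cost; negative net cost indicates a cost-saving intervention.
    """
    total = (
        discounted_sum(healthcare_delta, discount_rate, horizon_years)
        + discounted_sum(gov, discount_rate, horizon_years)
        + discounted_sum(industry, discount_rate, horizon_years)
    )
    return total
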