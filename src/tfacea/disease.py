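"""IHD illness-death submodel (well -> diseased -> IHD death).

The three states are proportions conditional on surviving all non-IHD causes
of death, which stay outside this submodel (the proportional multistate
lifetable combines the two mortality streams). Remission is fixed at 0: IHD
is treated as a chronic condition with ongoing follow-up care.

The within-year flow is the linear ODE system

    dS/dt = -i S,   dC/dt = i S - f C,   dD/dt = f C,

with incidence i and case fatality f constant within each single year of age.
One year advances by the exact solution; within-year average occupancies (the
exact time integrals of S and C over the year) feed the event and mortality
rates handed to the lifetable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DiseaseState",
    "DiseaseRates",
    "derive_case_fatality",
    "step_disease",
    "occupancy",
    "ihd_mortality_rate",
    "incidence_rate_among_alive",
]


@dataclass(frozen=True)
class DiseaseState:
    s: float  # alive, IHD-free
    c: float  # alive with IHD
    d: float  # cumulative IHD deaths

    def __post_init__(self) -> None:
        if min(self.s, self.c, self.d) < 0:
            raise ValueError(f"negative state {self}")

    @property
    def total(self) -> float:
        return self.s + self.c + self.d


@dataclass(frozen=True)
class DiseaseRates:
    i: float  # annual IHD incidence among the well
    f: float  # annual case fatality among prevalent cases
    r: float = 0.0  # remission, structurally zero

    def __post_init__(self) -> None:
        if self.i < 0 or self.f < 0:
            raise ValueError("negative disease rates")
        if self.r != 0.0:
            raise ValueError("remission is fixed at 0 in this model")


def derive_case_fatality(epi: pd.DataFrame) -> pd.Series:
    """Per-stratum case fatality f = IHD mortality rate / IHD prevalence.

    This is the steady-state identity relating cause-specific mortality among
    the whole population to the death rate among prevalent cases; it stands in
    for a full DisMod-style reconciliation of incidence, prevalence and
    mortality, which is not attempted here.
    """
    mort = epi["ihd_mort"]
    prev = epi["ihd_prev"]
    bad = (mort > 0) & (prev == 0)
    if bad.any():
        raise ValueError(f"case fatality undefined (ihd_mort > 0, ihd_prev = 0) at {list(epi.index[bad])[0]}")
    f = pd.Series(0.0, index=epi.index, name="case_fatality")
    nz = prev > 0
    f[nz] = mort[nz] / prev[nz]
    return f


def _eps(x: float) -> float:
    """(1 - exp(-x)) / x, the one-year average of exp(-x t); 1 at x = 0."""
    if abs(x) < 1e-5:
        return 1.0 - x / 2.0 + x * x / 6.0 - x ** 3 / 24.0
    return -math.expm1(-x) / x


def _eps_prime(x: float) -> float:
    """Derivative of :func:`_eps`; -1/2 at x = 0."""
    if abs(x) < 1e-4:
        return -0.5 + x / 3.0 - x * x / 8.0 + x ** 3 / 30.0
    return (math.exp(-x) * (1.0 + x) - 1.0) / (x * x)


def step_disease(state: DiseaseState, rates: DiseaseRates) -> DiseaseState:
    """Advance the illness-death system exactly one year.

    S1 = S0 e^{-i};  C1 = C0 e^{-f} + i S0 (e^{-i} - e^{-f}) / (f - i)
    (with the series limit i S0 e^{-i} as f -> i); D1 by conservation of
    S + C + D.
    """
    i, f = rates.i, rates.f
    if i == 0.0 and f == 0.0:
        return state
    s1 = state.s * math.exp(-i)
    # (e^{-i} - e^{-f})/(f - i) = e^{-i} * eps(f - i), stable for all f, i
    c1 = state.c * math.exp(-f) + i * state.s * math.exp(-i) * _eps(f - i)
    d1 = state.total - s1 - c1
    return DiseaseState(s=s1, c=c1, d=max(d1, 0.0))


def occupancy(state: DiseaseState, rates: DiseaseRates) -> tuple[float, float]:
    """Exact within-year average occupancy (s_bar, c_bar) of the two live states.

    s_bar = S0 eps(i);  c_bar = C0 eps(f) + i S0 (eps(i) - eps(f)) / (f - i),
    with the limit -i S0 eps'(i) as f -> i.
    """
    i, f = rates.i, rates.f
    s_bar = state.s * _eps(i)
    delta = f - i
    if abs(delta) < 1e-9:
        mix = -_eps_prime((i + f) / 2.0)
    else:
        mix = (_eps(i) - _eps(f)) / delta
    c_bar = state.c * _eps(f) + i * state.s * mix
    return s_bar, c_bar


def ihd_mortality_rate(state: DiseaseState, rates: DiseaseRates) -> float:
    """Annual IHD death rate among the living over the coming year.

    f * c_bar / (s_bar + c_bar), i.e. IHD deaths divided by person-years lived
    in the conditional submodel, using the exact within-year occupancies.
    """
    s_bar, c_bar = occupancy(state, rates)
    denom = s_bar + c_bar
    if denom <= 0:
        raise ValueError("no survivors in disease submodel")
    return rates.f * c_bar / denom


def incidence_rate_among_alive(state: DiseaseState, rates: DiseaseRates) -> float:
    """Annual rate of new IHD cases per person-year among the living."""
    s_bar, c_bar = occupancy(state, rates)
    denom = s_bar + c_bar
    if denom <= 0:
        raise ValueError("no survivors in disease submodel")
    return rates.i * s_bar / denom
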