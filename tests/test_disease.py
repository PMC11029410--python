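"""Illness-death submodel against an adaptive ODE oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from tfacea.disease import (
    DiseaseRates,
    DiseaseState,
    derive_case_fatality,
    incidence_rate_among_alive,
    ihd_mortality_rate,
    step_disease,
)


def ode_oracle(state: DiseaseState, i: float, f: float):
    """Integrate dS=-iS, dC=iS-fC, dD=fC over one year, plus the person-year
    integral of S+C, with an adaptive high-accuracy solver."""

    def rhs(_, y):
        s, c, d, py = y
        return [-i * s, i * s - f * c, f * c, s + c]

    sol = solve_ivp(
        rhs, (0, 1), [state.s, state.c, state.d, 0.0], rtol=1e-12, atol=1e-14, dense_output=False
    )
    s, c, d, py = sol.y[:, -1]
    return s, c, d, py


def test_zero_rates_leave_state_unchanged():
    state = DiseaseState(s=0.9, c=0.05, d=0.05)
    out = step_disease(state, DiseaseRates(i=0.0, f=0.0))
    assert (out.s, out.c, out.d) == (state.s, state.c, state.d)


def test_one_year_closed_form_example():
    """S0=1, C0=0, i=0.01, f=0.1: C1 = 0.01 (e^-0.01 - e^-0.1)/(0.1 - 0.01)."""
    out = step_disease(DiseaseState(s=1.0, c=0.0, d=0.0), DiseaseRates(i=0.01, f=0.1))
    expected = 0.01 * (np.exp(-0.01) - np.exp(-0.1)) / (0.1 - 0.01)
    assert out.c == pytest.approx(expected, abs=1e-14)
    assert out.s == pytest.approx(np.exp(-0.01), abs=1e-15)


@given(
    s0=st.floats(0.0, 1.0),
    c_frac=st.floats(0.0, 1.0),
    i=st.floats(0.0, 1.0),
    f=st.floats(0.0, 1.0),
)
def test_closed_form_matches_ode_oracle(s0, c_frac, i, f):
    """Closed-form yearly step agrees with adaptive integration to 1e-8 and
    conserves S + C + D to 1e-12."""
    state = DiseaseState(s=s0, c=(1.0 - s0) * c_frac, d=(1.0 - s0) * (1.0 - c_frac))
    out = step_disease(state, DiseaseRates(i=i, f=f))
    s, c, d, _ = ode_oracle(state, i, f)
    assert out.s == pytest.approx(s, abs=1e-8)
    assert out.c == pytest.approx(c, abs=1e-8)
    assert out.d == pytest.approx(d, abs=1e-8)
    assert abs(out.total - state.total) < 1e-12


@pytest.mark.parametrize("i,f", [(0.05, 0.05), (0.3, 0.3 + 1e-13), (0.2, 0.2 - 1e-13)])
def test_equal_rates_degeneracy(i, f):
    """The f = i degeneracy resolves to the series limit, matching the oracle."""
    state = DiseaseState(s=0.8, c=0.15, d=0.05)
    out = step_disease(state, DiseaseRates(i=i, f=f))
    s, c, d, _ = ode_oracle(state, i, f)
    assert out.c == pytest.approx(c, abs=1e-10)
    assert abs(out.total - state.total) < 1e-12


@given(
    c0=st.floats(0.0, 0.5),
    i=st.floats(0.0, 0.8),
    f=st.floats(0.0, 0.8),
)
def test_mortality_rate_consistent_with_death_increment(c0, i, f):
    """f * c_bar / (s_bar + c_bar) equals (D increment)/(person-years) from
    the ODE oracle within 1e-8."""
    state = DiseaseState(s=1.0 - c0, c=c0, d=0.0)
    rates = DiseaseRates(i=i, f=f)
    _, _, d1, py = ode_oracle(state, i, f)
    if py == 0:
        return
    assert ihd_mortality_rate(state, rates) == pytest.approx(d1 / py, abs=1e-8)


def test_mortality_rate_trivial_zeros():
    # no prevalent cases and no inflow -> no IHD deaths
    assert ihd_mortality_rate(DiseaseState(s=1.0, c=0.0, d=0.0), DiseaseRates(i=0.0, f=0.2)) == 0.0
    # zero case fatality -> no IHD deaths regardless of prevalence
    assert ihd_mortality_rate(DiseaseState(s=0.5, c=0.5, d=0.0), DiseaseRates(i=0.1, f=0.0)) == 0.0
    # with inflow, cases incident within the year contribute person-time at
    # risk, so the rate is positive even from a disease-free start
    assert ihd_mortality_rate(DiseaseState(s=1.0, c=0.0, d=0.0), DiseaseRates(i=0.1, f=0.2)) > 0.0


def test_incidence_rate_among_alive_bounds():
    state = DiseaseState(s=0.7, c=0.3, d=0.0)
    rates = DiseaseRates(i=0.02, f=0.1)
    r = incidence_rate_among_alive(state, rates)
    assert 0 < r < 0.02  # diluted by the prevalent fraction


def test_lower_incidence_never_raises_prevalence_or_mortality():
    """An intervention that only lowers incidence keeps prevalence and IHD
    mortality at or below the reference at every age."""
    f = 0.08
    ref = DiseaseState(s=0.95, c=0.05, d=0.0)
    cut = DiseaseState(s=0.95, c=0.05, d=0.0)
    for _ in range(60):
        r_ref = DiseaseRates(i=0.01, f=f)
        r_cut = DiseaseRates(i=0.007, f=f)
        assert cut.c <= ref.c + 1e-15
        assert ihd_mortality_rate(cut, r_cut) <= ihd_mortality_rate(ref, r_ref) + 1e-15
        ref = step_disease(ref, r_ref)
        cut = step_disease(cut, r_cut)


def test_case_fatality_from_prevalence_and_mortality():
    epi = pd.DataFrame(
        {"ihd_mort": [0.001, 0.0, 0.004], "ihd_prev": [0.02, 0.0, 0.05]},
        index=["a", "b", "c"],
    )
    f = derive_case_fatality(epi)
    assert f["a"] == pytest.approx(0.05)
    assert f["b"] == 0.0
    assert f["c"] == pytest.approx(0.08)
    bad = pd.DataFrame({"ihd_mort": [0.001], "ihd_prev": [0.0]})
    with pytest.raises(ValueError, match="case fatality"):
        derive_case_fatality(bad)


def test_remission_is_structurally_zero():
    with pytest.raises(ValueError):
        DiseaseRates(i=0.01, f=0.1, r=0.05)
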