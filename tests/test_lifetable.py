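"""Cohort lifetable: hand-checkable survivorship, HALYs, aggregation."""

import math

import numpy as np
import pytest

import tfacea as t
from tfacea.costs import discounted_sum
from tfacea.lifetable import band_inputs, halys_for_year, run_cohort


def geometric_life_expectancy(m: float, years: int = 80) -> float:
    """Closed-form trapezoidal life expectancy under constant hazard m."""
    return (1 + math.exp(-m)) / 2 * (1 - math.exp(-years * m)) / (1 - math.exp(-m))


def test_toy_life_expectancy_matches_hand_arithmetic(toy_inputs):
    """The worked fixture has constant mortality and no disease, so the
    lifetable must reproduce the geometric-sum life expectancy to 1e-6."""
    pifs = np.zeros(len(t.AGE_LOWER_BOUNDS))
    for sex, m in (("female", 0.01), ("male", 0.02)):
        bi = band_inputs(toy_inputs, sex)
        traj = run_cohort(bi, 20, pifs)
        le = traj.arms["reference"].person_years.sum() / traj.arms["reference"].alive[0]
        assert le == pytest.approx(geometric_life_expectancy(m), abs=1e-6)


def test_null_intervention_arms_identical(synth_inputs):
    """PIF = 0 makes every intervention field bitwise equal to reference."""
    bi = band_inputs(synth_inputs, "male")
    traj = run_cohort(bi, 40, np.zeros(len(t.AGE_LOWER_BOUNDS)))
    ref, inter = traj.arms["reference"], traj.arms["intervention"]
    for fieldname in ("alive", "person_years", "ihd_deaths", "incident_cases", "prevalent_py", "halys"):
        assert np.array_equal(getattr(ref, fieldname), getattr(inter, fieldname))


def test_immortal_cohort(toy_inputs):
    """Zero mortality keeps the cohort constant with person-years = alive."""
    immortal = toy_inputs.copy()
    immortal.strata["acm"] = 0.0
    bi = band_inputs(immortal, "female")
    traj = run_cohort(bi, 20, np.zeros(len(t.AGE_LOWER_BOUNDS)))
    ref = traj.arms["reference"]
    assert np.all(ref.alive == ref.alive[0])
    assert np.all(ref.person_years == ref.alive[0])


def test_alive_nonincreasing_and_halys_bounded(synth_inputs):
    bi = band_inputs(synth_inputs, "female")
    traj = run_cohort(bi, 20, np.full(len(t.AGE_LOWER_BOUNDS), 0.03))
    for arm in traj.arms.values():
        assert np.all(np.diff(arm.alive) <= 0)
        assert np.all(arm.halys >= 0)
        assert np.all(arm.halys <= arm.person_years + 1e-12)


def test_halys_arithmetic():
    """100 PY, 5% background disability, 10 prevalent PY at weight 0.1 -> 94."""
    assert halys_for_year(100.0, 10.0, 0.05, 0.1) == pytest.approx(94.0)
    assert halys_for_year(100.0, 0.0, 0.0, 0.0) == 100.0
    with pytest.raises(ValueError):
        halys_for_year(100.0, 10.0, 0.0, 1.5)


def test_discounting_geometric_sum():
    """A constant annual amount discounts to the geometric sum with t=0 first."""
    g = 123.0
    got = discounted_sum(np.full(5, g), 0.03)
    expected = sum(g * 1.03**-t for t in range(5))
    assert got == pytest.approx(expected, rel=1e-12)
    assert discounted_sum(np.full(5, g), 0.0) == pytest.approx(5 * g)


def test_sex_totals_additive(central_results):
    """Total rows equal the sum of per-sex rows exactly for all
    sex-attributable outcomes."""
    for h in ("5y", "10y", "lifetime"):
        for outcome in (
            "ihd_events",
            "ihd_deaths",
            "halys",
            "ihd_healthcare_cost",
            "nonihd_healthcare_cost",
            "total_healthcare_cost",
        ):
            f = central_results.value(h, outcome, "female")
            m = central_results.value(h, outcome, "male")
            tot = central_results.value(h, outcome, "total")
            assert tot == f + m


def test_nested_horizons(central_results):
    """Undiscounted averted counts accumulate with the horizon."""
    for outcome in ("ihd_events", "ihd_deaths"):
        v5 = -central_results.value("5y", outcome)
        v10 = -central_results.value("10y", outcome)
        vlife = -central_results.value("lifetime", outcome)
        assert 0 <= v5 <= v10 <= vlife


def test_percent_reductions_in_unit_interval(central_results):
    for h in ("5y", "10y", "lifetime"):
        s = central_results.stats["horizons"][h]
        assert 0 <= s["pct_events"] < 100
        assert 0 <= s["pct_deaths"] < 100


def test_sign_coherence(central_results):
    """Eliminating a harmful exposure averts events and deaths and gains HALYs."""
    for h in ("5y", "10y", "lifetime"):
        assert central_results.value(h, "ihd_events") < 0
        assert central_results.value(h, "ihd_deaths") < 0
        assert central_results.value(h, "halys") > 0


def test_discount_zero_increases_halys(synth_inputs, scenario, central_results):
    undiscounted = t.run_pipeline(synth_inputs, scenario.model_copy(update={"discount_rate": 0.0}))
    assert undiscounted.value("lifetime", "halys") > central_results.value("lifetime", "halys")
    # counts are undiscounted in both runs
    assert undiscounted.value("10y", "ihd_deaths") == pytest.approx(
        central_results.value("10y", "ihd_deaths"), rel=1e-12
    )
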