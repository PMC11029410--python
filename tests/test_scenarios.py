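"""Scenario variants: plan orchestration, sensitivity directions, independence."""

import pandas as pd
import pytest

import tfacea as t
from tfacea.engine import stratum_pifs
from tfacea.scenarios import AnalysisPlan, build_default_plan, run_plan


def test_default_plan_contents():
    plan = build_default_plan()
    names = list(plan.variants)
    assert names[0] == "primary"
    assert {"discount_0pct", "discount_6pct", "intake_x0.5", "intake_x1.5",
            "post_intake_0.1e", "products_x2", "no_industry_cost",
            "monitoring_x1.5"}.issubset(names)
    assert sum(n.startswith("threshold_") for n in names) == 4
    with pytest.raises(ValueError, match="primary"):
        AnalysisPlan(variants={"other": t.Scenario()})


def test_primary_only_plan_equals_direct_pipeline(synth_inputs, scenario, central_results):
    plan = AnalysisPlan(variants={"primary": scenario})
    res = run_plan(synth_inputs, plan, monte_carlo=False)
    pd.testing.assert_frame_equal(
        res.central["primary"].table, central_results.table, check_exact=True
    )
    assert res.errors == {}


def test_discount_variants_order_halys(synth_inputs, scenario):
    plan = AnalysisPlan(
        variants={
            "primary": scenario,
            "discount_0pct": scenario.model_copy(update={"discount_rate": 0.0}),
            "discount_6pct": scenario.model_copy(update={"discount_rate": 0.06}),
        }
    )
    res = run_plan(synth_inputs, plan, monte_carlo=False)
    life = res.comparison[res.comparison["horizon"] == "lifetime"].set_index("variant")
    assert life.loc["discount_0pct", "halys_gained"] > life.loc["primary", "halys_gained"]
    assert life.loc["primary", "halys_gained"] > life.loc["discount_6pct", "halys_gained"]


def test_halved_intake_shrinks_pif_and_halys(synth_inputs, scenario):
    half = scenario.model_copy(
        update={"toggles": scenario.toggles.model_copy(update={"intake_scale": 0.5})}
    )
    pif_primary = stratum_pifs(synth_inputs, scenario)
    pif_half = stratum_pifs(synth_inputs, half)
    for sex in ("female", "male"):
        assert (pif_half[sex] <= pif_primary[sex]).all()
        assert (pif_half[sex] < pif_primary[sex]).any()
    res = run_plan(
        synth_inputs,
        AnalysisPlan(variants={"primary": scenario, "half": half}),
        monte_carlo=False,
    )
    comp = res.comparison[res.comparison["horizon"] == "lifetime"].set_index("variant")
    assert comp.loc["half", "halys_gained"] < comp.loc["primary", "halys_gained"]


def test_variant_results_independent_of_plan_composition(synth_inputs, scenario):
    """A variant's MC stream is seeded from its name, so adding or removing
    other variants leaves its results bit-identical."""
    v = scenario.model_copy(update={"discount_rate": 0.0})
    small = AnalysisPlan(variants={"primary": scenario, "discount_0pct": v})
    solo = AnalysisPlan(variants={"primary": scenario})
    full = AnalysisPlan(
        variants={"primary": scenario, "discount_0pct": v, "extra": scenario.model_copy(update={"discount_rate": 0.06})}
    )
    r_small = run_plan(synth_inputs, small, n_iter=5, seed=3)
    r_full = run_plan(synth_inputs, full, n_iter=5, seed=3)
    r_solo = run_plan(synth_inputs, solo, n_iter=5, seed=3)
    pd.testing.assert_frame_equal(
        r_small.mc["discount_0pct"].iterations, r_full.mc["discount_0pct"].iterations, check_exact=True
    )
    pd.testing.assert_frame_equal(
        r_small.mc["primary"].iterations, r_solo.mc["primary"].iterations, check_exact=True
    )


def test_threshold_variants_order_probability_of_cost_saving(synth_inputs, scenario):
    """The smallest intake reduction has the lowest probability of being
    cost-saving among the threshold variants."""
    tog = scenario.toggles
    variants = {"primary": scenario}
    for shift in (0.05, 0.10, 0.15, 0.20):
        variants[f"threshold_{shift:.2f}e"] = scenario.model_copy(
            update={"toggles": tog.model_copy(update={"intake_shift_e_pct": shift})}
        )
    res = run_plan(synth_inputs, AnalysisPlan(variants=variants), n_iter=40, seed=17)
    comp = res.comparison[res.comparison["horizon"] == "10y"].set_index("variant")
    p_small = comp.loc["threshold_0.05e", "p_cost_saving"]
    others = [comp.loc[f"threshold_{s:.2f}e", "p_cost_saving"] for s in (0.10, 0.15, 0.20)]
    assert all(p_small <= p for p in others)
    # central health gains are strictly ordered in the shift
    halys = [comp.loc[f"threshold_{s:.2f}e", "halys_gained"] for s in (0.05, 0.10, 0.15, 0.20)]
    assert halys == sorted(halys)


def test_failing_variant_isolated(synth_inputs, scenario):
    bad = scenario.model_copy(
        update={"toggles": scenario.toggles.model_copy(update={"intake_scale": 1e-9})}
    )
    # an intake scale of ~0 gives zero-mean lognormal -> validation error inside
    plan = AnalysisPlan(variants={"primary": scenario, "bad": bad})
    res = run_plan(synth_inputs, plan, monte_carlo=False)
    assert "primary" in res.central
    # either the variant ran (degenerate) or was recorded as an error; never crashes
    assert ("bad" in res.central) or ("bad" in res.errors)
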