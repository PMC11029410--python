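"""Monte Carlo propagation: reproducibility, degenerate collapse, ICER/ROI."""

import math

import numpy as np
import pandas as pd
import pytest

import tfacea as t
from tfacea.uncertainty import draw_inputs, icer, probabilities, roi


def degenerate(inputs: t.StratifiedInputs) -> t.StratifiedInputs:
    """Copy of the inputs with every uncertainty spread set to zero."""
    import dataclasses

    d = inputs.copy()
    d.strata["intake_sd"] = 0.0
    d.rr["ln_rr_sd"] = 0.0
    for prefix in ("ihd_incident", "ihd_prevalent"):
        for k in ("min", "max"):
            d.strata[f"{prefix}_{k}"] = d.strata[f"{prefix}_mode"]
    comps = tuple((n, kind, a, 0.0) for n, kind, a, _ in d.policy.gov_components)
    return dataclasses.replace(
        d, policy=dataclasses.replace(d.policy, gov_components=comps, cost_sd_frac=0.0)
    )


def test_single_iteration_summary_collapses(synth_inputs, scenario):
    mc = t.run_monte_carlo(synth_inputs, scenario, n_iter=1, seed=5)
    s = mc.summary
    assert np.allclose(s["mean"], s["p2_5"], equal_nan=True)
    assert np.allclose(s["mean"], s["p97_5"], equal_nan=True)


def test_degenerate_distributions_reproduce_central_run_exactly(synth_inputs, scenario):
    """With all spreads at zero, every draw reproduces the central inputs
    and every iteration equals the central run."""
    d = degenerate(synth_inputs)
    rng = np.random.default_rng(9)
    drawn = draw_inputs(d, rng)
    assert drawn.equals(d)

    central = t.run_pipeline(d, scenario)
    mc = t.run_monte_carlo(d, scenario, n_iter=3, seed=9)
    for h in ("5y", "10y", "lifetime"):
        s = central.stats["horizons"][h]
        grp = mc.iterations[mc.iterations["horizon"] == h]
        assert (grp["net_cost"] == s["net_cost"]).all()
        assert (grp["halys_gained"] == s["halys_gained"]).all()
        assert (grp["gov_cost"] == s["gov_cost"]).all()
    merged = mc.summary.merge(
        central.table, on=["horizon", "sex", "outcome"], suffixes=("", "_central")
    )
    mask = ~merged["value"].isna()
    assert np.allclose(merged.loc[mask, "mean"], merged.loc[mask, "value"], rtol=1e-14)
    assert (merged.loc[mask, "p2_5"] == merged.loc[mask, "value"]).all()


def test_identical_seeds_are_bit_identical(synth_inputs, scenario):
    a = t.run_monte_carlo(synth_inputs, scenario, n_iter=8, seed=13)
    b = t.run_monte_carlo(synth_inputs, scenario, n_iter=8, seed=13)
    pd.testing.assert_frame_equal(a.iterations, b.iterations, check_exact=True)
    pd.testing.assert_frame_equal(a.summary, b.summary, check_exact=True)
    c = t.run_monte_carlo(synth_inputs, scenario, n_iter=8, seed=14)
    assert not a.iterations["net_cost"].equals(c.iterations["net_cost"])


def test_mc_mean_near_central(synth_inputs, scenario, central_results):
    """The MC mean of HALYs gained sits within 3 SE of the central run
    (the pipeline is near-linear in its uncertain inputs)."""
    mc = t.run_monte_carlo(synth_inputs, scenario, n_iter=200, seed=21)
    grp = mc.iterations[mc.iterations["horizon"] == "10y"]["halys_gained"]
    se = grp.std(ddof=1) / math.sqrt(len(grp))
    assert abs(grp.mean() - central_results.value("10y", "halys")) < 3 * se


def test_percentile_ordering_and_probability_bounds(synth_inputs, scenario):
    mc = t.run_monte_carlo(synth_inputs, scenario, n_iter=30, seed=2)
    clean = mc.summary.dropna()
    assert (clean["p2_5"] <= clean["p97_5"]).all()
    for h, s in mc.stats.items():
        assert 0 <= s["p_cost_saving"] <= 1
        assert 0 <= s["p_cost_effective"] <= 1
        assert s["p_cost_saving"] <= s["p_cost_effective"]


@pytest.mark.parametrize(
    "net, halys, saving, effective, dominated, value",
    [
        (-1_000_000, 1000, True, True, False, -1000.0),
        (374_000, 1000, False, False, False, 374.0),  # strict '<' at threshold
        (373_999, 1000, False, True, False, 373.999),
        (0, 1000, False, True, False, 0.0),
        (5_000, -10, False, False, True, None),
    ],
)
def test_icer_classification(net, halys, saving, effective, dominated, value):
    res = icer(net, halys, threshold=374.0)
    assert res.cost_saving is saving
    assert res.cost_effective is effective
    assert res.dominated is dominated
    if value is None:
        assert res.value is None
    else:
        assert res.value == pytest.approx(value)


def test_roi_arithmetic():
    assert roi(90e6, 2e6) == pytest.approx(45.0)
    assert roi(0.0, 2e6) == 0.0
    with pytest.raises(ValueError):
        roi(1.0, 0.0)


def test_probabilities_fractions():
    net = [-1.0, -2.0, 3.0, 4.0]
    icers = [None, None, 100.0, 500.0]
    p_save, p_eff = probabilities(net, icers, threshold=374.0)
    assert p_save == 0.5
    assert p_eff == 0.75
    assert probabilities([-1.0], [None])[0] == 1.0


def test_probabilities_binomial_consistency():
    """Estimated fraction over 2000 Bernoulli-like iterations lies within
    3 binomial SE of the generating probability."""
    rng = np.random.default_rng(0)
    p = 0.43
    net = np.where(rng.uniform(size=2000) < p, -1.0, 1.0)
    p_save, _ = probabilities(net.tolist(), [None] * 2000)
    assert abs(p_save - p) < 3 * math.sqrt(p * (1 - p) / 2000)


def test_draws_respect_nonnegativity(synth_inputs):
    rng = np.random.default_rng(123)
    for _ in range(20):
        d = draw_inputs(synth_inputs, rng)
        assert (d.strata["intake_mean"] >= 0).all()
        assert (d.strata["nonihd_percap"] >= 0).all()
        assert (d.rr["rr_per_2e"] > 0).all()
        assert all(a >= 0 for _, _, a, _ in d.policy.gov_components)


def test_roi_per_iteration_vs_ratio_of_means(synth_inputs, scenario):
    """The reported ROI averages per-iteration ratios; the ratio of means is
    a different (only approximately equal) quantity."""
    mc = t.run_monte_carlo(synth_inputs, scenario, n_iter=40, seed=31)
    grp = mc.iterations[mc.iterations["horizon"] == "10y"]
    per_iter = grp["roi"].mean()
    ratio_of_means = grp["healthcare_savings"].mean() / grp["gov_cost"].mean()
    assert mc.stats["10y"]["roi"]["mean"] == pytest.approx(per_iter)
    assert per_iter == pytest.approx(ratio_of_means, rel=0.5)  # same scale, not identical
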