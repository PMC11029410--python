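"""Deterministic end-to-end pipeline: inputs + scenario -> tidy results.

Shared by the scenario orchestrator (central runs) and the Monte Carlo layer
(one call per draw). The sequence is: counterfactual intake per stratum ->
potential impact fraction -> 30 cohort lifetables (both arms) -> healthcare
and policy cost streams -> per-horizon aggregation, ICER and ROI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (
    AGE_CEILING,
    AGE_LOWER_BOUNDS,
    OUTCOMES,
    IntakeDistribution,
    ResultsSummary,
    Scenario,
    StratifiedInputs,
    config_hash,
    horizon_years,
)
from .costs import discounted_sum, policy_cost_schedule, trajectory_costs
from .exposure import compute_pif
from .lifetable import ARMS, aggregate_population, band_inputs, run_cohort

__all__ = ["counterfactual_intake", "stratum_pifs", "run_pipeline"]


def counterfactual_intake(ref: IntakeDistribution, scenario: Scenario) -> IntakeDistribution:
    """Counterfactual intake distribution for one stratum under a scenario.

    The primary analysis eliminates trans-fat intake (``post_intake``,
    degenerate at 0%E by default). A nonzero ``intake_shift_e_pct`` instead
    runs the partial-compliance threshold analysis: the reference mean is
    lowered by the shift (floored at 0), keeping the SD.
    """
    shift = scenario.toggles.intake_shift_e_pct
    if shift > 0:
        new_mean = max(ref.mean_e_pct - shift, 0.0)
        if new_mean == 0 or ref.family == "degenerate" or ref.sd_e_pct == 0:
            return IntakeDistribution(mean_e_pct=new_mean, sd_e_pct=0.0, family="degenerate")
        return IntakeDistribution(mean_e_pct=new_mean, sd_e_pct=ref.sd_e_pct, family="lognormal")
    return scenario.post_intake


def _scaled_reference(ref: IntakeDistribution, scale: float) -> IntakeDistribution:
    if scale == 1.0 or ref.mean_e_pct == 0:
        return ref
    return IntakeDistribution(
        mean_e_pct=ref.mean_e_pct * scale,
        sd_e_pct=ref.sd_e_pct * scale,
        family=ref.family,
    )


def stratum_pifs(inputs: StratifiedInputs, scenario: Scenario) -> dict[str, np.ndarray]:
    """Per-sex arrays of potential impact fractions, one entry per age band."""
    out: dict[str, np.ndarray] = {}
    for sex in inputs.sexes():
        pifs = np.zeros(len(AGE_LOWER_BOUNDS))
        for k, age_lo in enumerate(AGE_LOWER_BOUNDS):
            if (sex, age_lo) not in inputs.strata.index:
                continue
            ref = _scaled_reference(inputs.intake(sex, age_lo), scenario.toggles.intake_scale)
            cf = counterfactual_intake(ref, scenario)
            rr = inputs.relative_risk(age_lo)
            pifs[k] = compute_pif(ref, cf, rr, scenario.tmrel_e_pct, sex=sex).pif
        out[sex] = pifs
    return out


def run_pipeline(inputs: StratifiedInputs, scenario: Scenario) -> ResultsSummary:
    """Run the full deterministic model and return tidy per-horizon results."""
    pifs = stratum_pifs(inputs, scenario)
    sexes = inputs.sexes()
    n_total = AGE_CEILING - AGE_LOWER_BOUNDS[0]

    trajectories = []
    hc = {
        sex: {arm: {"ihd": np.zeros(n_total), "nonihd": np.zeros(n_total)} for arm in ARMS}
        for sex in sexes
    }
    for sex in sexes:
        bi = band_inputs(inputs, sex)
        for age_lo in AGE_LOWER_BOUNDS:
            if (sex, age_lo) not in inputs.strata.index:
                continue
            traj = run_cohort(bi, age_lo, pifs[sex], scenario)
            trajectories.append(traj)
            tc = trajectory_costs(traj, bi, n_total)
            for arm in ARMS:
                hc[sex][arm]["ihd"] += tc[arm]["ihd"]
                hc[sex][arm]["nonihd"] += tc[arm]["nonihd"]

    health = aggregate_population(trajectories, scenario.horizons, scenario.discount_rate)
    gov, industry = policy_cost_schedule(inputs.policy, n_total, scenario.toggles)

    r = scenario.discount_rate
    rows = []
    stats: dict = {"horizons": {}}
    for h in scenario.horizons:
        ny = horizon_years(h, n_total)
        gov_h = discounted_sum(gov, r, ny)
        industry_h = discounted_sum(industry, r, ny)

        # Per-sex values first; total rows sum the per-sex values so that
        # sex additivity holds exactly in floating point.
        values_by_sex: dict[str, dict[str, float]] = {}
        for sex in sexes:
            hrow = health[(health["horizon"] == h) & (health["sex"] == sex)].iloc[0]
            d_ihd_stream = hc[sex]["intervention"]["ihd"] - hc[sex]["reference"]["ihd"]
            d_non_stream = hc[sex]["intervention"]["nonihd"] - hc[sex]["reference"]["nonihd"]
            d_ihd = discounted_sum(d_ihd_stream, r, ny)
            d_non = discounted_sum(d_non_stream, r, ny)
            values_by_sex[sex] = {
                "ihd_events": float(hrow["ihd_events"]),
                "ihd_deaths": float(hrow["ihd_deaths"]),
                "halys": float(hrow["halys"]),
                "ihd_healthcare_cost": d_ihd,
                "nonihd_healthcare_cost": d_non,
                "total_healthcare_cost": d_ihd + d_non,
                "policy_cost": np.nan,
                "net_cost": np.nan,
            }
        total_vals = {
            k: sum(values_by_sex[s][k] for s in sexes)
            for k in OUTCOMES
            if k not in ("policy_cost", "net_cost")
        }
        total_vals["policy_cost"] = gov_h + industry_h
        total_vals["net_cost"] = total_vals["total_healthcare_cost"] + gov_h + industry_h
        values_by_sex["total"] = total_vals

        for sex in sexes + ["total"]:
            for outcome in OUTCOMES:
                rows.append(
                    {"horizon": h, "sex": sex, "outcome": outcome, "value": values_by_sex[sex][outcome]}
                )
            if sex == "total":
                hrow = health[(health["horizon"] == h) & (health["sex"] == "total")].iloc[0]
                halys_gained = total_vals["halys"]
                hc_savings = -total_vals["total_healthcare_cost"]
                net = total_vals["net_cost"]
                stats["horizons"][h] = {
                    "gov_cost": gov_h,
                    "industry_cost": industry_h,
                    "net_cost": net,
                    "halys_gained": halys_gained,
                    "icer": net / halys_gained if halys_gained != 0 else np.nan,
                    "roi": hc_savings / gov_h if gov_h > 0 else np.nan,
                    "pct_events": -100.0 * float(hrow["ihd_events"]) / float(hrow["ref_ihd_events"])
                    if hrow["ref_ihd_events"] > 0
                    else 0.0,
                    "pct_deaths": -100.0 * float(hrow["ihd_deaths"]) / float(hrow["ref_ihd_deaths"])
                    if hrow["ref_ihd_deaths"] > 0
                    else 0.0,
                }

    table = pd.DataFrame(rows)
    meta = {
        "config_hash": config_hash(scenario),
        "usd_to_ngn": inputs.currency.usd_to_ngn,
        "discount_rate": r,
    }
    return ResultsSummary(table=table, stats=stats, meta=meta)
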