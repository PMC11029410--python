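"""Monte Carlo propagation of input uncertainty; ICER, ROI and probabilities.

Each iteration draws one realisation of every uncertain input —

* intake means per stratum: lognormal moment-matched to the stratum's
  (mean, SD); the PIF's reference distribution is recentred at the draw;
* relative risks per age band: lognormal on RR (normal in log-RR);
* IHD unit costs: one triangular quantile per cost type, mapped through each
  stratum's (min, mode, max) triangle;
* non-IHD per-capita costs: one shared normal multiplier, SD 20% of central;
* policy costs: each government component normal with its own SD; industry
  initial and recurring outlays each get an independent normal multiplier
  (SD 20%), truncated at zero —

then runs the full deterministic pipeline, so reference and intervention
arms share every draw (common random numbers). Point estimates and 95%
uncertainty intervals are the mean and 2.5th-97.5th percentiles across
iterations. Cost-effectiveness uses strict ICER < threshold (US$374/HALY
by default); negative net cost means cost-saving.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import OUTCOMES, Scenario, StratifiedInputs
from .engine import run_pipeline
from .exposure import lognormal_params

__all__ = [
    "IcerResult",
    "McSummary",
    "draw_inputs",
    "run_monte_carlo",
    "icer",
    "roi",
    "probabilities",
]


class McIterationError(RuntimeError):
    """A Monte Carlo iteration produced invalid inputs."""


@dataclass(frozen=True)
class IcerResult:
    """Classified incremental cost-effectiveness ratio."""

    value: float | None  # USD per HALY; None when dominated
    cost_saving: bool
    cost_effective: bool
    dominated: bool


def icer(net_cost: float, halys_gained: float, threshold: float = 374.0) -> IcerResult:
    """Net cost per HALY gained, classified against the threshold.

    Cost-saving when net cost < 0; cost-effective when cost-saving or the
    ratio is strictly below the threshold. Positive net cost with
    non-positive health gain is dominated and carries no ratio.
    """
    if halys_gained == 0 and net_cost != 0:
        raise ValueError("ICER undefined for zero HALYs gained")
    cost_saving = net_cost < 0
    if halys_gained <= 0 and net_cost >= 0:
        return IcerResult(value=None, cost_saving=False, cost_effective=False, dominated=True)
    value = net_cost / halys_gained if halys_gained != 0 else 0.0
    return IcerResult(
        value=value,
        cost_saving=cost_saving,
        cost_effective=cost_saving or value < threshold,
        dominated=False,
    )


def roi(healthcare_savings: float, gov_costs: float) -> float:
    """Return on government investment: healthcare savings per USD spent."""
    if gov_costs <= 0:
        raise ValueError("government costs must be positive")
    return healthcare_savings / gov_costs


def probabilities(
    net_costs: Sequence[float], icers: Sequence[float | None], threshold: float = 374.0
) -> tuple[float, float]:
    """(p_cost_saving, p_cost_effective) across iterations."""
    net_costs = list(net_costs)
    if not net_costs:
        raise ValueError("need at least one iteration")
    saving = np.array([nc < 0 for nc in net_costs])
    effective = np.array(
        [
            nc < 0 or (ic is not None and not math.isnan(ic) and ic < threshold)
            for nc, ic in zip(net_costs, icers)
        ]
    )
    return float(saving.mean()), float(effective.mean())


# ---------------------------------------------------------------------------
# Draws


def _triangular_ppf(u: float, lo: float, mode: float, hi: float) -> float:
    if hi == lo:
        return mode
    c = (mode - lo) / (hi - lo)
    if u < c:
        return lo + math.sqrt(u * (hi - lo) * (mode - lo))
    return hi - math.sqrt((1.0 - u) * (hi - lo) * (hi - mode))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, counter: dict) -> float:
    if sd == 0:
        return mean
    x = rng.normal(mean, sd)
    if x < 0:
        counter["truncated"] = counter.get("truncated", 0) + 1
        return 0.0
    return x


def draw_inputs(
    inputs: StratifiedInputs, rng: np.random.Generator, counter: dict | None = None
) -> StratifiedInputs:
    """One Monte Carlo realisation of all uncertain inputs.

    Draws with zero spread return the central value exactly, so degenerate
    uncertainty collapses the simulation onto the central run.
    """
    counter = counter if counter is not None else {}
    drawn = inputs.copy()
    strata = drawn.strata

    # Intake means: lognormal matched to the stratum's natural (mean, SD).
    means = strata["intake_mean"].to_numpy(float)
    sds = strata["intake_sd"].to_numpy(float)
    z = rng.standard_normal(len(means))
    new_means = means.copy()
    for k in range(len(means)):
        if means[k] > 0 and sds[k] > 0:
            mu, sigma = lognormal_params(means[k], sds[k])
            new_means[k] = math.exp(mu + sigma * z[k])
    strata["intake_mean"] = new_means

    # Relative risks: normal in log-RR per age band.
    rr = drawn.rr
    z_rr = rng.standard_normal(len(rr))
    rr_draw = rr["rr_per_2e"].to_numpy(float).copy()
    for k, sd in enumerate(rr["ln_rr_sd"].to_numpy(float)):
        if sd > 0:
            rr_draw[k] = math.exp(math.log(rr_draw[k]) + sd * z_rr[k])
    rr["rr_per_2e"] = rr_draw

    # IHD unit costs: one quantile per cost type, common across strata.
    for prefix in ("ihd_incident", "ihd_prevalent"):
        u = rng.uniform()
        vals = [
            _triangular_ppf(u, row[f"{prefix}_min"], row[f"{prefix}_mode"], row[f"{prefix}_max"])
            for _, row in strata.iterrows()
        ]
        for k in ("min", "mode", "max"):
            strata[f"{prefix}_{k}"] = vals

    # Non-IHD per-capita costs: one shared normal multiplier, SD = 20%.
    sd_frac = inputs.policy.cost_sd_frac
    mult = _truncated_normal(rng, 1.0, sd_frac, counter)
    if mult != 1.0:
        strata["nonihd_percap"] = strata["nonihd_percap"] * mult

    # Policy costs: per-component government draws; industry initial and
    # recurring streams get independent multipliers.
    comps = tuple(
        (name, kind, _truncated_normal(rng, amount, sd, counter), sd)
        for name, kind, amount, sd in inputs.policy.gov_components
    )
    init_mult = _truncated_normal(rng, 1.0, sd_frac, counter)
    annual_mult = _truncated_normal(rng, 1.0, sd_frac, counter)
    frac = inputs.policy.industry_annual_frac
    if init_mult > 0:
        frac = min(frac * annual_mult / init_mult, 1.0)
    drawn = dataclasses.replace(
        drawn,
        policy=dataclasses.replace(
            inputs.policy,
            gov_components=comps,
            industry_cost_per_product=inputs.policy.industry_cost_per_product * init_mult,
            industry_annual_frac=frac,
        ),
    )
    return drawn


# ---------------------------------------------------------------------------
# Monte Carlo driver


@dataclass
class McSummary:
    """Summaries over Monte Carlo iterations.

    ``summary`` rows: horizon, sex, outcome, mean, p2_5, p97_5.
    ``stats`` per horizon: icer/roi mean and UI, p_cost_saving,
    p_cost_effective. ``iterations`` is the per-iteration outcome dump.
    """

    summary: pd.DataFrame
    stats: dict
    iterations: pd.DataFrame
    n_iter: int
    seed: int | None
    meta: dict = field(default_factory=dict)


def run_monte_carlo(
    inputs: StratifiedInputs,
    scenario: Scenario,
    n_iter: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> McSummary:
    """Propagate input uncertainty through the full pipeline.

    Reproducible bit-for-bit given the seed. Any iteration producing invalid
    inputs aborts with the iteration index in the error message.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    counter: dict = {}
    threshold = scenario.cost_effectiveness_threshold

    records: list[dict] = []
    value_rows: list[pd.DataFrame] = []
    for it in range(n_iter):
        drawn = draw_inputs(inputs, rng, counter)
        try:
            res = run_pipeline(drawn, scenario)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise McIterationError(
                f"iteration {it} failed: {exc}; drawn intake means="
                f"{np.round(drawn.strata['intake_mean'].to_numpy(float), 4).tolist()}"
            ) from exc
        tab = res.table.copy()
        tab["iteration"] = it
        value_rows.append(tab)
        for h, s in res.stats["horizons"].items():
            ic = icer(s["net_cost"], s["halys_gained"], threshold)
            records.append(
                {
                    "iteration": it,
                    "horizon": h,
                    "net_cost": s["net_cost"],
                    "halys_gained": s["halys_gained"],
                    "gov_cost": s["gov_cost"],
                    "industry_cost": s["industry_cost"],
                    "icer": np.nan if ic.value is None else ic.value,
                    "roi": roi(-(s["net_cost"] - s["gov_cost"] - s["industry_cost"]), s["gov_cost"])
                    if s["gov_cost"] > 0
                    else np.nan,
                    "cost_saving": ic.cost_saving,
                    "cost_effective": ic.cost_effective,
                    "dominated": ic.dominated,
                }
            )

    iters = pd.DataFrame(records)
    iters["healthcare_savings"] = -(iters["net_cost"] - iters["gov_cost"] - iters["industry_cost"])
    values = pd.concat(value_rows, ignore_index=True)

    summary = (
        values.groupby(["horizon", "sex", "outcome"], sort=False)["value"]
        .agg(
            mean="mean",
            p2_5=lambda v: float(np.percentile(v, 2.5)),
            p97_5=lambda v: float(np.percentile(v, 97.5)),
        )
        .reset_index()
    )

    stats: dict = {}
    for h, grp in iters.groupby("horizon", sort=False):
        p_saving, p_effective = probabilities(
            grp["net_cost"].tolist(),
            [None if math.isnan(v) else v for v in grp["icer"]],
            threshold,
        )
        def _mi(series: pd.Series) -> dict:
            clean = series.dropna()
            if clean.empty:
                return {"mean": float("nan"), "p2_5": float("nan"), "p97_5": float("nan")}
            return {
                "mean": float(clean.mean()),
                "p2_5": float(np.percentile(clean, 2.5)),
                "p97_5": float(np.percentile(clean, 97.5)),
            }

        stats[h] = {
            "p_cost_saving": p_saving,
            "p_cost_effective": p_effective,
            "icer": _mi(grp["icer"]),
            "roi": _mi(grp["roi"]),
            "net_cost": _mi(grp["net_cost"]),
            "halys_gained": _mi(grp["halys_gained"]),
        }

    meta = {"truncated_draws": counter.get("truncated", 0), "threshold": threshold}
    return McSummary(
        summary=summary, stats=stats, iterations=iters, n_iter=n_iter, seed=seed, meta=meta
    )
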