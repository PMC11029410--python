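"""Named scenario variants and plan orchestration.

The default plan mirrors the published univariate sensitivity analyses around
the primary (full elimination, 3% discount) run: discount rates of 0% and 6%;
preintervention intake mean and SD scaled by 0.5 and 1.5; a residual
postintervention intake of 0.1 +/- 0.01 %E; doubled product count; no
industry cost; 50% greater monitoring costs; and a threshold analysis with
absolute intake reductions of 0.05-0.20 %E.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import IntakeDistribution, Scenario, StratifiedInputs
from .engine import run_pipeline
from .uncertainty import McSummary, run_monte_carlo

__all__ = ["AnalysisPlan", "build_default_plan", "run_plan", "variant_seed"]


@dataclass
class AnalysisPlan:
    """Ordered mapping of unique variant names to scenarios; 'primary' first."""

    variants: dict[str, Scenario]

    def __post_init__(self) -> None:
        if "primary" not in self.variants:
            raise ValueError("plan must contain a 'primary' variant")
        # dict keys are unique by construction; enforce primary-first order
        names = list(self.variants)
        if names[0] != "primary":
            self.variants = {"primary": self.variants["primary"]} | {
                k: v for k, v in self.variants.items() if k != "primary"
            }


def build_default_plan(base: Scenario | None = None) -> AnalysisPlan:
    base = base or Scenario()
    t = base.toggles

    def tog(**kw) -> Scenario:
        return base.model_copy(update={"toggles": t.model_copy(update=kw)})

    variants: dict[str, Scenario] = {
        "primary": base,
        "discount_0pct": base.model_copy(update={"discount_rate": 0.0}),
        "discount_6pct": base.model_copy(update={"discount_rate": 0.06}),
        "intake_x0.5": tog(intake_scale=0.5),
        "intake_x1.5": tog(intake_scale=1.5),
        "post_intake_0.1e": base.model_copy(
            update={
                "post_intake": IntakeDistribution(mean_e_pct=0.1, sd_e_pct=0.01, family="lognormal")
            }
        ),
        "products_x2": tog(products_scale=2.0),
        "no_industry_cost": tog(no_industry_cost=True),
        "monitoring_x1.5": tog(monitoring_scale=1.5),
    }
    for shift in (0.05, 0.10, 0.15, 0.20):
        variants[f"threshold_{shift:.2f}e"] = tog(intake_shift_e_pct=shift)
    return AnalysisPlan(variants=variants)


def variant_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic per-variant seed, independent of plan composition."""
    digest = sum(ord(ch) * 131**k for k, ch in enumerate(name)) % (2**31)
    return np.random.SeedSequence([int(seed) % (2**31), digest])


@dataclass
class PlanResults:
    central: dict[str, object]  # variant -> ResultsSummary
    mc: dict[str, McSummary]
    comparison: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)


def run_plan(
    inputs: StratifiedInputs,
    plan: AnalysisPlan | None = None,
    n_iter: int = 2000,
    seed: int = 0,
    monte_carlo: bool = True,
) -> PlanResults:
    """Run every variant through the pipeline (with MC where configured).

    Each variant draws from its own deterministic seed stream, so results are
    unaffected by which other variants are present. A variant that fails
    validation is recorded and the remaining variants continue.
    """
    plan = plan or build_default_plan()
    central: dict[str, object] = {}
    mc: dict[str, McSummary] = {}
    errors: dict[str, str] = {}
    rows = []
    for name, scenario in plan.variants.items():
        try:
            central[name] = run_pipeline(inputs, scenario)
            if monte_carlo:
                rng = np.random.default_rng(variant_seed(seed, name))
                mc[name] = run_monte_carlo(inputs, scenario, n_iter=n_iter, rng=rng, seed=seed)
        except Exception as exc:  # noqa: BLE001 - variant isolation
            errors[name] = str(exc)
            continue
        for h, s in central[name].stats["horizons"].items():
            row = {
                "variant": name,
                "horizon": h,
                "halys_gained": s["halys_gained"],
                "net_cost": s["net_cost"],
                "icer": s["icer"],
                "roi": s["roi"],
            }
            if monte_carlo:
                st = mc[name].stats[h]
                row.update(
                    p_cost_saving=st["p_cost_saving"],
                    p_cost_effective=st["p_cost_effective"],
                    net_cost_mean=st["net_cost"]["mean"],
                    net_cost_p2_5=st["net_cost"]["p2_5"],
                    net_cost_p97_5=st["net_cost"]["p97_5"],
                    halys_mean=st["halys_gained"]["mean"],
                )
            rows.append(row)
    comparison = pd.DataFrame(rows)
    return PlanResults(central=central, mc=mc, comparison=comparison, errors=errors)
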