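#!/usr/bin/env python
"""Figures from the saved Monte Carlo and sensitivity outputs.

Reads results/mc/mc_summary.csv and results/sensitivity.csv (produced by
03_monte_carlo.py and 04_sensitivity.py) and renders:

* sex-specific averted events/deaths, HALYs and healthcare savings with 95%
  uncertainty bars, per horizon;
* net cost vs HALYs gained across sensitivity variants with the $374/HALY
  cost-effectiveness threshold line.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "figures"


def sex_panels(summary: pd.DataFrame) -> None:
    panels = [
        ("ihd_events", -1, "IHD events averted"),
        ("ihd_deaths", -1, "IHD deaths averted"),
        ("halys", 1, "HALYs gained"),
        ("total_healthcare_cost", -1e-6, "healthcare savings (M$)"),
    ]
    horizons = ["5y", "10y", "lifetime"]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    for ax, (outcome, scale, title) in zip(axes.flat, panels):
        for k, sex in enumerate(("female", "male")):
            rows = summary[(summary.outcome == outcome) & (summary.sex == sex)]
            rows = rows.set_index("horizon").loc[horizons]
            x = [i + (k - 0.5) * 0.35 for i in range(len(horizons))]
            lo = (rows["mean"] - rows[["p2_5", "p97_5"]].min(axis=1)) * abs(scale)
            hi = (rows[["p2_5", "p97_5"]].max(axis=1) - rows["mean"]) * abs(scale)
            ax.bar(x, rows["mean"] * scale, width=0.35, yerr=[lo, hi], capsize=3, label=sex)
        ax.set_xticks(range(len(horizons)), horizons)
        ax.set_title(title, fontsize=10)
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(OUT / "sex_specific_effects.png", dpi=150)
    print(f"wrote {OUT / 'sex_specific_effects.png'}")


def sensitivity_plane(comp: pd.DataFrame) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(11, 5), sharey=False)
    for ax, h in zip(axes, ("5y", "lifetime")):
        sel = comp[comp.horizon == h]
        ax.scatter(sel["halys_gained"], sel["net_cost"] / 1e6, s=25)
        for _, row in sel.iterrows():
            ax.annotate(row["variant"], (row["halys_gained"], row["net_cost"] / 1e6), fontsize=6)
        xs = sorted(sel["halys_gained"])
        ax.plot(xs, [374 * x / 1e6 for x in xs], "k:", lw=1, label="$374/HALY threshold")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel("HALYs gained")
        ax.set_ylabel("net cost (M$)")
        ax.set_title(f"horizon: {h}", fontsize=10)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "sensitivity_plane.png", dpi=150)
    print(f"wrote {OUT / 'sensitivity_plane.png'}")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(ROOT / "results" / "mc" / "mc_summary.csv")
    sex_panels(summary)
    comp = pd.read_csv(ROOT / "results" / "sensitivity.csv")
    sensitivity_plane(comp)


if __name__ == "__main__":
    main()
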