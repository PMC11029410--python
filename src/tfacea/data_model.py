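"""Domain types, input-table schemas, validation and CSV readers/writers.

The model population is the adult Nigerian population stratified by sex and
5-year age band (20-24 ... 90+): 15 bands per sex, 30 strata in total.
Every rate is annual (events per person-year), intakes are expressed as per
cent of total energy (%E), and all monetary amounts are 2019 USD; Naira
values are obtained only at reporting time through :class:`CurrencyContext`.

Input tables (one directory, plain CSV with headers):

``demography.csv``
    sex, age_lo, pop, acm — population count and all-cause mortality rate.
``epi_ihd.csv``
    sex, age_lo, ihd_inc, ihd_prev, ihd_mort, ihd_yld_rate, other_yld_rate —
    ischaemic heart disease incidence, prevalence (proportion), cause-specific
    mortality, and years-lived-with-disability rates (per person) from IHD and
    from all other causes.
``intake.csv``
    sex, age_lo, intake_mean, intake_sd — trans-fat intake in %E.
``rr.csv``
    age_lo, rr_per_2e, ln_rr_sd — relative risk of incident IHD per 2%E of
    trans-fat intake (age-specific, shared across sexes).
``costs_health.csv``
    sex, age_lo, ihd_incident_min/mode/max, ihd_prevalent_min/mode/max,
    nonihd_percap — triangular distributions of unit IHD costs (acute care per
    incident event; follow-up care per prevalent case-year) and per-capita
    non-IHD health expenditure.
``costs_policy.csv``
    component, kind (oneoff|annual), amount_usd, sd_usd — government
    implementation cost components (legislation, monitoring, enforcement,
    campaigns). Industry reformulation parameters live in the run config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "AGE_LOWER_BOUNDS",
    "SEXES",
    "AGE_CEILING",
    "Stratum",
    "IntakeDistribution",
    "RelativeRisk",
    "Scenario",
    "ScenarioToggles",
    "PolicyCosts",
    "CurrencyContext",
    "StratifiedInputs",
    "ResultsSummary",
    "InputValidationError",
    "read_inputs",
    "write_inputs",
    "write_results",
    "read_results",
    "load_run_config",
]

#: Lower bounds of the 5-year age bands (20-24 ... 90+): 15 bands per sex,
#: 30 strata. The top band is open-ended and supplies rates up to age 100.
AGE_LOWER_BOUNDS: tuple[int, ...] = tuple(range(20, 95, 5))
SEXES: tuple[str, str] = ("female", "male")
#: Cohorts are simulated until extinction or this age.
AGE_CEILING: int = 100

#: Tidy-results outcome names (intervention minus reference, except policy
#: streams which exist only in the intervention arm).
OUTCOMES: tuple[str, ...] = (
    "ihd_events",
    "ihd_deaths",
    "halys",
    "ihd_healthcare_cost",
    "nonihd_healthcare_cost",
    "total_healthcare_cost",
    "policy_cost",
    "net_cost",
)

STRATA_COLUMNS: tuple[str, ...] = (
    "pop",
    "acm",
    "ihd_inc",
    "ihd_prev",
    "ihd_mort",
    "ihd_yld_rate",
    "other_yld_rate",
    "intake_mean",
    "intake_sd",
    "ihd_incident_min",
    "ihd_incident_mode",
    "ihd_incident_max",
    "ihd_prevalent_min",
    "ihd_prevalent_mode",
    "ihd_prevalent_max",
    "nonihd_percap",
)


class InputValidationError(ValueError):
    """Raised when an input table violates the published schema or an
    epidemiological invariant; the message names the offending file/row."""


def band_of_age(age: float) -> int:
    """Lower bound of the 5-year band containing ``age``, clipped to [20, 95]."""
    return int(min(max(5 * (int(age) // 5), AGE_LOWER_BOUNDS[0]), AGE_LOWER_BOUNDS[-1]))


@dataclass(frozen=True, order=True)
class Stratum:
    sex: str
    age_lo: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InputValidationError(f"unknown sex {self.sex!r}")
        if self.age_lo not in AGE_LOWER_BOUNDS:
            raise InputValidationError(f"age band lower bound {self.age_lo} not in {AGE_LOWER_BOUNDS}")

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_lo}-{self.age_lo + 4}"


def all_strata() -> list[Stratum]:
    return [Stratum(s, a) for s in SEXES for a in AGE_LOWER_BOUNDS]


class IntakeDistribution(BaseModel):
    """Trans-fat intake distribution on the natural %E scale.

    A ``lognormal`` family is parameterised by its natural-scale mean and SD
    (moment matching to log-scale parameters happens in the exposure module);
    ``degenerate`` is a point mass at ``mean_e_pct``.
    """

    model_config = ConfigDict(frozen=True)

    mean_e_pct: float = Field(ge=0)
    sd_e_pct: float = Field(default=0.0, ge=0)
    family: Literal["lognormal", "degenerate"] = "lognormal"

    @model_validator(mode="after")
    def _check(self) -> "IntakeDistribution":
        if self.family == "lognormal" and self.mean_e_pct <= 0:
            raise ValueError("lognormal intake requires mean_e_pct > 0")
        return self


class RelativeRisk(BaseModel):
    """Relative risk of incident IHD per 2%E trans-fat intake for one age band."""

    model_config = ConfigDict(frozen=True)

    age_lo: int
    rr_per_2e: float = Field(gt=0)
    ln_rr_sd: float = Field(default=0.0, ge=0)


class ScenarioToggles(BaseModel):
    """Switches for the deterministic sensitivity analyses."""

    model_config = ConfigDict(frozen=True)

    no_industry_cost: bool = False
    monitoring_scale: float = Field(default=1.0, ge=0)
    products_scale: float = Field(default=1.0, ge=0)
    intake_scale: float = Field(default=1.0, gt=0)
    #: Threshold analysis: counterfactual mean = max(ref mean − shift, 0),
    #: SD unchanged. 0 disables and the counterfactual is ``post_intake``.
    intake_shift_e_pct: float = Field(default=0.0, ge=0)


class Scenario(BaseModel):
    """Exposure counterfactual plus economic settings for one model run."""

    model_config = ConfigDict(frozen=True)

    post_intake: IntakeDistribution = IntakeDistribution(mean_e_pct=0.0, family="degenerate")
    tmrel_e_pct: float = Field(default=0.0, ge=0)
    discount_rate: float = Field(default=0.03, ge=0)
    horizons: tuple[str, ...] = ("5y", "10y", "lifetime")
    toggles: ScenarioToggles = ScenarioToggles()
    cost_effectiveness_threshold: float = Field(default=374.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        for h in self.horizons:
            horizon_years(h)  # raises on unknown labels
        if len(set(self.horizons)) != len(self.horizons):
            raise ValueError("duplicate horizons")
        return self


def horizon_years(label: str, lifetime_years: int = AGE_CEILING - AGE_LOWER_BOUNDS[0]) -> int:
    """Number of simulated calendar years covered by a horizon label."""
    if label == "lifetime":
        return lifetime_years
    if label.endswith("y") and label[:-1].isdigit():
        n = int(label[:-1])
        if n >= 1:
            return min(n, lifetime_years)
    raise ValueError(f"unknown horizon {label!r}")


@dataclass(frozen=True)
class PolicyCosts:
    """Government and industry implementation costs (2019 USD).

    Government components are kept individually so Monte Carlo draws preserve
    each component's own normal (SD = 20% of central) uncertainty.
    """

    #: rows: (component, kind in {oneoff, annual}, amount_usd, sd_usd)
    gov_components: tuple[tuple[str, str, float, float], ...]
    industry_products: int
    industry_cost_per_product: float
    industry_annual_frac: float
    cost_sd_frac: float = 0.20

    def __post_init__(self) -> None:
        for name, kind, amount, sd in self.gov_components:
            if kind not in ("oneoff", "annual"):
                raise InputValidationError(f"policy component {name!r}: kind must be oneoff|annual")
            if amount < 0 or sd < 0:
                raise InputValidationError(f"policy component {name!r}: negative amount/sd")
        if self.industry_products < 0 or self.industry_cost_per_product < 0:
            raise InputValidationError("industry reformulation inputs must be nonnegative")
        if not 0 <= self.industry_annual_frac <= 1:
            raise InputValidationError("industry_annual_frac must lie in [0, 1]")

    @property
    def gov_oneoff(self) -> float:
        return sum(a for _, k, a, _ in self.gov_components if k == "oneoff")

    @property
    def gov_annual(self) -> float:
        return sum(a for _, k, a, _ in self.gov_components if k == "annual")

    @property
    def industry_initial(self) -> float:
        return self.industry_products * self.industry_cost_per_product


class CurrencyContext(BaseModel):
    model_config = ConfigDict(frozen=True)

    usd_to_ngn: float = Field(default=358.0, gt=0)
    report_ngn: bool = False

    def to_ngn(self, usd: float) -> float:
        return usd * self.usd_to_ngn


# ---------------------------------------------------------------------------
# Stratified inputs container


@dataclass
class StratifiedInputs:
    """All per-(sex, age band) model inputs plus policy/currency context.

    ``strata`` is a DataFrame indexed by (sex, age_lo) with the columns in
    :data:`STRATA_COLUMNS`; ``rr`` is indexed by age_lo with columns
    rr_per_2e, ln_rr_sd.
    """

    strata: pd.DataFrame
    rr: pd.DataFrame
    policy: PolicyCosts
    currency: CurrencyContext = field(default_factory=CurrencyContext)

    def validate(self, require_full: bool = True) -> "StratifiedInputs":
        df = self.strata
        if not isinstance(df.index, pd.MultiIndex) or df.index.names != ["sex", "age_lo"]:
            raise InputValidationError("strata table must be indexed by (sex, age_lo)")
        missing_cols = set(STRATA_COLUMNS) - set(df.columns)
        if missing_cols:
            raise InputValidationError(f"strata table missing columns: {sorted(missing_cols)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise InputValidationError(f"duplicate stratum {dup}")
        for sex, age_lo in df.index:
            Stratum(sex, int(age_lo))  # validates labels
        if require_full:
            expected = {(s.sex, s.age_lo) for s in all_strata()}
            present = {(s, int(a)) for s, a in df.index}
            missing = expected - present
            if missing:
                raise InputValidationError(f"missing stratum {sorted(missing)[0]} (of {len(missing)} missing)")
            ages = set(int(a) for a in self.rr.index)
            if ages != set(AGE_LOWER_BOUNDS):
                raise InputValidationError("rr table must cover every 5-year age band once")
        for (sex, age_lo), row in df.iterrows():
            where = f"stratum ({sex}, {age_lo})"
            for col in STRATA_COLUMNS:
                v = row[col]
                if not np.isfinite(v) or v < 0:
                    raise InputValidationError(f"{where}: {col}={v} must be finite and >= 0")
            if not 0 <= row["ihd_prev"] < 1:
                raise InputValidationError(f"{where}: ihd_prev={row['ihd_prev']} outside [0, 1)")
            if row["ihd_mort"] > row["acm"] + 1e-15:
                raise InputValidationError(
                    f"{where}: ihd_mort={row['ihd_mort']} exceeds all-cause mortality {row['acm']}"
                )
            if row["ihd_mort"] > 0 and row["ihd_prev"] == 0:
                raise InputValidationError(f"{where}: ihd_mort > 0 with ihd_prev = 0 (case fatality undefined)")
            if row["ihd_prev"] > 0 and not 0 <= row["ihd_yld_rate"] / row["ihd_prev"] <= 1:
                raise InputValidationError(f"{where}: implied IHD disability weight outside [0, 1]")
            if row["intake_mean"] > 0 and row["intake_sd"] < 0:
                raise InputValidationError(f"{where}: negative intake SD")
            for prefix in ("ihd_incident", "ihd_prevalent"):
                lo, mode, hi = (row[f"{prefix}_{k}"] for k in ("min", "mode", "max"))
                if not lo <= mode <= hi:
                    raise InputValidationError(f"{where}: triangular {prefix} costs need min <= mode <= max")
        for age_lo, row in self.rr.iterrows():
            RelativeRisk(age_lo=int(age_lo), rr_per_2e=row["rr_per_2e"], ln_rr_sd=row["ln_rr_sd"])
        return self

    def sexes(self) -> list[str]:
        return sorted(self.strata.index.get_level_values("sex").unique())

    def intake(self, sex: str, age_lo: int) -> IntakeDistribution:
        row = self.strata.loc[(sex, age_lo)]
        if row["intake_mean"] == 0:
            return IntakeDistribution(mean_e_pct=0.0, family="degenerate")
        return IntakeDistribution(
            mean_e_pct=float(row["intake_mean"]), sd_e_pct=float(row["intake_sd"]), family="lognormal"
        )

    def relative_risk(self, age_lo: int) -> RelativeRisk:
        row = self.rr.loc[age_lo]
        return RelativeRisk(age_lo=age_lo, rr_per_2e=float(row["rr_per_2e"]), ln_rr_sd=float(row["ln_rr_sd"]))

    def copy(self) -> "StratifiedInputs":
        return StratifiedInputs(
            strata=self.strata.copy(),
            rr=self.rr.copy(),
            policy=dataclasses.replace(self.policy),
            currency=self.currency,
        )

    def equals(self, other: "StratifiedInputs") -> bool:
        return (
            self.strata.sort_index().equals(other.strata.sort_index())
            and self.rr.sort_index().equals(other.rr.sort_index())
            and self.policy == other.policy
            and self.currency == other.currency
        )


# ---------------------------------------------------------------------------
# Readers / writers

_TABLE_FILES = {
    "demography": ("demography.csv", ["sex", "age_lo", "pop", "acm"]),
    "epi_ihd": (
        "epi_ihd.csv",
        ["sex", "age_lo", "ihd_inc", "ihd_prev", "ihd_mort", "ihd_yld_rate", "other_yld_rate"],
    ),
    "intake": ("intake.csv", ["sex", "age_lo", "intake_mean", "intake_sd"]),
    "rr": ("rr.csv", ["age_lo", "rr_per_2e", "ln_rr_sd"]),
    "costs_health": (
        "costs_health.csv",
        [
            "sex",
            "age_lo",
            "ihd_incident_min",
            "ihd_incident_mode",
            "ihd_incident_max",
            "ihd_prevalent_min",
            "ihd_prevalent_mode",
            "ihd_prevalent_max",
            "nonihd_percap",
        ],
    ),
    "costs_policy": ("costs_policy.csv", ["component", "kind", "amount_usd", "sd_usd"]),
}


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise InputValidationError(f"missing input table {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise InputValidationError(f"{path.name}: missing columns {sorted(missing)}")
    return df[list(columns)]


def read_inputs(
    input_dir: str | Path,
    config: Mapping | str | Path | None = None,
    require_full: bool = True,
) -> StratifiedInputs:
    """Read and validate the standard CSV table set from ``input_dir``.

    ``config`` (mapping or YAML path) supplies the industry reformulation
    parameters and the currency context; defaults are used when absent.
    """
    input_dir = Path(input_dir)
    if config is None and (input_dir / "config.yaml").exists():
        config = input_dir / "config.yaml"
    cfg = _load_config_mapping(config)

    tables = {}
    for key, (fname, cols) in _TABLE_FILES.items():
        tables[key] = _read_table(input_dir / fname, cols)

    stratified = tables["demography"]
    for key in ("epi_ihd", "intake", "costs_health"):
        before = len(stratified)
        stratified = stratified.merge(tables[key], on=["sex", "age_lo"], how="outer", indicator=True)
        bad = stratified[stratified["_merge"] != "both"]
        if len(bad):
            sex, age = bad.iloc[0][["sex", "age_lo"]]
            raise InputValidationError(
                f"{_TABLE_FILES[key][0]}: stratum ({sex}, {age}) present in only one of the tables"
            )
        stratified = stratified.drop(columns="_merge")
        del before
    stratified["age_lo"] = stratified["age_lo"].astype(int)
    stratified = stratified.set_index(["sex", "age_lo"]).sort_index()

    rr = tables["rr"].copy()
    rr["age_lo"] = rr["age_lo"].astype(int)
    if rr["age_lo"].duplicated().any():
        raise InputValidationError("rr.csv: duplicated age band")
    rr = rr.set_index("age_lo").sort_index()

    gov = tuple(
        (str(r.component), str(r.kind), float(r.amount_usd), float(r.sd_usd))
        for r in tables["costs_policy"].itertuples()
    )
    industry = cfg.get("industry", {})
    policy = PolicyCosts(
        gov_components=gov,
        industry_products=int(industry.get("products", 331)),
        industry_cost_per_product=float(industry.get("cost_per_product_usd", 42_500.0)),
        industry_annual_frac=float(industry.get("annual_frac", 0.01)),
    )
    currency = CurrencyContext(**cfg.get("currency", {}))
    return StratifiedInputs(strata=stratified, rr=rr, policy=policy, currency=currency).validate(
        require_full=require_full
    )


def write_inputs(inputs: StratifiedInputs, out_dir: str | Path) -> None:
    """Write the standard CSV table set (inverse of :func:`read_inputs`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flat = inputs.strata.reset_index()
    for key, (fname, cols) in _TABLE_FILES.items():
        if key == "rr":
            df = inputs.rr.reset_index()[cols]
        elif key == "costs_policy":
            df = pd.DataFrame(
                [dict(zip(cols, row)) for row in inputs.policy.gov_components], columns=cols
            )
        else:
            df = flat[cols]
        df.to_csv(out_dir / fname, index=False)
    cfg = {
        "industry": {
            "products": inputs.policy.industry_products,
            "cost_per_product_usd": inputs.policy.industry_cost_per_product,
            "annual_frac": inputs.policy.industry_annual_frac,
        },
        "currency": {
            "usd_to_ngn": inputs.currency.usd_to_ngn,
            "report_ngn": inputs.currency.report_ngn,
        },
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _load_config_mapping(config: Mapping | str | Path | None) -> Mapping:
    if config is None:
        return {}
    if isinstance(config, Mapping):
        return config
    with open(config) as fh:
        loaded = yaml.safe_load(fh)
    return loaded or {}


@dataclass(frozen=True)
class RunConfig:
    scenario: Scenario
    n_iter: int = 2000
    seed: int = 12345
    raw: Mapping = field(default_factory=dict)


def load_run_config(config: Mapping | str | Path | None) -> RunConfig:
    """Build the run configuration (scenario + Monte Carlo settings)."""
    cfg = _load_config_mapping(config)
    scenario = Scenario(**cfg.get("scenario", {}))
    mc = cfg.get("mc", {})
    return RunConfig(
        scenario=scenario,
        n_iter=int(mc.get("n_iter", 2000)),
        seed=int(mc.get("seed", 12345)),
        raw=cfg,
    )


# ---------------------------------------------------------------------------
# Results container


@dataclass
class ResultsSummary:
    """Tidy per-horizon results plus scalar statistics and run metadata.

    ``table`` columns: horizon, sex ("female" | "male" | "total"), outcome
    (one of :data:`OUTCOMES`), value. Health and healthcare outcomes are
    intervention-minus-reference differences; policy_cost and net_cost are
    population-level and carried only on the "total" rows (NaN otherwise).
    """

    table: pd.DataFrame
    stats: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def value(self, horizon: str, outcome: str, sex: str = "total") -> float:
        t = self.table
        sel = t[(t["horizon"] == horizon) & (t["sex"] == sex) & (t["outcome"] == outcome)]
        if len(sel) != 1:
            raise KeyError((horizon, sex, outcome))
        return float(sel["value"].iloc[0])


def config_hash(scenario: Scenario, extra: Mapping | None = None) -> str:
    payload = {"scenario": scenario.model_dump(), "extra": dict(extra or {})}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(summary: ResultsSummary, out_dir: str | Path) -> None:
    """Write ``results.csv`` (tidy table) and ``manifest.json`` (stats + meta)."""
    if summary.table.empty or summary.table["horizon"].nunique() == 0:
        raise ValueError("results summary has no horizons")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ["horizon", "sex", "outcome", "value"]
    summary.table[cols].to_csv(out_dir / "results.csv", index=False, float_format="%.17g")
    manifest = {"stats": summary.stats, "meta": summary.meta}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_results(out_dir: str | Path) -> ResultsSummary:
    out_dir = Path(out_dir)
    table = pd.read_csv(out_dir / "results.csv", float_precision="round_trip")
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    return ResultsSummary(table=table, stats=manifest.get("stats", {}), meta=manifest.get("meta", {}))
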