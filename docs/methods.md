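# Methods

## Model structure and assumptions

The model compares two closed populations that share every input: a
*reference* arm that keeps the observed trans-fat intake, and an
*intervention* arm in which a mandatory iTFA limit changes the intake
distribution (full elimination to 0%E in the primary scenario). The adult
population (ages 20+) is split into 30 strata — two sexes × fifteen 5-year
age bands (20–24 … 90+) — and each stratum enters a cohort lifetable at the
lower bound of its band, simulated in single years of age until extinction
or age 100. No new cohorts enter, and background rates are held constant
over calendar time: the model isolates the policy's effect on the people
alive at implementation.

Three standard assumptions of the proportional multistate lifetable frame
are inherited here. First, cause-deleted mortality is formed additively:
total mortality in an arm is all-cause mortality minus the input IHD
mortality plus the IHD mortality produced by the disease submodel for that
arm. Second, the disease submodel is conditional on surviving other causes,
i.e. IHD and non-IHD mortality act independently. Third, the policy affects
only IHD incidence (through the PIF); case fatality, disability weights and
all costs per case are unchanged.

### Exposure and potential impact fraction

Intake distributions are lognormal, parameterised by their natural-scale
mean and SD via moment matching (σ² = ln(1 + CV²), μ = ln m − σ²/2).
Relative risk is log-linear in intake above the theoretical-minimum-risk
level (TMREL = 0%E): RR(x) = RR₂^((x − TMREL)⁺/2). The PIF
(1 − E_cf[RR]/E_ref[RR]) is evaluated with adaptive Gauss–Kronrod
quadrature in standard-normal coordinates of the log intake.

One numerical point deserves emphasis: E[RR(X)] under a lognormal X is
formally divergent — exp(c·x) eventually outgrows the lognormal tail — but
the divergence lives entirely at intakes that cannot occur. The expectation
is therefore taken over the physiological domain [0, 10]%E (trans-fat never
contributes more than a few percent of energy; the omitted mass is far
below 1e−9 for any realistic mean/SD). Without this cap, extreme Monte
Carlo draws produce arbitrarily inflated expectations.

The full PIF applies to incidence from the first simulated year: the policy
is modelled at its post-regulation steady state, with no phase-in lag.
Because TMREL = 0, exponentiating intake above TMREL and absolute intake
coincide.

### Disease submodel

The illness–death system dS = −iS, dC = iS − fC, dD = fC (remission fixed
at 0; IHD is chronic, with ongoing follow-up care) is advanced one year at
a time by its exact solution, with the f = i degeneracy handled by a series
limit rather than branching on near-equality. Event and death *rates among
the living* divide flows by the exact within-year average occupancies
(time-integrals of S and C), so they agree with adaptive ODE integration to
better than 1e−8; note this means a disease-free state with positive
incidence still produces a small positive IHD death rate, because cases
incident within the year contribute person-time at risk.

Case fatality is derived per stratum as f = IHD mortality / IHD prevalence.
This is a deliberate, documented stand-in for a full DisMod-style
reconciliation of incidence, prevalence and mortality: it is exact at the
steady state the synthetic generator constructs, but real GBD exports are
not perfectly mutually consistent and a smoothing reconciliation could give
different f(a).

Cohort initial conditions set prevalence at entry to the stratum's input
prevalence. Rates are piecewise constant in single years of age, looked up
from the 5-year bands by step function (no smoothing); ages above the last
band reuse it.

### Lifetable, HALYs, aggregation

Survivorship uses the exponential within-year hazard, l(a+1) = l(a)e^(−m),
which composes cleanly with the exponential disease submodel (the classical
q = m/(1 + m/2) conversion gives visibly different numbers only at the very
oldest ages). Person-years are trapezoidal; incident cases are counted in
the year they occur. HALYs weight each person-year by 1 − other-cause YLD
rate and subtract prevalent IHD person-years times the per-case IHD
disability weight (YLD rate / prevalence), floored at zero.

Horizon aggregation sums intervention-minus-reference differences over all
cohorts within the first 5, 10 or 80 calendar years. Averted events and
deaths are undiscounted counts; HALYs and all costs discount year t by
(1 + r)^(−t) with t = 0 in the first simulation year (a convention that must
simply be fixed; results at 3% shift by ~1.5% per half-year of origin).
Totals are computed as sums of the per-sex values, so sex additivity holds
exactly in floating point; the healthcare decomposition (total = IHD +
non-IHD) is exact per sex and per year, and holds on the total row up to
reassociation of the same terms.

### Costs

All monetary inputs are 2019 USD; the model does no inflation arithmetic
and converts to Naira only for reporting (₦358/USD). Per year and arm:
IHD costs = incident cases × acute-care cost + prevalent person-years ×
annual follow-up cost; non-IHD costs = person-years × per-capita non-IHD
expenditure of the stratum at the attained age. Charging non-IHD costs to
all person-years is what prices the *added years of life* the intervention
creates — it is why total savings are smaller than IHD-specific savings,
and why a 0% discount rate can flip the lifetime net cost positive.

Policy costs enter only the intervention arm. Government components
(legislation one-off; monitoring, enforcement and campaign annuals) are read
per component. Defaults place the one-off at $0.10M in year 1 and $0.24M/yr
recurring — a plausible scale for a national food-standards amendment with
agency monitoring; the true component schedule is configurable via
`costs_policy.csv`. Industry reformulation costs 331 products × $42,500 in
year 1 (a UK-derived per-product estimate of £25,000, carried to 2019 USD
with a combined exchange/inflation factor of 1.70, both overridable) plus a
recurring 1% of the initial outlay. Scenario toggles double the product
count, zero the industry stream, or scale the annual government stream by
1.5 without touching the one-off.

## Uncertainty analysis

Monte Carlo (default n = 2000, single seeded generator, bit-reproducible):

| quantity | distribution | spread |
|---|---|---|
| intake mean, per stratum | lognormal matched to (mean, SD) | stratum SD |
| RR per 2%E, per age band | lognormal in RR (normal in ln RR) | ln-RR SD 0.05 |
| IHD unit costs | triangular (min, mode, max) | [½·mode, 2·mode] |
| non-IHD per-capita costs | normal multiplier | SD 20% |
| each gov component | normal | SD 20% (per component) |
| industry initial & annual | independent normal multipliers | SD 20% |

Drawing the *parameters* of the intake distribution (and recentring the PIF
integral at the drawn mean, SD unchanged) treats the stratum mean as the
uncertain quantity, which is the conventional reading of "draws from the
intake distribution" in this modelling lineage; RR draws are shared across
sexes and strata within an age band, and independent across bands. Both
arms of an iteration share every draw (common random numbers). Draws with
zero spread return the central value exactly, so a fully degenerate
configuration reproduces the deterministic run bit for bit. Negative normal
draws are truncated at zero and counted (the truncation rate is negligible
at CV 0.2). ICER uses strict "<" at the $374/HALY threshold;
cost-effectiveness probability counts iterations that are cost-saving or
below the threshold; ROI is computed per iteration and summarised (the
ratio of means is a different, only approximately equal, quantity).

The sensitivity plan runs each variant with an MC stream seeded from the
variant's name, so a variant's results are invariant to which other
variants run alongside it.

## Synthetic data generator

The generator emulates the *structure* of GBD-2019-style inputs, not
Nigeria's actual values: Gompertz all-cause mortality (0.003·e^(0.07·(a−20)),
male ×1.15), log-linear IHD incidence (6e−4 at age 40, slope 0.08/yr, male
×1.4), constant case fatality 0.08/yr, a 90M adult population declining
4.5%/yr of age, intake means drawn uniformly in 0.25–0.31%E with CV 0.35,
RR₂ = 1.23, IHD disability weight 0.08, other-cause YLD 0.06 + 0.001/yr of
age, and cost levels at Nigerian magnitudes (incident $300, prevalent
$150/yr, non-IHD per-capita $30 at age 20 growing 1.5%/yr).

Prevalence is *not* sampled: it is the prevalence implied by the incidence
and case fatality under the illness–death process, computed by advancing
the submodel from age 20 (with a starting prevalence equivalent to roughly
a decade of exposure to the age-20 rates), and IHD mortality is case
fatality × prevalence. This makes the disease stage self-consistent by
construction — a property the test suite verifies against an independent
ODE integration of dp/da = i(1−p) − f·p(1−p).

What passing tests on synthetic data do and do not show: they demonstrate
that every stage implements its stated mathematics (closed forms, oracles,
invariances, accounting identities) and that the pipeline's qualitative
behaviour (direction and ordering of sensitivity analyses, cost-saving
patterns) is robust. They do not validate Nigeria-specific magnitudes:
real GBD inputs have internally inconsistent i/p/f triples, age patterns
that are not exactly Gompertz/log-linear, and cost structures with
different skew — so absolute outputs on synthetic data are illustrative,
not estimates for Nigeria.

A two-stratum worked toy (constant mortality 0.01 and 0.02/yr, no IHD)
gives a closed-form lifetable — life expectancy at 20 equals
(1+e^(−m))/2 · (1−e^(−80m))/(1−e^(−m)) — used for exact arithmetic tests.

## Degenerate inputs and edge cases

* Prevalence 0 with positive IHD mortality, prevalence ≥ 1, IHD mortality
  above all-cause mortality, or an implied disability weight outside [0, 1]
  are rejected at read time with the offending stratum named.
* PIF > 1 (impossible with RR ≥ 1) would drive incidence negative and
  raises; identical reference and counterfactual distributions short-circuit
  to PIF = 0 exactly, which propagates to exactly zero differences
  everywhere.
* A counterfactual shift larger than the reference mean collapses to a point
  mass at zero.
* Negative arm mortality (inconsistent inputs) raises rather than clamps.

## Problem sizes

The full analysis — 30 cohorts to age 100, both arms, 2000 Monte Carlo
iterations — takes about two minutes on one CPU; the deterministic pipeline
runs in ~60 ms. The test suite uses the same cohort structure with smaller
iteration counts (≤ 400) and finishes in well under five minutes.

## Known limitations

* Case fatality from m/p is a steady-state identity, not a DisMod fit.
* Closed population: no births, ageing-in, migration, or secular trends in
  rates, intake or costs.
* The RR is for overall dietary replacement of trans fat, not a specific
  substitution; substitution toward saturated fat would attenuate effects.
* Indirect/productivity costs and equity stratification are out of scope.
* Government cost timing (one-off vs annual split) is an assumption exposed
  in the inputs, not an estimate.
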