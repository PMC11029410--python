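# tfacea — trans-fat elimination cost-effectiveness model for Nigeria

`tfacea` is a proportional multistate lifetable (Markov cohort) model of a
mandatory limit on industrial *trans*-fatty acids (iTFA) in the Nigerian food
supply. It estimates, for the adult population (ages 20+ in 30 sex × 5-year
cohorts followed to age 100), the ischaemic heart disease (IHD) events and
deaths averted, health-adjusted life years (HALYs) gained, healthcare and
policy implementation costs, and the resulting cost-effectiveness of the
policy, with probabilistic uncertainty. It is written for health economists
and epidemiological modellers who want a tested, reusable implementation of
this class of dietary-policy simulation.

## Model core

1. **Exposure → incidence.** The relative risk of incident IHD is log-linear
   in trans-fat intake x (%E): RR(x) = RR₂^((x − TMREL)⁺ / 2), with RR₂ the
   risk per 2%E (1.23 by default) and TMREL = 0. The policy's effect is the
   potential impact fraction under a continuous distribution shift,

   PIF = 1 − E_cf[RR(X)] / E_ref[RR(X)],

   with expectations over lognormal intake distributions (moment-matched to
   the stratum's mean ± SD) by adaptive quadrature. Intervention incidence is
   i·(1 − PIF).

2. **Incidence → prevalence and mortality.** An illness–death submodel
   (well → IHD → IHD death; remission 0) advances annually by the exact
   solution of dS = −iS, dC = iS − fC, dD = fC, with case fatality
   f = IHD mortality / IHD prevalence.

3. **Lifetable.** Each cohort's total mortality swaps the input IHD mortality
   for the submodel's arm-specific rate, m = ACM − m_IHD,input + m_IHD,arm;
   survivorship decays as l·e^(−m), person-years are trapezoidal, and each
   person-year is discounted for prevalent disability from IHD and other
   causes to give HALYs.

4. **Costs and decision metrics.** IHD healthcare costs (incident + prevalent
   care), non-IHD healthcare costs in all years lived (including added years
   of life), government implementation and industry reformulation costs; all
   in 2019 USD, discounted at 3%, with Naira reported at ₦358/USD. Net cost =
   Δ healthcare + policy costs; ICER = net cost / HALYs gained against a
   $374/HALY threshold; ROI = healthcare savings per USD of government spend.
   Monte Carlo simulation (n = 2000) yields means, 95% uncertainty intervals,
   and probabilities of being cost-saving / cost-effective.

A synthetic-data generator produces internally consistent GBD-style inputs
(steady-state prevalence implied by incidence and case fatality) so the whole
pipeline is testable end to end.

## Worked example

```bash
python analysis/01_generate_inputs.py   # writes data/synthetic/*.csv
python analysis/02_central_run.py       # deterministic primary scenario
```

prints (seed 1):

```
horizon     events averted  deaths averted  HALYs gained  net cost (M$)  ICER ($/HALY)    ROI
5y                  16,759           2,701         6,160            6.7          1,090    7.5
10y                 30,503           7,676        24,002           -1.8            -76    8.8
lifetime           157,831          73,276       284,446          -43.9           -155    9.2
```

Reading the 10-year row: eliminating iTFA intake averts ~30,500 IHD events
and ~7,700 IHD deaths, gains ~24,000 HALYs, and saves more in healthcare than
the policy costs (net −$1.8M, i.e. cost-saving, so the negative ICER is moot),
returning $8.8 in healthcare savings per government dollar. At 5 years the
up-front reformulation outlay still dominates; over the lifetime the policy
is firmly cost-saving. `analysis/03_monte_carlo.py` adds 95% uncertainty
intervals and `analysis/04_sensitivity.py` runs the discount-rate, intake,
cost and partial-compliance threshold variants; `analysis/05_figures.py`
renders the sex-specific effect and sensitivity-plane figures from the saved
tables. The same functionality is exposed by the `tfacea` CLI
(`synth`, `run`, `sensitivity`, `report`).

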