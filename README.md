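# fpcea

Decision-analytic cost-effectiveness pipeline for **mobile phone–based
postabortion family-planning support** versus standard care, built for
health economists and family-planning program analysts who need a tested,
reproducible implementation of a trial-based evaluation: from per-1000-client
contraceptive service rates and unit costs to societal, provider and user
costs; health effects; incremental cost-effectiveness ratios (ICERs);
deterministic and probabilistic sensitivity analysis; and cost-effectiveness
acceptability curves (CEACs).

The setting is a two-arm trial in Cambodia: women receiving safe abortion
care were randomized to standard postabortion family-planning care, or to
standard care plus automated voice messages with counsellor phone support.
The intervention shifted the method mix toward long-acting reversible
contraception (implants, IUDs), at a higher delivery cost.

## Model

For each arm, annual services per 1000 clients (pill cycles, injectable
doses, implant/IUD insertions, repeat abortions) drive both costs and
effects.

**Effects.** Services convert to couple-years of protection with standard
factors (15 cycles/CYP, 4 doses/CYP, 3.2 CYP/implant, 4.6 CYP/IUD; 4-year
implant and 10-year IUD lifespans). Unintended pregnancies averted follow a
two-class conversion calibrated to the trial's published arm totals,

&nbsp;&nbsp;&nbsp;&nbsp;ΔPreg = r_s·CYP_short + r_l·CYP_long,

with abortions averted = 0.57·ΔPreg (share of unintended pregnancies ending
in abortion in Asia) and DALYs averted proportional to pregnancies averted.

**Costs** (US$, constant 2011 PPP). Provider gross cost = commodities +
clinical personnel time (with a 20% overhead loading) + intervention
delivery (airtime, equipment, counsellor time). User costs = fees +
motorbike transport (one-third distance reduction for non-study clinics) +
time valued at the gross daily income. Fees are a transfer, so

&nbsp;&nbsp;&nbsp;&nbsp;societal = provider net + user total = provider gross + transport + indirect,

which is invariant to user-fee scenarios.

**Decision metrics.** ICER = ΔC/ΔE per effect measure; net monetary benefit
NMB(λ) = λ·ΔE − ΔC; the CEAC is the fraction of Monte Carlo draws with
NMB(λ) > 0. Every uncertain parameter carries a 95% interval read as the
2.5th/97.5th percentile of its lognormal/gamma/beta distribution
(quantile-matched to 1e-8), sampled independently in a 1000-iteration PSA.

A synthetic trial-cohort generator (500 participants/arm, 66% retention,
monthly method states) stands in for the individual-level data; its
aggregation reproduces the published service rates.

## Worked example

```
$ fpcea base --out out/
== Costs (US$ per 1000 clients) ==
          intervention  standard_care  incremental
provider      4,079.74      -1,625.20     5,704.94
user         15,906.83      13,451.28     2,455.55
total        19,986.57      11,826.08     8,160.49

== Effects (per 1000 clients) ==
                              intervention  standard_care  incremental
Couple-years of protection        1,349.90         831.58       518.32
Pregnancies averted                 441.00         260.00       181.00
Abortions averted                   251.37         148.20       103.17
...
DALYs averted                       241.83         142.57        99.25

== ICERs (societal perspective) ==
                         effect  icer_usd_per_unit   category
0    Couple-years of protection              15.74       icer
...
5                 DALYs averted              82.22       icer
```

Phone support costs an extra US$8,160 per 1000 clients from a societal
perspective and gains 518 CYPs and 99 DALYs averted — US$15.74 per CYP and
US$82.22 per DALY averted, inside the empirical Cambodian threshold range
of US$58–176 per DALY. The negative standard-care provider cost means fee
income exceeds delivery cost in that arm. Other subcommands: `scenario`
(user-fee scenarios and provider-perspective ICERs), `tornado` (one-way
sensitivity), `psa`, `ceac`, `simulate` (synthetic cohort), and `full`
(everything plus a reproducibility manifest); see `fpcea --help`.

Python API: `DecisionModel().base_case()`, `run_psa`, `ceac`, `tornado`,
`generate_cohort` / `aggregate_services`.

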