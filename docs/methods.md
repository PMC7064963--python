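# Methods

## Scope and structure

`fpcea` models one year of postabortion family-planning service delivery
to a cohort of 1000 clients per arm (intervention: phone-based support
added to standard care; control: standard care), with effects accrued over
the service lifespan of each contraceptive method. Costs are not
discounted (they fall within one year); effects are undiscounted sums.
The pipeline is: parameter registry → per-arm service mixes → cost model
and effects chain → incremental analysis → sensitivity analysis.

## Parameters and distributions

Every uncertain parameter is a `(base, lo, hi, family)` record; `(lo, hi)`
is both the deterministic one-way range and the 95% interval of the
probability distribution used in the PSA. Families follow standard
practice for cost-effectiveness models: lognormal for trial-derived
service counts, gamma for unit costs (non-negative, right-skewed), beta
for the repeat-abortion count re-expressed as a proportion of the
1000-client cohort. Trial-derived rates and the home–clinic distance carry
their trial confidence intervals; income parameters use ±10%; all other
unit costs use ±50%.

Distributions are **quantile-matched**: shape parameters are solved so the
2.5th/97.5th percentiles equal `(lo, hi)` exactly (closed form for the
lognormal; scale-free shape bracketing for the gamma; a nested root solve
for the beta; verified to 1e-8 relative). The base value is used only as
the deterministic point estimate. A consequence worth knowing: for the
±50% gamma ranges the implied mean and median sit 5–10% *below* the base
value (e.g. the implant commodity cost calibrated to (4, 12) has mean
≈7.5 against a base of 8), so PSA summaries center slightly below the
deterministic base case. This is inherent to calibrating skewed
distributions to symmetric ranges, and it shifts the simulated median ICER
a few dollars below the deterministic ICER (see Limitations).

Sampling uses one `numpy` Generator stream in fixed declaration order, so
all Monte Carlo output is bit-reproducible under a seed. Parameters are
sampled independently (no correlation information exists); the two arms'
service counts are sampled independently as well, which is a conservative
assumption for incremental effects.

## Cost model

Provider gross cost per arm = commodity costs for all services (pharmacy
resupply is costed at clinic commodity prices) + clinical personnel
minutes × the midwife hourly wage × 1.2 (20% overhead loading on all
personnel) + intervention delivery in the intervention arm only
(per-participant airtime for voice messages and calls, computer and phone
shares — US$4.49 per participant at base — plus counsellor time, also
overhead-loaded).

User costs = direct fees (clinic or pharmacy prices by resupply split) +
transport (round-trip distance × motorbike price per km; visits to a
non-study clinic save one third of the distance) + time (clinical plus
travel minutes valued at the gross daily income over an 8-hour day,
attributed to all attendees regardless of employment) + a fixed household
indirect cost per repeat abortion. Dedicated trips are generated by the
separate-visit share of resupply and insertion services, by removals and
follow-up checks (1.2 per insertion), and by every repeat abortion.

All user fees are treated as income to the provider sector, giving the
transfer identity `societal = provider gross + transport + indirect`; a
fee scenario scales fees and fee income together, leaving the societal
total invariant.

**Calibration.** Per-service clinical minutes, the clinic/pharmacy split,
the medical/surgical repeat-abortion split, removals and follow-up visits
per insertion, the separate-visit share and counsellor minutes are not
identifiable from published unit costs. Plausible defaults were
back-solved once against the published arm totals
(`scripts/derive_assumptions.py`): the raw mechanistic model then matches
those totals within 5% (provider net +2.2%/−3.1%, user totals within
0.7%). Small additive per-arm residuals (fees, provider gross, non-fee
user cost) anchor the base case to the published totals exactly and are
held fixed through all sensitivity analyses, so sampled-parameter variance
remains mechanistic. Disable with `DecisionModel(calibrated=False)`.

## Effects chain

CYP factors are the standard per-method conversions (15 pill cycles, 4
injectable doses per CYP; 3.2 and 4.6 CYPs per implant and IUD insertion,
consistent with 4- and 10-year lifespans); they reproduce both arms'
published CYPs to ≤0.15%. Abortion services contribute no effects.

Pregnancies averted use two rates — per short-acting CYP (r_s ≈ 0.254) and
per long-acting CYP (r_l ≈ 0.346) — solved exactly from the two arms'
published pregnancies averted via a 2×2 linear system. A single pooled
rate cannot reproduce both arms (441/1350.6 ≠ 260/832.6); the class split
is a deliberate surrogate for lifespan-discounted fertility in the
original effects tool, whose internals are unpublished. DALYs and under-5
deaths averted per pregnancy averted are pooled two-arm ratios
(d_p ≈ 0.548, u_p ≈ 0.0071); abortions averted are 0.57 of pregnancies
averted; maternal deaths averted are identically zero (none were estimated
in either arm, so no maternal ICER exists).

Against the published per-arm DALY figures (which round intermediate
values) the pooled-ratio chain is within 0.2%, and the incremental DALY
total is 99.25 vs the printed 98.8; the deterministic societal ICER is
US$82.22/DALY vs the printed US$82.57 (0.4%). The published under-5 ICER
(7659.96) implies an unrounded incremental under-5 value (≈1.07) that
cannot be recovered from the published per-arm values (our pooled-ratio
chain gives ≈1.29); the under-5 ICER is reported but should be read with
that caveat.

## Incremental analysis

ICERs are computed from unrounded internals and reported per measure under
societal, provider or user perspective. Ratios are only formed in the
north-east quadrant (ΔC ≥ 0, ΔE > 0); cheaper-and-more-effective draws are
flagged `dominant`, zero incremental effect `undefined`. NMB(λ) = λ·ΔE − ΔC
is the decision rule everywhere, including PSA iterations with negative
incremental effects (no draw is discarded).

## Sensitivity and scenario analysis

*Tornado:* each parameter in turn is set to `lo` then `hi` (identical to
the distribution's 95% bounds by construction), all others at base, and
the full pipeline re-run; bars are sorted by ICER swing. The overhead
proportion participates with a 0.10–0.30 range. Because fees cancel
societally, fee parameters produce zero-width bars on the societal ICER.

*PSA:* 1000 iterations by default; per iteration every registry parameter
is redrawn and service mixes, costs and effects recomputed. Calibration
residuals and effects-chain coefficients are **not** resampled (the
surrogate's internal uncertainty is out of scope). A CEAC is evaluated on
a US$0–300 grid in steps of 1, and the cost-effectiveness plane is
exported with threshold rays at US$58 and US$176 per DALY averted (the
empirical Cambodian range, 12–35% of GDP per capita).

*Fee scenarios:* user fees at 100%/50%/0% shift cost between users and the
provider without changing the societal total; provider-perspective ICERs
rise monotonically as fees fall (57.48 → 67.36 → 77.25 US$/DALY computed;
57.72 → 67.65 → 77.58 published).

## Synthetic cohort generator

The generator emulates the *structure* of the trial data — 500
participants per arm, 66% retained, one method episode starting in month
1, short-acting durations of `1 + Binomial(11, q)` months, long-acting
methods persisting to month 12, optional switching on discontinuation,
annual repeat-abortion events — with parameters solved so expected
aggregate rates equal the published per-1000 rates (`calibrate_cohort_config`).
Initiation uses proportional largest-remainder allocation rather than iid
draws: the published rate intervals are narrower than iid multinomial
noise at n≈330, so an iid generator could not have produced them, and the
low-dispersion allocation reproduces the reported precision. Aggregation
counts one pill cycle per use-month, one injectable dose per started
3-month block, one insertion per long-acting episode start, scaled per
1000 *retained* participants.

What passing cohort tests show: the plumbing from person-month records to
service rates, and parameter recovery within the published intervals in
≥90% of seeds. What they do not show: real behavioral dynamics — seasonal
initiation, postpartum/postabortion timing effects, correlated dropout, or
any mechanism of the phone intervention (arm differences enter only
through the calibrated rates).

## Numerical choices and degenerate inputs

Root solves use Brent's method with quantile-space verification at 1e-8;
degenerate intervals (`lo == hi`) must be declared `fixed`; beta bounds
must lie strictly inside the unit interval after rescaling; arms with
identical short/long CYP shares raise a calibration error (singular
system); aggregation of a cohort with no retained participants is an
error, as is a non-positive iteration count or a fee fraction outside
[0, 1].

## Known limitations

- The micro-costing assumptions are back-solved, not measured; the
  calibration offsets absorb what they miss. Conclusions about cost
  *levels* inherit the published totals; only the sensitivity structure is
  mechanistic.
- Quantile-matched skewed distributions center below base values, so the
  simulated 50% CEAC crossing (≈76–78 US$/DALY) sits below the
  deterministic ICER (82.2) and the published simulated crossing (≈83);
  probabilities at the threshold bounds are correspondingly shifted
  (≈13% at US$58, ≈98% at US$176, vs 11% and 95% published).
- No demand response to fees (price elasticity assumed zero), no currency
  conversion, no correlation between parameters, no uncertainty in the
  effects-conversion coefficients.
- Under-5 mortality estimates are the least reliable link of the effects
  chain and are carried for completeness only.
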