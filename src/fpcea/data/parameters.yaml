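# Default model parameters: two-arm postabortion family-planning service
# provision rates (annual counts per 1000 clients) and unit costs (constant
# 2011 PPP-adjusted US$), each with its deterministic range and the
# probability family used for probabilistic sensitivity analysis.  The
# deterministic range is read as the 95% interval of that distribution.
#
# Range conventions: trial-derived rates and the home-clinic distance carry
# their trial 95% CIs; income figures use +/-10%; all other unit costs use
# +/-50% around the base estimate.
meta:
  seed: 2020
  psa_iterations: 1000
  threshold_range: [58.0, 176.0]
  overhead_proportion: 0.20        # added to personnel costs
  overhead_range: [0.10, 0.30]     # deterministic range for one-way DSA
  distance_reduction_other_clinic: 0.33333333333333331  # fraction of distance saved at a non-study clinic
parameters:
  # ---- annual services per 1000 clients, intervention arm ----
  - {name: svc.intervention.ocp,             base: 2172, lo: 2013,   hi: 2330,   family: lognormal, units: "cycles/1000/yr"}
  - {name: svc.intervention.injectable,      base: 558,  lo: 512,    hi: 604,    family: lognormal, units: "doses/1000/yr"}
  - {name: svc.intervention.implant,         base: 172,  lo: 123,    hi: 220,    family: lognormal, units: "insertions/1000/yr"}
  - {name: svc.intervention.iud,             base: 112,  lo: 72,     hi: 153,    family: lognormal, units: "insertions/1000/yr"}
  - {name: svc.intervention.repeat_abortion, base: 47,   lo: 21,     hi: 91,     family: beta,      units: "events/1000/yr", scale: 1000}
  # ---- annual services per 1000 clients, control (standard care) arm ----
  - {name: svc.control.ocp,                  base: 3308, lo: 3112,   hi: 3499,   family: lognormal, units: "cycles/1000/yr"}
  - {name: svc.control.injectable,           base: 325,  lo: 291,    hi: 358,    family: lognormal, units: "doses/1000/yr"}
  - {name: svc.control.implant,              base: 75,   lo: 42,     hi: 109,    family: lognormal, units: "insertions/1000/yr"}
  - {name: svc.control.iud,                  base: 63,   lo: 32,     hi: 93,     family: lognormal, units: "insertions/1000/yr"}
  - {name: svc.control.repeat_abortion,      base: 69,   lo: 35,     hi: 120,    family: beta,      units: "events/1000/yr", scale: 1000}
  # ---- intervention delivery costs, US$ per participant ----
  - {name: cost.delivery.voice_airtime,      base: 0.79, lo: 0.39,   hi: 1.18,   family: gamma, units: "USD/participant"}
  - {name: cost.delivery.call_airtime,       base: 2.16, lo: 1.08,   hi: 3.25,   family: gamma, units: "USD/participant"}
  - {name: cost.delivery.computer,           base: 1.34, lo: 0.67,   hi: 2.01,   family: gamma, units: "USD/participant"}
  - {name: cost.delivery.phone,              base: 0.20, lo: 0.10,   hi: 0.30,   family: gamma, units: "USD/participant"}
  # ---- provider commodity costs, US$ per service ----
  - {name: cost.commodity.ocp_cycle,         base: 0.29, lo: 0.15,   hi: 0.44,   family: gamma, units: "USD/cycle"}
  - {name: cost.commodity.iud_device,        base: 0.40, lo: 0.20,   hi: 0.60,   family: gamma, units: "USD/device"}
  - {name: cost.commodity.medical_abortion,  base: 0.70, lo: 0.35,   hi: 1.05,   family: gamma, units: "USD/event"}
  - {name: cost.commodity.surgical_abortion, base: 5.00, lo: 2.50,   hi: 7.50,   family: gamma, units: "USD/event"}
  - {name: cost.commodity.injectable_dose,   base: 0.50, lo: 0.25,   hi: 0.75,   family: gamma, units: "USD/dose"}
  - {name: cost.commodity.implant_device,    base: 8.00, lo: 4.00,   hi: 12.00,  family: gamma, units: "USD/device"}
  - {name: cost.commodity.larc_removal,      base: 3.00, lo: 1.50,   hi: 4.50,   family: gamma, units: "USD/removal"}
  # ---- personnel, US$ per hour ----
  - {name: cost.personnel.midwife_hourly,    base: 2.36, lo: 1.18,   hi: 3.54,   family: gamma, units: "USD/h"}
  - {name: cost.personnel.counsellor_hourly, base: 2.52, lo: 1.26,   hi: 3.78,   family: gamma, units: "USD/h"}
  # ---- user fees, US$ per service ----
  - {name: fee.iud_insertion,                base: 5.00, lo: 2.50,   hi: 7.50,   family: gamma, units: "USD"}
  - {name: fee.implant_insertion,            base: 25.0, lo: 12.50,  hi: 37.50,  family: gamma, units: "USD"}
  - {name: fee.injectable_clinic,            base: 1.00, lo: 0.50,   hi: 1.50,   family: gamma, units: "USD"}
  - {name: fee.injectable_pharmacy,          base: 0.73, lo: 0.37,   hi: 1.10,   family: gamma, units: "USD"}
  - {name: fee.ocp_clinic,                   base: 0.40, lo: 0.20,   hi: 0.60,   family: gamma, units: "USD"}
  - {name: fee.ocp_pharmacy,                 base: 0.37, lo: 0.19,   hi: 0.56,   family: gamma, units: "USD"}
  - {name: fee.iud_removal,                  base: 2.00, lo: 1.00,   hi: 3.00,   family: gamma, units: "USD"}
  - {name: fee.implant_removal,              base: 3.75, lo: 1.80,   hi: 5.63,   family: gamma, units: "USD"}
  - {name: fee.abortion_surgical,            base: 25.0, lo: 12.50,  hi: 37.50,  family: gamma, units: "USD"}
  - {name: fee.abortion_medical,             base: 20.0, lo: 10.00,  hi: 30.00,  family: gamma, units: "USD"}
  # ---- user phone, transport and time costs ----
  - {name: user.hotline_airtime_per_min,     base: 0.07, lo: 0.04,   hi: 0.11,   family: gamma, units: "USD/min"}
  - {name: user.motorbike_per_km,            base: 0.22, lo: 0.11,   hi: 0.33,   family: gamma, units: "USD/km"}
  - {name: user.roundtrip_km,                base: 38.2, lo: 30.1,   hi: 46.3,   family: gamma, units: "km"}
  - {name: user.gni_per_capita,              base: 2534, lo: 2280.6, hi: 2787.4, family: gamma, units: "USD/yr"}
  - {name: user.daily_income,                base: 6.90, lo: 6.20,   hi: 7.60,   family: gamma, units: "USD/day"}
  - {name: user.abortion_household_indirect, base: 5.07, lo: 2.54,   hi: 7.61,   family: gamma, units: "USD/event"}
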