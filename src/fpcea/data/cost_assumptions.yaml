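# Micro-costing assumptions not identifiable from published unit costs alone:
# per-service clinical minutes, clinic/pharmacy resupply split, the
# medical/surgical split of repeat abortions, removals and follow-up visits
# per insertion, the share of services delivered at a dedicated visit, and
# counsellor time to deliver the phone-support intervention.  Defaults were
# back-solved once (scripts/derive_assumptions.py) so that the mechanistic
# cost model reproduces the anchored arm totals within 5%; they are plausible
# service-delivery values, not measured quantities.
clinic_share: 0.40                # share of pill cycles / injectable doses obtained at a clinic (rest: pharmacy)
abortion_medical_share: 0.80      # share of repeat abortions managed medically (rest: surgical)
removals_per_insertion: 0.10      # LARC removals occurring within the costing year, per insertion
separate_visit_proportion: 0.42   # share of clinic contraceptive services needing a dedicated trip
other_clinic_share: 0.50          # share of contraceptive clinic visits at a non-study clinic
larc_followup_visits: 1.20        # follow-up check visits per implant/IUD insertion
minutes:                          # clinical minutes per service unit
  ocp_cycle: 10.0
  injectable_dose: 25.0
  implant_insertion: 40.0
  iud_insertion: 40.0
  larc_removal: 30.0
  repeat_abortion: 180.0
  larc_followup: 15.0
counsellor_minutes_per_participant: 55.0  # intervention training + phone support
hotline_minutes_per_participant: 0.0      # user-paid airtime; default: none beyond the intervention
travel_speed_kmh: 30.0
workday_hours: 8.0
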