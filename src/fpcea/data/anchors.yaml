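# Arm-level base-case totals from the trial's published economic evaluation,
# used as calibration anchors: the cost model's unreported micro-costing
# assumptions are back-solved against these, the effects chain's
# pregnancies-per-CYP coefficients are solved from them exactly, and small
# additive residuals anchor the base case to these totals.
# Units: US$ (costs) or events (effects), per 1000 clients per year.
costs:
  intervention:
    provider_net: 4079.74
    user_total: 15906.83
    user_total_no_fee: 8772.00     # user total with fees removed = transport + indirect
  control:
    provider_net: -1625.20
    user_total: 13451.28
    user_total_no_fee: 8278.66
effects:
  cyps: {intervention: 1350.6, control: 832.6}
  pregnancies_averted: {intervention: 441.0, control: 260.0}
  abortions_averted: {intervention: 251.0, control: 148.0}
  under5_deaths_averted: {intervention: 3.0, control: 2.0}
  maternal_deaths_averted: {intervention: 0.0, control: 0.0}
  dalys_averted: {intervention: 241.6, control: 142.8}
abortion_fraction: 0.57            # share of unintended pregnancies ending in abortion (Asia)
unintended_pregnancy_fraction: 0.31  # documentation constant; not used in computation
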