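# Healthy adult lung: regional RV/TLC profile and whole-lung summary.
scenario: healthy
sweep:
  parameters: [n, k, vmin_vmax, p_tm]
  span: 0.25
  points: 3
  mode: one_at_a_time
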