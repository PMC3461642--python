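# Severe homogeneous emphysema, calibrated to whole-lung RV/TLC = 0.68 and
# RV = 5.8 L, then paired upper- vs lower-lobe volume reduction: eliminate
# 22e6 alveoli, recoil at full inflation 12.5 -> 14 cm H2O, airway closing
# pressure 1 -> 0.5 cm H2O, apex-to-base height 35 -> 33 cm.
scenario:
  name: emphysema
  height_cm: 35
  n_total: 150.0e6
  v_max_ul: 40
  v_min_ul: 20
  k_per_cmh2o: 0.3
  p_tlc_apex_cmh2o: 12.5
  p_tm_cmh2o: 1.0
calibration:
  rv_tlc: 0.68
  rv_liters: 5.8
treatment:
  ult:
    region: upper
    n_removed: 22.0e6
    p_tlc_apex_post_cmh2o: 14
    p_tm_post_cmh2o: 0.5
    height_post_cm: 33
  llt:
    region: lower
    n_removed: 22.0e6
    p_tlc_apex_post_cmh2o: 14
    p_tm_post_cmh2o: 0.5
    height_post_cm: 33
sweep:
  parameters: [n, k, vmin_vmax, p_tm]
  span: 0.25
  points: 3
  mode: joint
  dominance: true
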