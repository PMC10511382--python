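# Example cohort-generator overrides for `tva-arousal simulate cohort --config ...`
# Omitted entries keep the study-calibrated defaults.
n_per_group: 40
indirect_only_mediation: false
rho:
  # pair keys are "A:B"; values are target Spearman rank correlations
  "PUI:C": -0.508
  "fatigue_mental:C": -0.535
marginals:
  patient:
    C: [26.23, 12.26]
    fatigue_mental: [18.65, 4.17]
  control:
    C: [33.72, 11.92]
    fatigue_mental: [8.97, 2.90]
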