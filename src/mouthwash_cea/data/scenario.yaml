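# Default run configuration for the mouthwash cost-effectiveness model.
rrr: 0.3
covid:
  mode: absolute_pp          # absolute_pp | calibrated
  pneumonia_increment: 0.018 # percentage-point rise in pneumonia risk (pandemic scenario)
  calibrated_increment: 0.0028
  per_patient_cost: 254.0    # 2020 international $ added to every patient
wtp_grid:
  start: 0.0
  stop: 30000.0
  step: 250.0
psa:
  n_iterations: 10000
  cost_cv: 0.2               # coefficient of variation for gamma cost draws
  mv_effective_sample_size: 39
dsa:
  rrr_values: [0.2, 0.1, 0.05, 0.01]
  rrr_context: 0.01
display_zar_per_intl_usd: 17.35
seed: 20210812
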