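# Demo simulation scenario: a small balanced synthetic cohort around the
# synthetic demo reference, with a prototype-driven outcome resembling a
# 10-year CVD risk percentage and a little eligibility contamination.
reference: demo
n_per_cluster:
  male: {SIDD: 25, SIRD: 25, MOD: 25, MARD: 25}
  female: {SIDD: 25, SIRD: 25, MOD: 25, MARD: 25}
dispersion: 0.6
outcome_effects: {SIDD: 14.0, SIRD: 12.0, MOD: 7.0, MARD: 9.0}
outcome_noise_sd: 1.5
proximity_coupling: -3.0
contamination_rate: 0.05
seed: 20260101
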