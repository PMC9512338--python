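# Demo pipeline config: a small SS-IMRT-like synthetic cohort.
seed: 1
technique: SS-IMRT
source: simulate
simulation:
  n_patients: 4
  fractions_per_patient: 6        # scalar broadcasts to every patient
  duration_s: 120.0
  sample_rate_hz: 4.0
  overall_mean_mm: [0.05, -0.10, 0.03]
  sigma_pt_mm: [0.00, 0.10, 0.00]
  sigma_fr_mm: [0.41, 0.80, 0.31]
  sigma_intra_mm: [0.34, 0.69, 0.23]
  drift_rate_mm_per_min: [0.0, 0.0, 0.0]
  gas_event_rate_per_fraction: 0.05
  gas_event_amplitude_mm: 9.7
  gas_event_duration_s: 10.0
summaries:
  bin_s: 1.0
estimate:
  ci_level: 0.95
  thin: 1
margins:
  n_fractions: max
  coefficients: [2.5, 0.7]
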