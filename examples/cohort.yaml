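# Example simulated-study configuration.
# Default cohort: 18 subjects aged 7-13, four 100-pulse blocks per day,
# 15 subjects attending two days (132 blocks). Trimmed here to a small,
# fast cohort; delete the overrides to run at full scale.

synthetic:
  n_trials: 60
  epoch_span: [-560, 420]   # full-scale default: [-1000, 1500]
  noise_sd: 6.0
  p_movement_trial: 0.03

cohort:
  n_subjects: 6
  schedule: [[2, 2], [2, 2], [2, 2], [2, 0], [2, 0], [2, 0]]
  age_snr_slope: 0.25       # older children -> larger evoked amplitude
  supra_amp_factor: 1.3     # suprathreshold stimulation -> larger amplitude

preprocess:
  mode: subset_only         # per_subset re-preprocesses every candidate

analysis:
  ccc_threshold: 0.8
  start_pulses: 10
  step_pulses: 5
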