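# Reference synthetic cohort: 5 subjects on a 5-step concentration ladder,
# >= 60 min per step, two spectral states (~6 Hz and ~2 Hz over 1/f),
# 10-minute mean dwells at the deepest level, dwells shortening and one
# state dropping out as the ladder descends.
#
# Schema: see README ("Configuration").
cohort:
  n_subjects: 5
  sampling_rate_hz: 1000.0
  window_duration_s: 10.0
  mean_dwell_windows: 60.0     # 10 min over 10-s windows
  noise_sd: 0.1
  seed: 0
  states:
    - state_id: 0
      peaks:
        - {center_hz: 6.0, bandwidth_hz: 1.0, relative_power: 1.0}
      background_exponent: 1.0
      background_power: 1.0
    - state_id: 1
      peaks:
        - {center_hz: 2.0, bandwidth_hz: 0.6, relative_power: 1.0}
      background_exponent: 1.0
      background_power: 1.0
  conditions:
    - {label: iso_1.75, dwell_multiplier: 1.0,  duration_s: 3600.0}
    - {label: iso_1.50, dwell_multiplier: 0.8,  duration_s: 3600.0}
    - {label: iso_1.25, dwell_multiplier: 0.67, duration_s: 3600.0}
    - {label: iso_1.00, dwell_multiplier: 0.57, duration_s: 3600.0}
    - {label: iso_0.75, dwell_multiplier: 0.5,  duration_s: 3600.0, available_states: [1]}
analysis:
  window_duration_s: 10.0
  band_hz: [0.5, 120.0]
  n_components: 3
  k: 8
  n_restarts: 20
  floor: 1.0e-3
  seed: 0
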