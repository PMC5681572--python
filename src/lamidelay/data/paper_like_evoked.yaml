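active_duration_ms: 25.0
active_gain: 40.0
cascade_lag_ms: 0.4
cascade_mode: layer_step
cascade_origin_layer: 6
evoked_onset_ms: 6.5
evoked_window_ms:
- 5.0
- 60.0
jitter_sd_ms: 0.3
n_animals: 6
n_epochs: 200
noise_sd: 1.0
participation:
  1: 0.4
  2: 0.5
  3: 0.6
  4: 0.9
  5: 0.95
  6: 0.85
rates_hz:
  contra:
  - 2.0
  - 4.0
  - 6.0
  - 10.0
  - 14.0
  - 8.0
  ipsi:
  - 2.0
  - 4.0
  - 6.0
  - 10.0
  - 14.0
  - 8.0
regime: evoked
relay_delay_ms: 9.0
relay_superficial_increment_ms: 1.6
sampling_rate_hz: 6250.0
seed: 0
spike_amplitude_sd: 10.0
spont_duration_ms: 7000.0
upstate_rate_hz: 0.4
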