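# Control animal, dexmedetomidine experiment: 6-h window from ZT18 with an
# i.p. injection at ZT19 forcing an NREM-like state (REM suppressed), evoked
# delta power peaking at 11 min at twice natural NREM delta, hypothermia to
# 25 C over ~2 h with slow rewarming, and a post-sedation delta rebound.
# Run with events: [] for the matched ZT18-24 natural baseline.
epoch_s: 5.0
fs_hz: 200.0
zt_start: 18.0
days: 0.25
seed: 0
state_params:
  WAKE:
    mean_episode_duration_s: {lights_on: 180.0, lights_off: 600.0}
    transition_weights: {NREM: 1.0}
    eeg_band_weights: {delta: 0.15, theta: 0.35, broadband: 0.50}
    eeg_amplitude: 40.0
    emg_rms_level: 30.0
  NREM:
    mean_episode_duration_s: {lights_on: 180.0, lights_off: 150.0}
    transition_weights: {WAKE: 0.75, REM: 0.25}
    eeg_band_weights: {delta: 0.55, theta: 0.10, broadband: 0.35}
    eeg_amplitude: 60.0
    emg_rms_level: 6.0
  REM:
    mean_episode_duration_s: {lights_on: 60.0, lights_off: 60.0}
    transition_weights: {WAKE: 0.5, NREM: 0.5}
    eeg_band_weights: {delta: 0.08, theta: 0.55, broadband: 0.37}
    eeg_amplitude: 45.0
    emg_rms_level: 4.0
rebound_params: {}
events:
  - kind: drug
    zt_onset: 19.0
    duration_h: 5.0
    forced_state: NREM
    rem_suppressed: true
temperature_params:
  mean_c: {lights_on: 35.0, lights_off: 36.0}
  diurnal_amplitude_c: 0.3
  noise_sd_c: 0.15
  zt24_spike_c: 0.0
  drug_response:
    nadir_c: 25.0
    time_to_nadir_min: 120.0
    recovery_rate_c_per_h: 1.0
    delta_peak_min: 11.0
    delta_peak_ratio: 2.0
    delta_decay_min: 120.0
    sedation_min: 180.0
    rebound_delta_gain: 1.4
    rebound_decay_h: 2.0
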