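# Preoptic-galanin-lesion phenotype: fragmented sleep (more, shorter WAKE and
# NREM episodes, mainly in lights-off), blunted homeostatic rebound (~22%
# recovery), chronically raised core temperature (37 C mean) with a larger
# diurnal range and a transient spike at the dark->light (ZT24) transition.
epoch_s: 5.0
fs_hz: 200.0
zt_start: 0.0
days: 1.0
seed: 0
state_params:
  WAKE:
    mean_episode_duration_s: {lights_on: 150.0, lights_off: 240.0}
    transition_weights: {NREM: 1.0}
    eeg_band_weights: {delta: 0.15, theta: 0.35, broadband: 0.50}
    eeg_amplitude: 40.0
    emg_rms_level: 30.0
  NREM:
    mean_episode_duration_s: {lights_on: 150.0, lights_off: 90.0}
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
rebound_params:
  delta_gain_post_sd: 1.15
  decay_hours: 3.5
  recovery_fraction_target: 0.22
  recovery_horizon_h: 19.0
events: []
temperature_params:
  mean_c: {lights_on: 36.0, lights_off: 38.0}
  diurnal_amplitude_c: 0.5
  noise_sd_c: 0.15
  zt24_spike_c: 1.0
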