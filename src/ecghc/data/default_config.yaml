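# Default configuration for ecghc.
#
# `analysis` mirrors ecghc.config.RunConfig; `kors_matrix` is the published
# regression matrix (rows X, Y, Z over leads I, II, V1..V6), exposed here
# for audit; `generator` holds the calibrated synthetic-cohort parameters
# (voltages in microvolts, durations in seconds, rates in Hz or bpm).

analysis:
  D: 4
  tau: 2
  window_ms: 512.0
  xcorr_threshold: 0.75
  rms_limit_uv: 20.0
  pre_q_ms: 20.0
  occlusion_window_s: 30.0
  recovery_window_s: 15.0
  line_freq: 60.0
  alpha: 0.05
  seed: 0

kors_matrix:
  leads: [I, II, V1, V2, V3, V4, V5, V6]
  X: [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54]
  Y: [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13]
  Z: [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31]

generator:
  fs: 1000.0
  heart_rate_bpm: 70.0
  rr_jitter: 0.02            # fractional beat-to-beat RR variability
  control_duration_s: 300.0
  occlusion_mean_s: 246.0    # 4 min 6 s
  occlusion_sd_s: 90.0
  occlusion_range_s: [120.0, 400.0]
  recovery_mean_s: 222.0     # 3.7 min
  recovery_sd_s: 60.0
  recovery_range_s: [60.0, 400.0]
  noise_rms_uv: 7.0          # broadband lead noise under the 20 uV gate
  wander_amplitude_uv: 120.0
  wander_freq_hz: 0.25
  line_amplitude_uv: 15.0
  line_freq_hz: 60.0
  st_amp_control_uv: 40.0    # resting ST-T dome amplitude
  morph:
    lad_occlusion:           # ST-T rises into a single smooth dome
      st_amp_max_uv: 380.0
    rca_occlusion:           # quiescent start, then flatter and noisier ST-T
      quiescent_fraction: 0.4
      t_scale_min: 0.45
      noise_rms_max_uv: 15.0
      st_jitter_max_uv: 50.0
    recovery:                # stochasticity grows during reperfusion
      lad_st_amp_start_uv: 200.0
      noise_rms_max_uv: 12.0
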