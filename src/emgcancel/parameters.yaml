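# Frozen model parameters.
#
# Values marked (printed) are the published model constants; the remainder
# were fixed once by the pilot tuning script (tools/tune_pool.py /
# tools/tune_emg.py) so that the pool's recruitment, discharge-rate, EMG
# median-frequency and force behaviour fall in the physiological ranges the
# model is meant to emulate.  Edit only via the tuning scripts.

pool:
  # drive values (offset, G2, noise gain) are currents in uA injected into
  # the soma; converted to nA for the integrator
  current_scale_nA: 1000.0
  v_rest_mV: 0.0            # (printed) membrane/leak equilibrium
  e_na_mV: 120.0            # (printed)
  e_k_mV: -10.0             # printed magnitude 10 mV; sign relative to rest
  c_m_uF_cm2: 1.0           # (printed)
  r_axial_ohm_cm: 70.0      # (printed)
  r_soma_kohm_cm2: [1.15, 0.65]    # (printed) low- -> high-threshold end
  r_dend_kohm_cm2: [14.4, 6.05]    # (printed)
  soma_diam_um: [77.5, 82.5]       # source-model geometry (not printed)
  dend_diam_um: [41.5, 62.5]       # source-model geometry (not printed)
  dend_len_mm: [5.5, 6.8]          # source-model geometry (not printed)
  g_na_mS_cm2: 30.0
  g_kf_mS_cm2: 4.0
  g_ks_mS_cm2: [30.0, 12.0]        # AHP strength, tuned
  # exponential-density skew of recruitment thresholds across the pool
  recruitment_skew: 2.0
  # pulse-based gating rate constants (1/ms)
  alpha_m: 22.0
  beta_m: 13.0
  alpha_h: 0.5
  beta_h: 4.0
  alpha_n: 1.5
  beta_n: 0.1
  alpha_q: 4.0
  beta_q: [0.09, 0.22]             # slow-K decay (AHP duration), tuned
  pulse_ms: 0.6
  v_thresh_mV: 8.05                # pulse trigger threshold, tuned
  spike_detect_mV: 60.0
  dead_time_ms: 5.0
  dt_ms: 0.05

input:
  fs_hz: 2048
  duration_s: 30.0
  n_sines: 30
  noise_cutoff_hz: 100.0
  noise_filter_order: 4
  # ISI coefficient-of-variation target for the independent-noise calibration
  isi_cov_target: [0.10, 0.30]

emg:
  # geometry/conductivity of the volume conductor lives on VolumeGeometry
  fs_hz: 2048
  conduction_velocity_m_s: 4.0     # not printed; standard value
  n_electrode_pairs: 15            # (printed)
  innervation_range: [6, 69]       # (printed) exponential across pool
  territory_radius_mm: {100: 7.0, 400: 14.0}   # (printed) selection disc
  territory_depth_mm: {100: 5.3, 400: 10.5}    # (printed) disc centre depth
  unit_territory_radius_mm: 2.0    # scatter of one unit's fibres, tuned
  depth_lambda_mm: 3.0             # amplitude decay length, tuned
  sfap_width_ms: [2.75, 0.25]       # w0 + k*depth_mm, temporal broadening, tuned
  library_depth_jitter_mm: 2.5     # electrode-site depth variation, tuned
  library_width_jitter: [0.80, 1.30]  # electrode-site tissue filtering, tuned
  innervation_rank_jitter: 0.0    # site-specific unit/innervation pairing
  template_ms: 25.0

force:
  twitch_peak_ratio: 100.0         # (printed) 100-fold range
  contraction_time_ms: [90.0, 30.0]  # (printed) slow low-threshold -> fast
  gain_rate_knee: 0.4              # Fuglevand nonlinearity knee (T/ISI)
  peak_rate_pps: [35.0, 25.0]      # MVC reference rates (onion-skin), tuned
  mvc_duration_s: 4.0
  mvc_settle_s: 2.0
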