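# Homogeneous-gelatin experiment: the default study conditions, written out
# in full.  Any subset of these keys can be passed as overrides to
# `fusmrt run --base homogeneous --config <file>`; values identical to the
# built-in defaults may be omitted.
name: homogeneous
phantom:
  kind: homogeneous
  shape: [128, 128, 96]
  spacing_mm: [0.7, 0.7, 1.0]
  z0_mm: 58.0            # first grid plane, measured from the transducer apex
  gel_z_mm: 60.0         # water/gel interface; gel extends upward from here
  shell: null
transducer:
  n_elements: 256
  frequency_hz: 1.0e6
  roc_mm: 130.0
  aperture_mm: null      # null -> calibrated to the 2 mm lateral focal FWHM
  target_lateral_fwhm_mm: 2.0
  layout_seed: 7
sonication:
  power_w: 40.0
  duration_s: 28.7
  efficiency: 0.34       # acoustic coupling efficiency (see docs/methods.md)
  focus_mm: [0.0, 0.0, 130.0]
acoustics:
  include_reflection: false
  aberration_correct: false
  spacing_check: raise
mr:
  b0_t: 3.0
  te_s: 0.011
  alpha_ppm_per_degc: -0.01
  truth_t_acq_s: 4.8
  sub_t_acq_s: 2.4
  n_truth_frames: 10
  R: 7
  etl: 7
  noise_sd: 0.0333       # ~1/30 of the gel baseline magnitude (focal SNR 30)
  baseline_seed: 11
  n_repeats: 3
recon:
  methods: [mpf]
  q_support_frac: 1.0e-6
  tcr: {lambda_t: null, n_iters: 40}
eval:
  zero_fill_mm: 0.5
  roi_z_halfwidth_mm: 22.5
lp_fit:
  power_w: 14.0
  duration_s: 28.7
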