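# Skull-shell experiment overrides (applied on top of the homogeneous
# defaults by `fusmrt run --base skull`): a PVC spherical-cap shell of
# 4-7 mm varying thickness concentric with the focus, higher power, and
# per-element phase aberration correction.
name: skull
phantom:
  kind: skull
  shell:
    center_mm: [0.0, 0.0, 130.0]
    inner_radius_mm: 42.0
    t_min_mm: 4.0
    t_max_mm: 7.0
    half_angle_deg: 50.0
sonication:
  power_w: 125.0
  duration_s: 23.9
acoustics:
  aberration_correct: true
mr:
  n_truth_frames: 9
lp_fit:
  power_w: 100.0
  duration_s: 14.3
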