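# Demo pipeline: simulate a small paired cohort and compare conditions.
seed: 7
out_dir: demo_out
alpha: 0.05
quantile_rule: haverage
simulate:
  n_male: 4
  n_female: 4
segmentation:
  d_mouth: 0.10
  d_bowl: 0.08
  hysteresis: 0.02
  min_dwell: 0.05
  smoothing_cutoff: 6
hand_metrics:
  amplitude_limit_mps: 0.020
  min_peak_interval_s: 0.150
  filter_cutoff_hz: 6
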