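# Example pupilprep configuration. Every key is optional except
# segmentation.max_missing_pct, which the pipeline requires explicitly.

io:
  timestamp_col: timestamp_s
  left_col: diameter_left_mm
  right_col: diameter_right_mm
  units: s              # or "ms"; internal unit is always seconds
  # validity_left_col: validity_left
  # validity_right_col: validity_right
  # invalid_values: [0, -1]

filter:
  range_min_mm: 1.5
  range_max_mm: 9.0
  speed_mad_multiplier: 16     # n in the median + n*MAD threshold; tune per dataset
  gap_edge_margin_ms: 50
  gap_min_duration_ms: 75
  deviation_mad_multiplier: 16
  deviation_passes: 2
  trendline_cutoff_hz: 4
  sparsity_split_gap_ms: 40
  sparsity_min_section_ms: 50

processing:
  target_rate_hz: 1000
  lowpass_cutoff_hz: 4
  max_interp_gap_ms: 250
  lowpass_order: 1             # per direction, applied forward-backward

segmentation:
  # max_missing_pct: 40        # REQUIRED: uncomment and choose for your study
  bin_ms: 100
  pairing:
    baseline: trial            # baseline label -> response label

output_dir: pupilprep_out
plots: true
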