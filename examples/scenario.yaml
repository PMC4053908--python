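# Demo pipeline configuration for `commute-exposure run --config examples/scenario.yaml`
scenario:
  domain_extent: [0, 0, 2000, 2000]
  street_spacing: 250.0
  grid_sizes: [25, 50, 100]
  background_level: 23.5
  road_increment: 30.0
  decay_length: 60.0
  side_street_share: 0.6
  n_subjects: 100
  mode_shares:
    walking: 0.27
    bicycle: 0.30
    motorized: 0.11
    public: 0.32
  noise_sd: 2.0
  n_weekday_days: 260
  seed: 1
n_perm: 999
outdir: pipeline_out
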