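seed: 7
outdir: polvel_smoke
genome:
  n_genes: 20
  length_min: 10000
  length_max: 60000
  intergenic_gap: 20000
  n_chroms: 2
kinetics:
  initiation_rate: 2.0
  velocity_kb_min: 2.0
conditions:
  - name: control
    velocity_factor: 1.0
    onset_time: 0.0
  - name: depleted
    velocity_factor: 0.5
    onset_time: 0.0
sampling:
  label_start: 60.0
  label_duration: 5.0
  replicates: 2
  ttseq_depth_per_kb: 2.0
  mnet_tags_per_pol: 10.0
  chip_reads_per_pol_kb: 2.0
  chip_background_per_kb: 2.0
  fragment_min: 150
  fragment_max: 300
  library_scales: [1.0, 1.2, 0.9, 1.1]
analysis:
  velocity_bin: 50
  chip_bin: 500
  rpk_threshold: 10.0
  bootstrap_iters: 10000
  pseudo_count: 1.0
  exclude_first: 1000
  n_body_bins: 100
  flank_bp: 2500
  flank_bins: 50
  heatmap_window_bp: 60000
  control: control
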