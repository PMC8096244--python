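# Demo run: four simulated octads of a hybrid msh2-null diploid, called and
# summarized.  `meiorec run --config examples/demo.yaml`
seed: 11
n_octads: 4
out_dir: meiorec_demo
sim:
  chrom_length: 200000
  mean_marker_spacing: 160
  events_per_chrom: 3.0
  p_co: 0.5
  tract_mean: 1300.0
  tract_shape: 2.0
  min_event_sep: 10000
  geno_error: 0.002
  missing_rate: 0.01
caller:
  min_depth: 5
  min_purity: 0.9
  merge_gap_markers: 0
  event_merge_bp: 5000
  flank_k: 5
  short_cutoff_bp: 300
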