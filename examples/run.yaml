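# Full orchestrated run on the synthetic drying study.
seed: 11
out_dir: hsidry_run
generator:
  n_levels: 13
  n_replicates: 8
  image_shape: [64, 96]
cars:
  n_runs: 60
  cv_folds: 10
preprocess:
  sg_window: 11
  sg_polyorder: 2
  apply_sg: true
  apply_snv: true
stages:
  image_features: true
  nmr: true
  maps: true
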