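# Demo configuration: a small synthetic study that runs end to end in a few
# minutes on one CPU. Any omitted key falls back to the package defaults
# (see myotomo.config.DEFAULT_CONFIG).
seed: 0

simulate:
  shape: [32, 80, 80]
  n_fibers: 16
  days: [1, 14]
  replicates: 3
  noise_sigma: 10.0

stats:
  metric: space_volume_vox
  variant: pooled
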