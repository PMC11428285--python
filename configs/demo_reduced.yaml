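# reduced-scale demonstration (minutes on one CPU)
simulation:
  time_step: 0.02
  gamma: 4.5
  lambda_vv: 0.65
equilibration:
  max_steps: 120000
  check_interval: 5000
  anneal_from: 2.0
  anneal_steps: 40000
dissolution:
  n_layers: 2
  end_concentration: 0.2
  relax_steps: 2000
  steps: 24000
  stride: 2000
analysis:
  bin_width: 0.332
  cluster_cutoff: 1.0
  n_zones: 5
system:
  fractions:
    3A2BC: 0.8
    water: 0.2
  box:
  - 10.0
  - 10.0
  - 10.0
  density: 3.0
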