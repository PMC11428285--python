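# Run configuration schema

Pipeline runs are described by a YAML mapping with four sections (all
keys optional unless marked; defaults in parentheses).  Example files
for the study's seven surfactant-mixture fractions and four oil chain
lengths, plus a reduced-scale demo, live in `configs/`.

```yaml
system:                      # required for simulation runs
  fractions:                 # molecule name -> volume fraction, sums to 1
    3A2BC: 0.8               # names: 3A2BC, 4ABC, oil1..oil4, water
    water: 0.2
  box: [20.0, 20.0, 20.0]    # edge lengths in r_c
  density: 3.0               # beads per r_c^3

simulation:
  time_step: 0.02
  gamma: 4.5                 # thermostat friction; sigma^2 = 2 gamma kT
  kT: 1.0
  lambda_vv: 0.65            # velocity-Verlet prediction weight

forcefield:                  # optional overrides
  repulsion:                 # pair -> A_ij, e.g. "A-O": 106.5
  spring_constant: 75.0      # bond kappa (all bonds)
  equilibrium_length: 0.45   # bond r_eq

equilibration:
  max_steps: 120000          # hard cap
  check_interval: 5000       # structure-factor check cadence
  anneal_from: 2.0           # start kT of the linear cooling ramp
  anneal_steps: 40000        # ramp length; omit both to quench directly

dissolution:
  n_layers: 4                # lamellar periods kept by the crop
  end_concentration: 0.2     # fully-dissolved target (sets water length)
  relax_steps: 10000         # restrained seam relaxation
  steps: 200000              # dissolution run length
  stride: 5000               # snapshot cadence

analysis:
  bin_width: 0.332           # concentration slab width in r_c
  cluster_cutoff: 1.0        # micelle linkage cutoff in r_c
  n_zones: 5                 # zonal model compartments
```

The root seed is passed separately (`--seed` on the CLI, `seed=` in
`run_pipeline`); every random stage derives its stream from it, and
rerunning an identical config + seed reproduces the trajectory
bit-for-bit.  The manifest written next to the outputs records the
config hash, seed, per-stage timings and output files.
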