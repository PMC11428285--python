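# lamella

Dissipative particle dynamics (DPD) simulation and analysis of
surfactant lamellar-phase dissolution.

Concentrated surfactant solutions order into lamellar mesophases;
when such a phase meets water it dissolves by shedding micelles layer
by layer, and the rate at which this happens controls how
surfactant-based formulations (detergents, personal-care products)
disperse in use.  `lamella` provides the full computational workflow
for studying that process in coarse-grained simulation, for anyone
interested in how surfactant mixtures and oil additives change
dissolution kinetics:

* a momentum-conserving **DPD engine** (soft repulsion
  F^C = A_ij(1 − r/r_c), pair-wise dissipative/random thermostat with
  σ² = 2γk_BT, harmonic bead-spring bonds, walls, cell lists, numba
  kernels, bit-reproducible for a fixed seed);
* a **system builder** that equilibrates an 80 vol% surfactant box to a
  lamellar phase (with optional temperature annealing), rotates and
  crops it, stitches it to a water column sized so the dissolved end
  state hits a target concentration, adds frozen-bead walls and relaxes
  the seam with tethered head beads;
* an **analysis stack**: concentration profiles along the dissolution
  axis and their standard deviation (homogeneity), micelle detection by
  tail-bead proximity clustering (aggregates of ≤ 3 chains count as
  free surfactant), aggregation numbers and the size metric V^(−1/3),
  and a compartmental **zonal model** — first-order lamellar
  transformation (rate k_trans) feeding Fickian exchange (constant D)
  between five equal zones:

      dC_S/dt = −k_trans C_S
      dC_1/dt = +k_trans C_S (V_S/V_z) + D (C_2 − C_1)
      dC_i/dt =  D (C_{i−1} − 2 C_i + C_{i+1})

  fitted to simulation output statsmodels-style:
  `ZonalDissolutionModel(series).fit().summary()`;
* **synthetic generators** (planted micelle fields, step concentration
  boxes, zone curves at known parameters) that make every analysis
  stage testable against constructed ground truth.

The forcefield is the five-species model A (−C₃H₆− tail), B (−EO₂−),
C (−OSO₃⁻, hydration encoded as low C–W repulsion, no explicit
charge), W (4 waters), O (oil ≡ tail fragment), with surfactants
3A2BC and 4ABC and oils O₁…O₄.  See `docs/methods.md` for the model,
parameters and numerical choices.

## Worked example

Identify planted micelles carrying solubilised oil, then fit the
dissolution kinetics of a synthetic zone series:

```python
from lamella import (
    PlantedSpec, gen_planted_micelles, find_micelles, micelle_statistics,
    gen_zonal_curves, ZonalDissolutionModel,
)

state, truth = gen_planted_micelles(
    PlantedSpec(n_clusters=3, chains_per_cluster=20, oil_per_cluster=5,
                oil_template="oil2", seed=42))
stats = micelle_statistics(find_micelles(state, cutoff=1.0))
print(stats.n_micelles, stats.mean_chains, stats.mean_volume, stats.size_metric)

series = gen_zonal_curves(k_trans=0.01, d=50.0, noise_sd=0.01, n_points=200, seed=1)
print(ZonalDissolutionModel(series).fit().summary())
```

Output:

```
micelles found: 3
mean chains per micelle: 20.0
mean micelle volume (beads): 130.0
size metric V^(-1/3): 0.197

Zonal dissolution model fit
==============================================
n observations                            1200
n zones                                      5
residual norm                         0.332584
----------------------------------------------
parameter           estimate         std err
k_trans           0.00996559         3.6e-06
D                    50.0641           0.172
----------------------------------------------
```

Each of the 3 planted 20-chain micelles is recovered exactly; the mean
volume of 130 beads (120 surfactant + 10 oil) gives the
Stokes–Einstein-style size metric 130^(−1/3) = 0.197, the quantity
that tracks micelle diffusion for solid spheres.  The fit recovers the
planted (k_trans, D) = (0.01, 50) within 0.4% from 1% noisy curves,
with standard errors from the Gauss–Newton covariance.

The full simulation pipeline is driven either from Python
(`lamella.run_pipeline`) or the CLI:

```bash
lamella run-all --seed 1 --out pipeline_out          # reduced demo config
lamella synth zonal --k-trans 0.01 --diffusion 50 --out curves.csv
lamella zonal-fit --series curves.csv --volume-ratio 1.6
```

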