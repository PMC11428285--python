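# Methods

`lamella` simulates and analyses the dissolution of surfactant lamellar
phases with dissipative particle dynamics (DPD), and provides the
analysis stack — concentration homogeneity, micelle clustering, and a
compartmental transformation/diffusion model — used to characterise how
surfactant mixtures and oil additives change the dissolution process.

## The coarse-grained model

Five bead species at reduced density ρ = 3 beads/r_c³:

| bead | fragment | role |
|------|----------|------|
| A | −C₃H₆− | hydrophobic tail segment |
| B | −EO₂− | head, ethoxy block |
| C | −OSO₃⁻ | head, sulfate (no explicit charge; its strong hydration is encoded as a low C–W repulsion of 83) |
| W | 4 H₂O | solvent |
| O | −C₃H₆− | oil segment (chemically identical to A) |

Surfactants are bead-spring chains `3A2BC` (A-A-A-B-B-C) and `4ABC`
(A-A-A-A-B-C); oils are Oₙ chains with n = 1…4; water is a single
unbonded bead.  Bonds are harmonic, κ = 75, r_eq = 0.45 (one bonded
interaction for the whole forcefield).  The repulsion matrix uses
A_ii = 106.5 on the diagonal — the value that reproduces the
compressibility of water when one bead lumps four water molecules at
ρ = 3 — with off-diagonal values encoding hydrophobicity contrast.
The printed source table for these parameters lists one inconsistent
tail–oil entry (A–O appears both as 106.5 and 126.5); since A and O are
the same −C₃H₆− fragment, their cross-repulsion must equal the A–A
self term, so the builder resolves the conflict to 106.5 and emits a
warning when fed an asymmetric raw table.

Reduced units everywhere: r_c = k_BT = m = 1.  The physical mapping
(bead mass 4·M_w/N_A ≈ 1.2×10⁻²⁵ kg; r_c from matching ρ = 3 to the
density of water ≈ 7.1×10⁻¹⁰ m; time unit r_c√(m/k_BT)) lives in
`lamella.units` and is never used by the dynamics.

## DPD engine

Pairwise forces inside the cutoff: conservative soft repulsion
F^C = A_ij(1−r)ê, dissipative friction F^D = −γ w²(r)(ê·v_ij)ê and
random kicks F^R = σ w(r) ζ_ij Δt^(−1/2) ê with w(r) = 1−r,
σ² = 2γk_BT (fluctuation–dissipation) and ζ_ij a unit Gaussian drawn
once per interacting pair per step and applied antisymmetrically —
this is what makes the thermostat conserve momentum exactly.
Defaults: Δt = 0.02, γ = 4.5.

Integration is the Groot–Warren modified velocity-Verlet.  The
velocity-prediction weight is λ = 0.65, the value Groot & Warren
recommend for σ = 3: with λ = 0.5 the measured kinetic temperature of
the ideal γ = 4.5 fluid at Δt = 0.02 sits ~4% above target (the
documented artifact of that variant), while λ = 0.65 holds it within
~1.5%.  λ is a `SimulationParameters` field for anyone wanting the
λ = 1/2 variant.

Neighbor search is a counting-sort cell list (cell edge ≥ r_c) rebuilt
every step, with positions gathered into cell-major order for cache
locality; boxes too small for a 3-cell grid fall back to an all-pairs
loop.  Single-threaded numba kernels make trajectories bit-reproducible
for a fixed seed: all thermostat noise derives from one root seed via
`SeedSequence` spawning per integration chunk.

Walled boxes (the dissolution geometry) are periodic in y, z and
bounded in x by a quadratic repulsion U = A_wall(1−z/z_c)² acting
within z_c = 1 of either boundary (A_wall = 106.5), backed by two rows
of frozen W beads just inside each wall plane at the areal density a
ρ = 3 fluid would supply.  Frozen beads exert forces but never move.

### Engine validation

* Momentum drift ≤ 10⁻¹⁰ per step in periodic wall-free runs.
* Kinetic temperature of a 3000-bead fluid within 2% of k_BT = 1.
* A harmonic dimer with the thermostat off shows no secular energy
  drift (segment means; velocity-Verlet's bounded shadow-Hamiltonian
  oscillation is not drift).
* Pressure: the engine's virial pressure was cross-checked against an
  independent Metropolis Monte Carlo of the same potential — the two
  agree to 0.2% at ρ = 3 for both A = 25 and A = 106.5.  The common
  soft-sphere estimate p ≈ ρk_BT + 0.101·A·ρ² uses the high-density
  plateau coefficient and overestimates the true pressure of this
  fluid by ~5% at ρ = 3 (8% at A = 25); the equation-of-state property
  test therefore runs at ρ = 5, inside the plateau regime, where the
  engine agrees with the estimate to ~1%.

## Building the dissolution experiment

1. **Random box** at the requested composition (volume fraction =
   bead-count fraction at unit bead volume; whole-molecule counts by
   largest-remainder rounding, water absorbing the residue).
2. **Equilibrate** until lamellar.  The order parameter is the dominant
   axis-aligned density-wave amplitude |⟨exp(2πi n x/L)⟩| of the tail
   (A) beads over the three axes and n = 1…8 — at 80 vol% surfactant
   the total surfactant field is nearly uniform and carries almost no
   signal, while the bilayer cores modulate strongly.  A direct quench
   of this strongly segregated mixture tends to arrest in a disordered
   sponge, so the equilibration supports a linear temperature ramp
   (default anneal from kT = 2 at reduced scale) that cools through
   the order–disorder transition before holding at kT = 1; annealing
   changes the path, not the sampled equilibrium.  The run stops when
   the amplitude plateaus (relative change < 5% over 3 checks) above a
   floor of 0.15, with a hard step cap; a run that hits the cap while
   still fluctuating returns its most-ordered snapshot (the best-so-far
   rule of annealed preparation).
3. **Crop & rotate**: the detected layer normal is permuted onto x and
   the box cut to n layer periods (default 4; 2 at reduced scale).
   Molecules are kept iff their first bead lies in the window and are
   unwrapped so they stay whole; the small density defect this leaves
   at the cut is healed by the restrained relaxation.
4. **Stitch**: a pre-equilibrated water column is appended so that the
   fully dissolved box would sit at the target end concentration
   (default 20 vol%): L_total = S/(ρ·c_end·L_y·L_z) with S the number
   of dissolving beads.  The combined box becomes walled in x.
5. **Relax** 10,000 steps with the sulfate (C) beads tethered to their
   original positions (κ_tether = 75, same as bonds, configurable),
   evening out the density seam; tethers are removed on return.

## Analysis stack

**Concentration profiles.**  Bead-count fraction of a species set per
x slab of width 0.332 r_c (final partial slab merged), wall beads
excluded from numerator and denominator.  The homogeneity metric is
the unweighted population std of the slab values: ~0 when dissolved,
large when the surfactant sits at one end.  Its time series is
summarised by the plateau end (first 5% drop from the initial value)
and the slope of the falling branch.

**Micelle clustering.**  Two chains are linked iff any pair of their
A beads lies within r_cl = 1.0 r_c (minimum image); micelles are
connected components of that graph, with groups of ≤ 3 chains counted
as free surfactant rather than micelles.  Each oil molecule joins the
micelle of its nearest A bead within the cutoff, else stays
unassigned.  The linkage uses a periodic KD-tree plus sparse connected
components and is cross-checked in the tests against an O(n²)
union-find oracle.  Size summary: mean aggregation number, micelle
count, mean micelle volume V = mean total bead count (oil included,
unit bead volume — the only volume definition consistent with the
study's printed size-metric columns) and the metric V^(−1/3), which
for a Stokes–Einstein solid sphere is proportional to its diffusion
constant.  The exponent is exactly 1/3: the printed label "1/V^0.33"
does not reproduce the printed numbers, 1/3 does, for all eleven
table rows.

**Zonal dissolution model.**  The walled box is split into the frozen
initial lamellar span (volume V_S) plus n = 5 equal water zones; per
snapshot each zone's surfactant(+oil) bead fraction is recorded.  The
kinetics is the linear compartment model

    dC_S/dt = −k_trans·C_S
    dC_1/dt = +k_trans·C_S·(V_S/V_z) + D(C_2 − C_1)
    dC_i/dt = D(C_{i−1} − 2C_i + C_{i+1}),   dC_n/dt = D(C_{n−1} − C_n)

— first-order transformation of the lamellar phase feeding a
discrete-Fickian chain.  The V_S/V_z factor makes total mass exactly
conserved; D absorbs the (zone width)⁻² geometry and is reported in
model-internal units (no physical conversion is attempted).  The
forward model is propagated with the matrix exponential (linear,
constant coefficients — exact and unconditionally stable), and
(k_trans, D) are fitted jointly over all six curves by trust-region
least squares, log-parameterised for positivity, from a log-spaced
multi-start grid.  Residuals are relatively weighted by default
(concentrations are count fractions with signal-proportional error);
absolute weighting is one keyword away.  When the zones carry no
signal the fit flags D as unidentifiable instead of reporting a
meaningless number.

## Synthetic data

The generators make every analysis stage testable without dynamics:

* **Planted micelles** — coiled chains whose first tail beads sit
  within 0.45 r_c of their cluster centre (hence mutually linked for
  any cutoff ≥ 0.9 r_c), cluster centres separated by > 2 cutoff +
  2 radius: ground-truth membership is unambiguous by construction and
  returned alongside the configuration.
* **Zone curves** — forward-model output at known (k_trans, D) with
  optional proportional Gaussian noise, on a log-spaced time grid: with
  k_trans and D separated by orders of magnitude a uniform grid never
  samples the fast zone-filling transient and leaves D nearly
  unidentifiable; geometric spacing resolves both timescales.
* **Step boxes** — surfactant uniform in the left x fraction at ρ = 3,
  giving closed-form profile and homogeneity expectations (a half-box
  step of height c has std exactly c/2).

None of the generators use the analysis code under test to define
their ground truth.  What they deliberately do not emulate: thermal
interface roughness, chain-conformation statistics, correlated noise
in zone series, and polydisperse micelle shapes — passing the
analysis tests therefore certifies bookkeeping and inference, not the
physics of real trajectories, which only the engine-level runs probe.

## Problem sizes

Desk-scale defaults were chosen so the full suite and the acceptance
script each run in minutes on one CPU: equilibration/phenomenology in
a 10×10×10 box (3,000 beads, 2-layer crop, ~30k-step dissolution),
thermostat checks at 3,000 beads × 2,000 steps, cluster cross-checks
at 200 chains, zonal recovery at 200 time points.  The study-scale
geometry (20×20×20 equilibration, 4 layers, 79–99 r_c dissolution
boxes, ~10⁵ beads) is fully supported by the same code path and config
files; its long stochastic schedules are simply not run in the test
suite, so the headline fitted diffusion constants of the full-scale
study are out of the desk-scale envelope (direction-of-effect checks
stand in for them).

## Known limitations

* No electrostatics (the sulfate head's hydration is mimicked by the
  C–W repulsion), no angle/dihedral potentials, no barostat (NVT
  only), single-CPU kernels.
* Lamellar-normal detection is restricted to axis permutations; tilted
  lamellae in large boxes would be missed (at the small box sizes used
  the layers form axis-aligned).
* The annealed equilibration at 10³ yields a 2-layer lamellar stack
  with residual defects; amplitudes ~0.2–0.4 rather than the ≳0.5 of
  a defect-free planted stack.
* k_trans and D are fitted jointly; the study's stage-wise reading of
  the same model is recovered by inspecting the per-stage residuals of
  the joint fit.
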