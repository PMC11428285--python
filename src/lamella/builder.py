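"""Construction of the two-stage dissolution experiment.

Stage one equilibrates a concentrated (80 vol%) surfactant/water box
until it orders into a lamellar phase.  Stage two turns that box into
the dissolution initial condition: rotate the lamellar normal onto the
x axis, crop to a fixed number of layers, stitch a pre-equilibrated
water column onto the slab so the fully-dissolved end concentration
hits a target (20 vol% in the study design), close the x direction
with repulsive walls backed by two rows of frozen water beads, and
relax the seam with the ionic head (C) beads tethered to their
original positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import RunSchedule, Tethers, run_simulation
from .forcefield import (
    InteractionMatrix,
    MoleculeTemplate,
    SimulationParameters,
    SPECIES_INDEX,
)
from .state import SystemState

__all__ = [
    "CompositionSpec",
    "build_random_box",
    "equilibrate_lamellar",
    "lamellar_order",
    "crop_and_rotate",
    "stitch_dissolution_box",
    "relax_restrained",
    "NotLamellarError",
]


class NotLamellarError(RuntimeError):
    """Raised when no periodic surfactant density wave is detectable."""


@dataclass
class CompositionSpec:
    """Volume fractions of molecule types filling a box at density rho."""

    fractions: dict[str, float]
    box: tuple[float, float, float]
    density: float = 3.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")

    @property
    def n_beads(self) -> int:
        return int(round(self.density * float(np.prod(self.box))))

    def molecule_counts(self, templates: dict[str, MoleculeTemplate]) -> dict[str, int]:
        """Whole-molecule counts by largest-remainder rounding on beads.

        Volume fraction equals bead-count fraction at uniform bead
        volume.  Residual beads left by chain rounding are balanced
        with water molecules when water is present.
        """
        n = self.n_beads
        counts: dict[str, int] = {}
        remainders: list[tuple[float, str]] = []
        for name, frac in self.fractions.items():
            if frac == 0.0:
                continue
            size = templates[name].n_beads
            ideal = frac * n / size
            if ideal < 1.0:
                raise ValueError(
                    f"fraction {frac} of {name!r} yields {ideal:.2f} < 1 molecule"
                )
            counts[name] = int(ideal)
            remainders.append((ideal - int(ideal), name))
        assigned = sum(counts[m] * templates[m].n_beads for m in counts)
        leftover = n - assigned
        # hand out whole molecules by largest remainder while they fit
        for rem, name in sorted(remainders, reverse=True):
            size = templates[name].n_beads
            if leftover >= size:
                counts[name] += 1
                leftover -= size
        if leftover and "water" in counts:
            counts["water"] += leftover  # 1-bead molecules absorb the rest
        return counts


def build_random_box(
    spec: CompositionSpec,
    templates: dict[str, MoleculeTemplate],
    seed: int = 0,
    kT: float = 1.0,
) -> SystemState:
    """Randomly placed molecules at the requested composition.

    Chains are grown as random walks with step r_eq from a uniform
    start; velocities are Maxwell-distributed at kT with zero net
    momentum.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)
    counts = spec.molecule_counts(templates)
    positions, species, mol_ids, bonds = [], [], [], []
    mol_id = 0
    offset = 0
    for name, count in counts.items():
        t = templates[name]
        for _ in range(count):
            start = rng.uniform(0, 1, 3) * box
            pos = np.empty((t.n_beads, 3))
            pos[0] = start
            for b in range(1, t.n_beads):
                step = rng.normal(size=3)
                step *= t.equilibrium_length / np.linalg.norm(step)
                pos[b] = pos[b - 1] + step
            positions.append(pos)
            species.append([SPECIES_INDEX[s] for s in t.bead_sequence])
            mol_ids.append(np.full(t.n_beads, mol_id))
            for i, j in t.bonds:
                bonds.append((offset + i, offset + j))
            offset += t.n_beads
            mol_id += 1
    n = offset
    vel = rng.normal(0.0, np.sqrt(kT), (n, 3))
    vel -= vel.mean(axis=0)
    state = SystemState(
        positions=np.vstack(positions),
        velocities=vel,
        species=np.concatenate(species),
        molecule_id=np.concatenate(mol_ids),
        box=box,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
    )
    state.wrap()
    return state


SURFACTANT = ("A", "B", "C")


def lamellar_order(
    state: SystemState,
    max_waves: int = 8,
    species_labels: tuple[str, ...] = SURFACTANT,
) -> tuple[int, int, float]:
    """Dominant axis-aligned density wave of the surfactant field.

    Returns (axis, n_layers, amplitude) maximising the normalised
    structure-factor amplitude |<exp(2 pi i n x_j / L)>| over the three
    axes and wavenumbers n = 1..max_waves.  An isotropic configuration
    gives amplitude O(N^-1/2); a well-formed lamellar phase typically
    exceeds 0.2.
    """
    sel = state.species_mask(set(species_labels)) & ~state.frozen
    x = state.positions[sel]
    if len(x) == 0:
        raise NotLamellarError("no surfactant beads present")
    best = (0, 1, 0.0)
    for axis in range(3):
        phase = 2j * np.pi * x[:, axis] / state.box[axis]
        for n in range(1, max_waves + 1):
            amp = float(np.abs(np.exp(phase * n).mean()))
            if amp > best[2]:
                best = (axis, n, amp)
    return best


def equilibrate_lamellar(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    max_steps: int = 200_000,
    check_interval: int = 5_000,
    plateau_rtol: float = 0.05,
    plateau_checks: int = 3,
    min_amplitude: float = 0.15,
    anneal_from: float | None = None,
    anneal_steps: int = 0,
    order_species: tuple[str, ...] = ("A",),
    keep_best: bool = True,
    kappa: float = 75.0,
    r_eq: float = 0.45,
) -> tuple[SystemState, list[dict]]:
    """Run NVT dynamics until the lamellar structure factor plateaus.

    The order parameter is the dominant density-wave amplitude of the
    tail (A) beads — at 80 vol% surfactant the total surfactant field is
    nearly uniform and carries almost no layering signal, while the
    bilayer cores modulate strongly.

    With ``anneal_from`` set, the temperature is ramped linearly from
    that value down to ``params.kT`` over the first ``anneal_steps``
    steps.  Cooling through the order-disorder transition relaxes the
    kinetically trapped sponge that direct quenches of strongly
    segregated mixtures produce, without changing the equilibrium state
    the run samples at the target temperature.

    Stops when the amplitude exceeds ``min_amplitude`` and has changed
    by less than ``plateau_rtol`` (relative) over ``plateau_checks``
    consecutive checks, or at ``max_steps``.  Small boxes fluctuate
    strongly around partial order; with ``keep_best`` (default) the
    most-ordered snapshot seen is returned when the run hits the step
    cap without a plateau — the standard best-so-far rule of annealed
    preparation.  Returns the state and the order-parameter history.
    """
    current = state.copy()
    history: list[dict] = []
    best_amp = -1.0
    best_state = current
    done = 0
    while done < max_steps:
        if anneal_from is not None and done < anneal_steps:
            frac = done / anneal_steps
            kT = anneal_from + (params.kT - anneal_from) * frac
        else:
            kT = params.kT
        p = SimulationParameters(
            time_step=params.time_step, cutoff=params.cutoff, kT=kT,
            density=params.density, gamma=params.gamma,
            wall_strength=params.wall_strength, wall_range=params.wall_range,
            rng_seed=params.rng_seed + done, lambda_vv=params.lambda_vv,
        )
        traj = run_simulation(
            current, matrix, p,
            RunSchedule(n_steps=check_interval, stride=check_interval),
            kappa=kappa, r_eq=r_eq,
        )
        current = traj[-1]
        done += check_interval
        axis, n, amp = lamellar_order(current, species_labels=order_species)
        history.append(
            {"step": done, "axis": axis, "n_layers": n, "amplitude": amp, "kT": kT}
        )
        if done > anneal_steps and amp > best_amp:
            best_amp = amp
            best_state = current.copy()
        if (
            len(history) > plateau_checks
            and amp > min_amplitude
            and done > anneal_steps
        ):
            recent = [h["amplitude"] for h in history[-plateau_checks - 1:]]
            if max(recent) - min(recent) <= plateau_rtol * max(recent):
                break
    else:
        if keep_best and best_amp > 0:
            current = best_state
            history.append(
                {"step": done, "axis": history[-1]["axis"],
                 "n_layers": history[-1]["n_layers"], "amplitude": best_amp,
                 "kT": params.kT, "kept_best": True}
            )
            axis, n, amp = lamellar_order(current, species_labels=order_species)
            history[-1].update({"axis": axis, "n_layers": n, "amplitude": amp})
    current.time = done * params.time_step
    return current, history


def _first_bead_index(state: SystemState) -> np.ndarray:
    """Index of the first bead of each molecule, in molecule order."""
    _, first = np.unique(state.molecule_id, return_index=True)
    return first


def _unwrap_molecules(state: SystemState) -> np.ndarray:
    """Positions with each molecule made whole around its first bead."""
    pos = state.positions.copy()
    order = np.argsort(state.molecule_id, kind="stable")
    mol_sorted = state.molecule_id[order]
    box = state.box
    start = 0
    while start < len(order):
        end = start
        while end < len(order) and mol_sorted[end] == mol_sorted[start]:
            end += 1
        idx = order[start:end]
        ref = pos[idx[0]]
        d = pos[idx] - ref
        d -= box * np.round(d / box)
        pos[idx] = ref + d
        start = end
    return pos


def crop_and_rotate(
    equilibrated: SystemState,
    n_layers: int = 4,
    min_amplitude: float = 0.15,
    order_species: tuple[str, ...] = ("A",),
) -> SystemState:
    """Align the lamellar normal with x and crop to ``n_layers`` periods.

    Rotation is an axis permutation (lamellae form axis-aligned in
    small periodic boxes).  A molecule is kept iff its first bead lies
    inside the crop window; kept molecules are unwrapped so they stay
    whole.  Raises :class:`NotLamellarError` when no density wave above
    ``min_amplitude`` exists (layer detection uses the tail beads,
    whose modulation carries the layering signal).
    """
    axis, n_detected, amp = lamellar_order(equilibrated, species_labels=order_species)
    if amp < min_amplitude:
        raise NotLamellarError(
            f"not lamellar: structure-factor amplitude {amp:.3f} < {min_amplitude}"
        )
    if n_layers > n_detected:
        raise NotLamellarError(
            f"requested {n_layers} layers but only {n_detected} periods present"
        )
    state = equilibrated.copy()
    if axis != 0:
        perm = list(range(3))
        perm[0], perm[axis] = perm[axis], perm[0]
        state.positions = np.ascontiguousarray(state.positions[:, perm])
        state.velocities = np.ascontiguousarray(state.velocities[:, perm])
        state.box = state.box[perm]
    period = state.box[0] / n_detected
    crop_len = n_layers * period
    pos = _unwrap_molecules(state)
    first = _first_bead_index(state)
    first_x = np.mod(pos[first, 0], state.box[0])
    keep_mol = state.molecule_id[first][first_x < crop_len]
    keep = np.isin(state.molecule_id, keep_mol)
    old_to_new = -np.ones(state.n_beads, dtype=np.int64)
    old_to_new[keep] = np.arange(int(keep.sum()))
    kept_bonds = state.bonds[np.all(keep[state.bonds], axis=1)]
    cropped = SystemState(
        positions=pos[keep],
        velocities=state.velocities[keep],
        species=state.species[keep],
        molecule_id=state.molecule_id[keep],
        box=np.array([crop_len, state.box[1], state.box[2]]),
        bonds=old_to_new[kept_bonds],
        time=state.time,
    )
    # molecules are unwrapped around their first bead (inside the crop
    # window), so beads may poke slightly past the window edges in x;
    # the restrained relaxation heals this. y/z stay periodic.
    cropped.positions[:, 1] %= cropped.box[1]
    cropped.positions[:, 2] %= cropped.box[2]
    return cropped


def _wall_rows(box: np.ndarray, x_positions: list[float], spacing_target: float = 0.82):
    """Square-lattice frozen W-bead rows at the given x planes."""
    ny = max(1, int(round(box[1] / spacing_target)))
    nz = max(1, int(round(box[2] / spacing_target)))
    ys = (np.arange(ny) + 0.5) * box[1] / ny
    zs = (np.arange(nz) + 0.5) * box[2] / nz
    pts = []
    for x in x_positions:
        for y in ys:
            for z in zs:
                pts.append((x, y, z))
    return np.array(pts)


def stitch_dissolution_box(
    lamellar: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    seed: int = 0,
    end_concentration: float = 0.2,
    water_equil_steps: int = 500,
    water_len: float | None = None,
) -> tuple[SystemState, tuple[float, float]]:
    """Attach a water column and walls to a cropped lamellar slab.

    The water column length is derived from the target fully-dissolved
    concentration: with S dissolving beads (surfactant + oil) the total
    fluid length is S / (rho * end_concentration * Ly * Lz), unless
    ``water_len`` overrides it.  The x direction becomes walled, with
    two rows of frozen W beads just inside each boundary.  Returns the
    combined state and the (x0, x1) span of the lamellar slab for the
    zonal analysis.
    """
    box = lamellar.box
    ly, lz = float(box[1]), float(box[2])
    rho = params.density
    dissolving = int(
        (lamellar.species_mask({"A", "B", "C", "O"}) & ~lamellar.frozen).sum()
    )
    lam_len = float(box[0])
    if water_len is None:
        total_len = dissolving / (rho * end_concentration * ly * lz)
        water_len = total_len - lam_len
        if water_len <= 0:
            raise ValueError(
                f"end concentration {end_concentration} needs no water "
                f"(lamellar already {lam_len:.1f} long)"
            )
    total_len = lam_len + water_len

    # pre-equilibrated water column (periodic box, then opened)
    rng = np.random.default_rng(seed)
    n_water = int(round(rho * water_len * ly * lz))
    wpos = rng.uniform(0, 1, (n_water, 3)) * np.array([water_len, ly, lz])
    wvel = rng.normal(0, 1, (n_water, 3))
    wvel -= wvel.mean(axis=0)
    water = SystemState(
        positions=wpos,
        velocities=wvel,
        species=np.full(n_water, SPECIES_INDEX["W"], dtype=np.int8),
        molecule_id=np.arange(n_water, dtype=np.int32),
        box=np.array([water_len, ly, lz]),
    )
    if water_equil_steps:
        wp = SimulationParameters(
            time_step=params.time_step, gamma=params.gamma, kT=params.kT,
            density=rho, rng_seed=seed + 1, lambda_vv=params.lambda_vv,
        )
        water = run_simulation(
            water, matrix, wp, RunSchedule(n_steps=water_equil_steps, stride=water_equil_steps)
        )[-1]

    max_mol = int(lamellar.molecule_id.max()) + 1
    wall_pts = _wall_rows(
        np.array([total_len, ly, lz]),
        [0.25, 0.75, total_len - 0.75, total_len - 0.25],
    )
    n_wall = len(wall_pts)
    positions = np.vstack(
        [lamellar.positions, water.positions + [lam_len, 0, 0], wall_pts]
    )
    velocities = np.vstack(
        [lamellar.velocities, water.velocities, np.zeros((n_wall, 3))]
    )
    species = np.concatenate(
        [lamellar.species, water.species,
         np.full(n_wall, SPECIES_INDEX["W"], dtype=np.int8)]
    )
    molecule_id = np.concatenate(
        [lamellar.molecule_id, water.molecule_id + max_mol,
         np.full(n_wall, -1, dtype=np.int32)]
    )
    frozen = np.concatenate(
        [lamellar.frozen, water.frozen, np.ones(n_wall, dtype=bool)]
    )
    bonds = np.vstack([lamellar.bonds, water.bonds + lamellar.n_beads])
    stitched = SystemState(
        positions=positions,
        velocities=velocities,
        species=species,
        molecule_id=molecule_id,
        box=np.array([total_len, ly, lz]),
        frozen=frozen,
        walled_x=True,
        bonds=bonds,
        time=0.0,
    )
    # clamp free beads into the open interval so nothing starts beyond a wall
    free = ~stitched.frozen
    stitched.positions[free, 0] = np.clip(
        stitched.positions[free, 0], 0.05, total_len - 0.05
    )
    stitched.wrap()
    return stitched, (0.0, lam_len)


def relax_restrained(
    stitched: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    n_steps: int = 10_000,
    tether_k: float = 75.0,
    stride: int | None = None,
    kappa: float = 75.0,
    r_eq: float = 0.45,
) -> SystemState:
    """Relax the stitched box with C beads tethered to their positions.

    Evens out the density and pressure discontinuities introduced by
    stitching while the tethers stop the lamellar slab from drifting;
    the tethers are removed on return.  Pure-water boxes (no C beads)
    simply thermalise.
    """
    c_idx = np.flatnonzero(stitched.species_mask({"C"}) & ~stitched.frozen)
    tethers = None
    if len(c_idx):
        tethers = Tethers(
            indices=c_idx,
            anchors=stitched.positions[c_idx].copy(),
            spring_constant=tether_k,
        )
    schedule = RunSchedule(
        n_steps=n_steps, stride=stride or max(1, n_steps), tethers=tethers
    )
    traj = run_simulation(stitched, matrix, params, schedule, kappa=kappa, r_eq=r_eq)
    return traj[-1]
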