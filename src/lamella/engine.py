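"""NVT dissipative-particle-dynamics engine.

Beads interact through three pairwise forces inside a cutoff r_c:

* conservative soft repulsion  F^C = A_ij (1 - r/r_c) e_ij,
* dissipative friction         F^D = -gamma w^D(r) (e_ij . v_ij) e_ij,
* random kicks                 F^R = sigma w^R(r) zeta_ij dt^(-1/2) e_ij,

with w^D = (w^R)^2 = (1 - r/r_c)^2 and sigma^2 = 2 gamma k_B T so that
the dissipative/random pair thermostats the system at k_B T while
conserving momentum exactly (zeta_ij is drawn once per pair per step and
applied antisymmetrically).  Bonded beads add harmonic springs
kappa (r - r_eq); walled boxes add a quadratic short-range repulsion at
the x boundaries.  Integration is the Groot-Warren modified
velocity-Verlet with velocity-prediction weight lambda = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _kernels
from .forcefield import InteractionMatrix, SimulationParameters
from .state import SystemState, Trajectory

__all__ = [
    "ForceBreakdown",
    "RunSchedule",
    "SimulationError",
    "pair_forces",
    "bond_forces",
    "wall_force",
    "integrate_step",
    "run_simulation",
    "measure_temperature",
    "measure_pressure",
    "potential_energy",
    "kinetic_energy",
]


class SimulationError(RuntimeError):
    """Dynamics failure; carries the offending snapshot when available."""

    def __init__(self, message: str, state: SystemState | None = None):
        super().__init__(message)
        self.state = state


@dataclass
class ForceBreakdown:
    """Per-bead forces split by physical origin, each (N, 3)."""

    conservative: np.ndarray
    dissipative: np.ndarray
    random: np.ndarray
    bond: np.ndarray
    wall: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.conservative + self.dissipative + self.random + self.bond + self.wall


@dataclass
class Tethers:
    """Harmonic restraints pinning selected beads to fixed anchor points."""

    indices: np.ndarray
    anchors: np.ndarray
    spring_constant: float = 75.0

    def __post_init__(self) -> None:
        self.indices = np.ascontiguousarray(self.indices, dtype=np.int64)
        self.anchors = np.ascontiguousarray(self.anchors, dtype=np.float64)
        if self.anchors.shape != (len(self.indices), 3):
            raise ValueError("anchors must be (n_tethers, 3)")


_NO_TETHER_IDX = np.zeros(0, dtype=np.int64)
_NO_TETHER_ANCHORS = np.zeros((0, 3), dtype=np.float64)


@dataclass
class RunSchedule:
    """What to run: step count, snapshot stride, optional restraints."""

    n_steps: int
    stride: int = 100
    tethers: Tethers | None = None
    log_interval: int = 0  # 0 disables physics logging

    def __post_init__(self) -> None:
        if self.n_steps < 0 or self.stride <= 0:
            raise ValueError("n_steps must be >= 0 and stride > 0")


def _chunk_seed(root_seed: int, chunk: int) -> int:
    """Independent 31-bit stream seed for one integration chunk."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(chunk,))
    return int(ss.generate_state(1)[0] % (2**31))


def pair_forces(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    step_seed: int | None = None,
) -> ForceBreakdown:
    """All pairwise DPD forces for one configuration.

    ``step_seed`` seeds the per-pair Gaussian draws of the random force;
    ``None`` disables the random force (sigma treated as 0), which gives
    the deterministic conservative + dissipative fields used by force
    oracles.
    """
    sigma = params.sigma
    if step_seed is None:
        sigma = 0.0
    else:
        _kernels.seed_rng(step_seed % (2**31))
    fc, fd, fr, _ = _kernels.pair_forces_kernel(
        state.positions,
        state.velocities,
        state.species,
        matrix.values,
        state.box,
        state.walled_x,
        params.cutoff,
        params.gamma,
        sigma,
        1.0 / np.sqrt(params.time_step),
    )
    n = state.n_beads
    return ForceBreakdown(fc, fd, fr, np.zeros((n, 3)), np.zeros((n, 3)))


def bond_forces(
    state: SystemState,
    kappa: float = 75.0,
    r_eq: float = 0.45,
) -> np.ndarray:
    """Harmonic bond forces from the state's bond list."""
    f, max_r = _kernels.bond_forces_kernel(
        state.positions, state.bonds, state.box, state.walled_x, kappa, r_eq
    )
    if max_r > 0.5 * float(state.box.min()):
        raise SimulationError(
            f"bond stretched to {max_r:.3f}, beyond half the smallest box edge "
            "(minimum-image ambiguity)",
            state,
        )
    return f


def wall_force(state: SystemState, params: SimulationParameters) -> np.ndarray:
    """Quadratic wall repulsion at the x boundaries of a walled box."""
    if not state.walled_x:
        raise SimulationError("wall_force requires a walled-x state")
    f, n_escaped = _kernels.wall_forces_kernel(
        state.positions, state.frozen, state.box, params.wall_strength, params.wall_range
    )
    if n_escaped:
        import warnings

        warnings.warn(
            f"{n_escaped} bead(s) beyond the wall plane; force clamped", stacklevel=2
        )
    return f


def _run_chunk_on_state(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    n_steps: int,
    kappa: float,
    r_eq: float,
    tethers: Tethers | None,
    thermostat: bool,
) -> None:
    t = tethers
    status, step = _kernels.run_chunk(
        state.positions,
        state.velocities,
        state.species,
        matrix.values,
        state.bonds,
        state.box,
        state.walled_x,
        state.frozen,
        n_steps,
        params.time_step,
        params.lambda_vv,
        params.cutoff,
        params.gamma if thermostat else 0.0,
        params.sigma if thermostat else 0.0,
        kappa,
        r_eq,
        params.wall_strength,
        params.wall_range,
        t.indices if t is not None else _NO_TETHER_IDX,
        t.anchors if t is not None else _NO_TETHER_ANCHORS,
        t.spring_constant if t is not None else 0.0,
    )
    if status == _kernels.STATUS_UNSTABLE:
        raise SimulationError(
            f"integration unstable at step {step}: displacement exceeded the cutoff "
            f"(time step {params.time_step})",
            state,
        )
    if status == _kernels.STATUS_NAN:
        raise SimulationError(f"NaN encountered at step {step}", state)


def integrate_step(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    step_seed: int | None = None,
    kappa: float = 75.0,
    r_eq: float = 0.45,
    tethers: Tethers | None = None,
    thermostat: bool = True,
) -> SystemState:
    """Advance one time step; returns a new state (input untouched)."""
    new = state.copy()
    if step_seed is not None:
        # without a seed the random force draws from the kernel RNG's
        # current stream; callers wanting reproducibility pass a seed
        _kernels.seed_rng(step_seed % (2**31))
    _run_chunk_on_state(new, matrix, params, 1, kappa, r_eq, tethers, thermostat)
    new.time = state.time + params.time_step
    return new


def run_simulation(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    schedule: RunSchedule,
    kappa: float = 75.0,
    r_eq: float = 0.45,
    thermostat: bool = True,
    log: list | None = None,
) -> Trajectory:
    """Run NVT dynamics, collecting snapshots every ``schedule.stride`` steps.

    Deterministic for a fixed ``params.rng_seed``: all thermostat noise
    derives from it.  The initial state is always frame 0.  If ``log``
    is a list and ``schedule.log_interval > 0``, per-interval dicts with
    step, time, kinetic temperature and total momentum are appended.
    """
    traj = Trajectory()
    current = state.copy()
    current.wrap()
    traj.append(current.copy())
    done = 0
    chunk_idx = 0
    while done < schedule.n_steps:
        n = min(schedule.stride, schedule.n_steps - done)
        _kernels.seed_rng(_chunk_seed(params.rng_seed, chunk_idx))
        _run_chunk_on_state(
            current, matrix, params, n, kappa, r_eq, schedule.tethers, thermostat
        )
        done += n
        chunk_idx += 1
        current.time = state.time + done * params.time_step
        traj.append(current.copy())
        if log is not None and schedule.log_interval > 0 and (
            done % schedule.log_interval == 0 or done == schedule.n_steps
        ):
            log.append(
                {
                    "step": done,
                    "time": current.time,
                    "temperature": measure_temperature(current),
                    "momentum": total_momentum(current).tolist(),
                }
            )
    return traj


def measure_temperature(state: SystemState) -> float:
    """Instantaneous kinetic temperature, 2<KE>/3 per free bead."""
    free = ~state.frozen
    n_free = int(free.sum())
    if n_free < 2:
        raise SimulationError("temperature undefined: fewer than 2 free beads")
    v = state.velocities[free]
    return float((v**2).sum() / (3.0 * n_free))


def total_momentum(state: SystemState) -> np.ndarray:
    """Total momentum of the free beads (reduced mass 1)."""
    return state.velocities[~state.frozen].sum(axis=0)


def measure_pressure(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
) -> float:
    """Instantaneous virial pressure, kinetic + conservative-pair terms.

    For a homogeneous one-species DPD fluid this tracks the soft-sphere
    equation of state p ~ rho kT + alpha A rho^2 with alpha ~ 0.101.
    """
    _, _, _, virial = _kernels.pair_forces_kernel(
        state.positions,
        state.velocities,
        state.species,
        matrix.values,
        state.box,
        state.walled_x,
        params.cutoff,
        params.gamma,
        0.0,
        1.0,
    )
    v = state.velocities[~state.frozen]
    volume = float(np.prod(state.box))
    return float(((v**2).sum() + virial) / (3.0 * volume))


@njit(cache=True)
def _potential_energy_kernel(pos, species, amat, bonds, box, walled_x, cutoff, kappa, r_eq):
    n = pos.shape[0]
    px = not walled_x
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if px:
                dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            dz -= box[2] * np.round(dz / box[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < cutoff:
                a = amat[species[i], species[j]]
                w = 1.0 - r / cutoff
                u += 0.5 * a * cutoff * w * w
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if px:
            dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u += 0.5 * kappa * (r - r_eq) ** 2
    return u


def potential_energy(
    state: SystemState,
    matrix: InteractionMatrix,
    params: SimulationParameters,
    kappa: float = 75.0,
    r_eq: float = 0.45,
) -> float:
    """Conservative + bond potential energy (O(N^2); diagnostics only)."""
    return float(
        _potential_energy_kernel(
            state.positions,
            state.species,
            matrix.values,
            state.bonds,
            state.box,
            state.walled_x,
            params.cutoff,
            kappa,
            r_eq,
        )
    )


def kinetic_energy(state: SystemState) -> float:
    return float(0.5 * (state.velocities[~state.frozen] ** 2).sum())
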