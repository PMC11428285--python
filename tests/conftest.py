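import numpy as np
import pytest

from lamella.forcefield import (
    SimulationParameters,
    default_interaction_matrix,
)
from lamella.state import SystemState


@pytest.fixture(scope="session")
def matrix():
    return default_interaction_matrix()


@pytest.fixture()
def params():
    return SimulationParameters(rng_seed=42)


def make_fluid(n_or_rho, box_len, seed=0, species_code=0, kT=1.0):
    """Random one-species fluid with zero net momentum."""
    rng = np.random.default_rng(seed)
    if isinstance(n_or_rho, float):
        n = int(round(n_or_rho * box_len**3))
    else:
        n = n_or_rho
    st = SystemState(
        positions=rng.uniform(0, box_len, (n, 3)),
        velocities=rng.normal(0, np.sqrt(kT), (n, 3)),
        species=np.full(n, species_code, dtype=np.int8),
        molecule_id=np.arange(n),
        box=[box_len, box_len, box_len],
    )
    st.velocities -= st.velocities.mean(axis=0)
    return st


@pytest.fixture(scope="session")
def small_fluid(matrix):
    """Pre-equilibrated 500-bead A fluid at rho ~ 3 (session-cached)."""
    from lamella.engine import RunSchedule, run_simulation

    st = make_fluid(500, 5.5, seed=3)
    p = SimulationParameters(rng_seed=9)
    return run_simulation(st, matrix, p, RunSchedule(n_steps=500, stride=500))[-1]


def two_bead_state(r, box_len=10.0, v1=None, v2=None, species=(0, 0)):
    """Two beads separated by r along x, at box centre."""
    c = box_len / 2
    pos = np.array([[c - r / 2, c, c], [c + r / 2, c, c]])
    vel = np.zeros((2, 3))
    if v1 is not None:
        vel[0] = v1
    if v2 is not None:
        vel[1] = v2
    return SystemState(
        positions=pos,
        velocities=vel,
        species=np.array(species, dtype=np.int8),
        molecule_id=np.array([0, 1]),
        box=[box_len] * 3,
    )
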