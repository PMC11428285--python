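"""In-memory containers for particle configurations and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import SPECIES, SPECIES_INDEX

__all__ = ["SystemState", "Trajectory"]


@dataclass
class SystemState:
    """A full particle configuration.

    Attributes
    ----------
    positions, velocities : (N, 3) float64
        Reduced-unit coordinates and velocities.
    species : (N,) int8
        Species codes in the canonical order ``A B C W O``.
    molecule_id : (N,) int32
        Beads with the same id belong to one molecule; wall beads carry
        id -1.
    frozen : (N,) bool
        Frozen beads (walls) exert forces but never move.
    box : (3,) float64
        Box edge lengths (Lx, Ly, Lz).
    walled_x : bool
        If True the x direction is bounded by repulsive walls and is not
        periodic; y and z are always periodic.
    bonds : (M, 2) int64
        Bonded bead index pairs (harmonic springs).
    time : float
        Reduced simulation time of this snapshot.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    box: np.ndarray
    frozen: np.ndarray | None = None
    walled_x: bool = False
    bonds: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        n = len(self.positions)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        self.molecule_id = np.ascontiguousarray(self.molecule_id, dtype=np.int32)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        self.frozen = np.ascontiguousarray(self.frozen, dtype=np.bool_)
        if self.bonds is None:
            self.bonds = np.zeros((0, 2), dtype=np.int64)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must be (N, 3)")
        for arr, name in ((self.species, "species"), (self.molecule_id, "molecule_id"), (self.frozen, "frozen")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape (N,)")
        self.velocities[self.frozen] = 0.0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_free(self) -> int:
        return int((~self.frozen).sum())

    def species_labels(self) -> np.ndarray:
        """Species as an array of single-letter labels."""
        return np.array(SPECIES, dtype="U1")[self.species]

    def species_mask(self, labels: str | set[str] | list[str]) -> np.ndarray:
        """Boolean mask of beads whose species is in ``labels``."""
        if isinstance(labels, str):
            labels = set(labels)
        codes = [SPECIES_INDEX[s] for s in labels]
        return np.isin(self.species, codes)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule_id=self.molecule_id.copy(),
            box=self.box.copy(),
            frozen=self.frozen.copy(),
            walled_x=self.walled_x,
            bonds=self.bonds.copy(),
            time=self.time,
        )

    def wrap(self) -> None:
        """Wrap coordinates into the primary box in periodic directions."""
        start = 1 if self.walled_x else 0
        for d in range(start, 3):
            self.positions[:, d] %= self.box[d]


@dataclass
class Trajectory:
    """An ordered sequence of snapshots from one run."""

    frames: list[SystemState] = field(default_factory=list)

    def append(self, state: SystemState) -> None:
        self.frames.append(state)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i])
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])
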