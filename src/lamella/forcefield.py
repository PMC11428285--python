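"""Bead species, interaction matrix, molecule templates and run parameters.

The model is a five-species coarse-grained surfactant forcefield:

========  =============================  =========================
label     chemical fragment              role
========  =============================  =========================
``A``     -C3H6-                         hydrophobic tail segment
``B``     -EO2-                          hydrophilic head (ethoxy)
``C``     -OSO3(-)                       hydrophilic head (sulfate)
``W``     4 x H2O                        solvent bead
``O``     -C3H6-                         oil segment
========  =============================  =========================

Surfactants are linear bead-spring chains (``3A2BC`` = A-A-A-B-B-C,
``4ABC`` = A-A-A-A-B-C), oils are O_n chains (n = 1..4) and water is a
single unbonded bead.  No explicit charges are used; the stronger
hydration of the sulfate head is encoded as a low C-W repulsion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPECIES",
    "BeadSpecies",
    "InteractionMatrix",
    "MoleculeTemplate",
    "SimulationParameters",
    "AsymmetricInteractionWarning",
    "build_interaction_matrix",
    "build_molecule_templates",
    "default_interaction_matrix",
    "DEFAULT_REPULSION_TABLE",
]

#: Canonical species ordering; integer codes used throughout the engine.
SPECIES: tuple[str, ...] = ("A", "B", "C", "W", "O")
SPECIES_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

#: Self-repulsion reproducing the compressibility of water at rho = 3
#: with four water molecules per bead.
SELF_REPULSION = 106.5

#: Pairwise maximum repulsion strengths A_ij (reduced energy / r_c).
#: Upper triangle listed once; the matrix is symmetric.  The tail (A) and
#: oil (O) beads are the same chemical fragment, hence identical rows.
DEFAULT_REPULSION_TABLE: dict[tuple[str, str], float] = {
    ("A", "A"): 106.5,
    ("A", "B"): 113.0,
    ("A", "C"): 127.7,
    ("A", "W"): 126.5,
    ("A", "O"): 106.5,
    ("B", "B"): 106.5,
    ("B", "C"): 106.5,
    ("B", "W"): 107.5,
    ("B", "O"): 113.0,
    ("C", "C"): 106.5,
    ("C", "W"): 83.0,
    ("C", "O"): 127.7,
    ("W", "W"): 106.5,
    ("W", "O"): 126.5,
    ("O", "O"): 106.5,
}


class AsymmetricInteractionWarning(UserWarning):
    """Raised when a raw repulsion table lists conflicting A_ij and A_ji."""


class ConfigurationError(ValueError):
    """Invalid forcefield or system configuration."""


@dataclass(frozen=True)
class BeadSpecies:
    """A coarse-grained bead type.

    Parameters
    ----------
    label : str
        One of ``A B C W O``.
    mass : float
        Reduced mass; 1.0 for every species by convention.
    physical_mass_kg : float
        Real mass the bead stands for; metadata for unit mapping only,
        never used by the dynamics.
    """

    label: str
    mass: float = 1.0
    physical_mass_kg: float = 1.2e-25

    def __post_init__(self) -> None:
        if self.label not in SPECIES:
            raise ConfigurationError(f"unknown species label {self.label!r}")
        if self.mass <= 0:
            raise ConfigurationError("bead mass must be positive")


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric matrix of maximum repulsion strengths A_ij.

    Stored densely over the canonical species order; access by label
    pair through :meth:`get`.
    """

    values: np.ndarray  # (5, 5) float64, symmetric, positive

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(SPECIES), len(SPECIES)):
            raise ConfigurationError("interaction matrix must be 5x5")
        if not np.allclose(v, v.T, rtol=0, atol=0):
            raise ConfigurationError("interaction matrix must be symmetric")
        if not (v > 0).all():
            raise ConfigurationError("repulsion strengths must be positive")
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[SPECIES_INDEX[a], SPECIES_INDEX[b]])

    def to_table(self) -> dict[tuple[str, str], float]:
        """Upper-triangle pair -> value mapping (round-trips exactly)."""
        out = {}
        for i, a in enumerate(SPECIES):
            for j in range(i, len(SPECIES)):
                out[(a, SPECIES[j])] = float(self.values[i, j])
        return out


@dataclass(frozen=True)
class MoleculeTemplate:
    """Bead sequence and bond topology of one molecule type.

    Bonds are harmonic springs between consecutive beads; the topology
    is always a simple path (no branching, rings, angles or dihedrals).
    """

    name: str
    bead_sequence: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    spring_constant: float = 75.0
    equilibrium_length: float = 0.45

    def __post_init__(self) -> None:
        n = len(self.bead_sequence)
        for s in self.bead_sequence:
            if s not in SPECIES:
                raise ConfigurationError(f"unknown species {s!r} in {self.name}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ConfigurationError(f"bond ({i},{j}) outside sequence in {self.name}")
        # simple-path check: consecutive-bead bonds only
        expected = tuple((k, k + 1) for k in range(n - 1))
        if tuple(sorted(tuple(sorted(b)) for b in self.bonds)) != expected:
            raise ConfigurationError(f"{self.name}: topology must be a simple chain")

    @property
    def n_beads(self) -> int:
        return len(self.bead_sequence)

    @property
    def is_surfactant(self) -> bool:
        """True for amphiphilic chains (contain both tail and head beads)."""
        s = set(self.bead_sequence)
        return "A" in s and ("B" in s or "C" in s)


@dataclass(frozen=True)
class SimulationParameters:
    """Global run parameters in reduced units.

    The noise amplitude ``sigma`` is derived, not set: the
    fluctuation-dissipation relation ``sigma^2 = 2 gamma k_B T`` ties it
    to the friction so that the pairwise thermostat samples the target
    temperature.
    """

    time_step: float = 0.02
    cutoff: float = 1.0
    kT: float = 1.0
    density: float = 3.0
    gamma: float = 4.5
    wall_strength: float = 106.5
    wall_range: float = 1.0
    rng_seed: int = 0
    lambda_vv: float = 0.5  # velocity prediction weight of the integrator

    def __post_init__(self) -> None:
        for name in ("time_step", "cutoff", "kT", "density", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def sigma(self) -> float:
        """Random-force amplitude from fluctuation-dissipation."""
        return math.sqrt(2.0 * self.gamma * self.kT)


def build_interaction_matrix(
    raw_table: dict[tuple[str, str], float] | None = None,
    *,
    prefer: str = "like-pair",
) -> InteractionMatrix:
    """Build a validated symmetric interaction matrix from a pair table.

    ``raw_table`` maps (species, species) pairs to repulsion strengths;
    each unordered pair must appear at least once.  If both orders are
    present with conflicting values the conflict is resolved and an
    :class:`AsymmetricInteractionWarning` is emitted.  The default
    ``prefer="like-pair"`` rule keeps, for the tail/oil pair (A, O), the
    value equal to the A-A self term — A and O are the same -C3H6-
    fragment so their cross repulsion must equal the like-pair value —
    and for any other conflict keeps the smaller entry.  ``prefer`` may
    also be ``"first"`` or ``"min"``/``"max"`` as an explicit override.
    """
    if raw_table is None:
        raw_table = DEFAULT_REPULSION_TABLE
    values = np.full((len(SPECIES), len(SPECIES)), np.nan)
    for (a, b), v in raw_table.items():
        if a not in SPECIES_INDEX or b not in SPECIES_INDEX:
            raise ConfigurationError(f"unknown species pair ({a}, {b})")
        if v <= 0:
            raise ConfigurationError(f"non-positive repulsion for ({a}, {b}): {v}")
        i, j = SPECIES_INDEX[a], SPECIES_INDEX[b]
        existing = values[j, i] if not np.isnan(values[j, i]) else None
        if existing is not None and existing != v:
            resolved = _resolve_conflict(a, b, existing, float(v), values, prefer)
            warnings.warn(
                f"asymmetric repulsion table: ({b},{a})={existing} vs ({a},{b})={v}; "
                f"using {resolved}",
                AsymmetricInteractionWarning,
                stacklevel=2,
            )
            v = resolved
        values[i, j] = values[j, i] = v
    if np.isnan(values).any():
        missing = [
            (SPECIES[i], SPECIES[j])
            for i in range(len(SPECIES))
            for j in range(i, len(SPECIES))
            if np.isnan(values[i, j])
        ]
        raise ConfigurationError(f"missing species pairs: {missing}")
    return InteractionMatrix(values)


def _resolve_conflict(
    a: str, b: str, first: float, second: float, values: np.ndarray, prefer: str
) -> float:
    if prefer == "first":
        return first
    if prefer == "min":
        return min(first, second)
    if prefer == "max":
        return max(first, second)
    if prefer == "like-pair":
        # If one candidate matches the self term of a chemically identical
        # partner (A vs O), that one wins; otherwise take the smaller.
        pair = {a, b}
        if pair == {"A", "O"}:
            self_term = values[SPECIES_INDEX["A"], SPECIES_INDEX["A"]]
            if not np.isnan(self_term):
                for cand in (first, second):
                    if cand == self_term:
                        return cand
        return min(first, second)
    raise ConfigurationError(f"unknown conflict resolution rule {prefer!r}")


def default_interaction_matrix() -> InteractionMatrix:
    """The study's interaction matrix (A_ii = 106.5 diagonal)."""
    return build_interaction_matrix(DEFAULT_REPULSION_TABLE)


_CANONICAL_SEQUENCES: dict[str, tuple[str, ...]] = {
    "3A2BC": ("A", "A", "A", "B", "B", "C"),
    "4ABC": ("A", "A", "A", "A", "B", "C"),
    "water": ("W",),
    "oil1": ("O",),
    "oil2": ("O", "O"),
    "oil3": ("O", "O", "O"),
    "oil4": ("O", "O", "O", "O"),
}


def build_molecule_templates(
    names: list[str] | tuple[str, ...] | None = None,
    spring_constant: float = 75.0,
    equilibrium_length: float = 0.45,
) -> list[MoleculeTemplate]:
    """Molecule templates for the requested molecule names.

    Supported names: ``3A2BC``, ``4ABC``, ``oil1`` .. ``oil4``,
    ``water``.  All bonds share one spring constant and equilibrium
    length (the forcefield defines a single bonded interaction).
    """
    if names is None:
        names = list(_CANONICAL_SEQUENCES)
    templates = []
    for name in names:
        if name not in _CANONICAL_SEQUENCES:
            raise ConfigurationError(
                f"unknown molecule {name!r}; known: {sorted(_CANONICAL_SEQUENCES)}"
            )
        seq = _CANONICAL_SEQUENCES[name]
        bonds = tuple((i, i + 1) for i in range(len(seq) - 1))
        templates.append(
            MoleculeTemplate(
                name=name,
                bead_sequence=seq,
                bonds=bonds,
                spring_constant=spring_constant,
                equilibrium_length=equilibrium_length,
            )
        )
    return templates


def template_by_name(name: str, **kwargs) -> MoleculeTemplate:
    return build_molecule_templates([name], **kwargs)[0]
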