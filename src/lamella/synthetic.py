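"""Synthetic fixtures with known ground truth.

These generators make every analysis stage testable without running
long simulations: planted micelle fields with known cluster membership,
step concentration fields with closed-form homogeneity, and zone
concentration curves from known (k_trans, D).  They are fixtures, not
physical surrogates — no dynamics is involved and the ground truth is
constructed, never inferred by the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import MicelleSet
from .forcefield import SPECIES_INDEX, template_by_name
from .state import SystemState
from .zonal import ZonalSeries, simulate_zonal_ode

__all__ = [
    "PlantedSpec",
    "gen_planted_micelles",
    "gen_zonal_curves",
    "gen_step_concentration_box",
]


@dataclass
class PlantedSpec:
    """Layout of a planted micelle configuration.

    ``chains_per_cluster`` maps surfactant template name -> chains of
    that type per cluster (an int means that many 3A2BC chains).  Every
    chain's first tail bead is placed within 0.45 r_c of its cluster
    centre, so for any linkage cutoff >= 0.9 r_c all chains of a
    cluster are mutually linked and the ground truth is unambiguous;
    cluster centres keep a pairwise gap > 2 cutoff + 2 radius.
    """

    n_clusters: int
    chains_per_cluster: dict[str, int] | int = 20
    cluster_radius: float = 2.0
    box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    seed: int = 0
    oil_per_cluster: int = 0
    oil_template: str = "oil2"
    n_free_chains: int = 0
    cutoff: float = 1.0

    def __post_init__(self) -> None:
        if isinstance(self.chains_per_cluster, int):
            self.chains_per_cluster = {"3A2BC": self.chains_per_cluster}


def _grid_centers(n: int, box: np.ndarray, min_gap: float, rng) -> np.ndarray:
    """Cluster centres on a jittered grid with guaranteed spacing."""
    per_axis = int(np.ceil(n ** (1 / 3)))
    spacing = box / per_axis
    if (spacing < min_gap).any():
        raise ValueError(
            f"cannot place {n} clusters with gap {min_gap:.2f} in box {box}"
        )
    pts = []
    for ix in range(per_axis):
        for iy in range(per_axis):
            for iz in range(per_axis):
                pts.append(((ix + 0.5) * spacing[0], (iy + 0.5) * spacing[1],
                            (iz + 0.5) * spacing[2]))
    pts = np.array(pts)[:n]
    jitter = rng.uniform(-0.1, 0.1, pts.shape) * min_gap
    return pts + jitter


def _coil_chain(template, start: np.ndarray, center: np.ndarray,
                radius: float, rng) -> np.ndarray:
    """Random coil with bond length r_eq, clamped inside the cluster sphere."""
    r_eq = template.equilibrium_length
    pos = np.empty((template.n_beads, 3))
    pos[0] = start
    for b in range(1, template.n_beads):
        for _ in range(64):
            step = rng.normal(size=3)
            step *= r_eq / np.linalg.norm(step)
            cand = pos[b - 1] + step
            if np.linalg.norm(cand - center) <= radius:
                pos[b] = cand
                break
        else:
            # fold back toward the centre as a last resort
            toward = center - pos[b - 1]
            pos[b] = pos[b - 1] + toward / np.linalg.norm(toward) * r_eq
    return pos


def gen_planted_micelles(spec: PlantedSpec) -> tuple[SystemState, MicelleSet]:
    """Planted micelle field plus its ground-truth cluster structure."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    chain_templates = {
        name: template_by_name(name) for name in spec.chains_per_cluster
    }
    oil_t = template_by_name(spec.oil_template) if spec.oil_per_cluster else None
    chains_each = sum(spec.chains_per_cluster.values())
    min_gap = 2.0 * spec.cutoff + 2.0 * spec.cluster_radius
    n_sites = spec.n_clusters + spec.n_free_chains
    centers = _grid_centers(n_sites, box, min_gap, rng) if n_sites else np.zeros((0, 3))

    positions, species, mol_ids, bonds = [], [], [], []
    truth_clusters: list[np.ndarray] = []
    truth_surf_beads: list[int] = []
    truth_oil_beads: list[int] = []
    truth_oil_mols: list[list[int]] = []
    free_chain_ids: list[int] = []
    mol_id = 0
    offset = 0

    def add_molecule(template, center):
        nonlocal mol_id, offset
        start = center + rng.normal(size=3) * 0.2
        d = np.linalg.norm(start - center)
        if d > 0.45:
            start = center + (start - center) * 0.45 / d
        pos = _coil_chain(template, start, center, spec.cluster_radius, rng)
        positions.append(pos)
        species.append([SPECIES_INDEX[s] for s in template.bead_sequence])
        mol_ids.append(np.full(template.n_beads, mol_id))
        for i, j in template.bonds:
            bonds.append((offset + i, offset + j))
        offset += template.n_beads
        mol_id += 1
        return mol_id - 1

    for c in range(spec.n_clusters):
        members = []
        surf_beads = 0
        for name, count in spec.chains_per_cluster.items():
            t = chain_templates[name]
            for _ in range(count):
                members.append(add_molecule(t, centers[c]))
                surf_beads += t.n_beads
        oil_mols = []
        oil_beads = 0
        for _ in range(spec.oil_per_cluster):
            oil_mols.append(add_molecule(oil_t, centers[c]))
            oil_beads += oil_t.n_beads
        if chains_each > 3:
            truth_clusters.append(np.array(members))
            truth_surf_beads.append(surf_beads)
            truth_oil_beads.append(oil_beads)
            truth_oil_mols.append(oil_mols)
        else:
            free_chain_ids.extend(members)  # too small: free surfactant

    free_template = chain_templates.get("3A2BC") or next(iter(chain_templates.values()))
    for k in range(spec.n_free_chains):
        free_chain_ids.append(
            add_molecule(free_template, centers[spec.n_clusters + k])
        )

    if not positions:
        raise ValueError("empty planted spec")
    state = SystemState(
        positions=np.vstack(positions),
        velocities=np.zeros((offset, 3)),
        species=np.concatenate(species),
        molecule_id=np.concatenate(mol_ids),
        box=box,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
    )
    state.wrap()
    truth = MicelleSet(
        clusters=truth_clusters,
        surfactant_beads=np.array(truth_surf_beads, dtype=int),
        oil_beads=np.array(truth_oil_beads, dtype=int),
        oil_molecules=[np.array(m, dtype=int) for m in truth_oil_mols],
        free_chains=np.array(sorted(free_chain_ids), dtype=int),
        total_chains=spec.n_clusters * chains_each + spec.n_free_chains,
    )
    return state, truth


def gen_zonal_curves(
    k_trans: float,
    d: float,
    noise_sd: float = 0.0,
    n_points: int = 200,
    seed: int = 0,
    c_s0: float = 0.8,
    n_zones: int = 5,
    volume_ratio: float = 1.6,
    t_end: float | None = None,
    time_spacing: str = "log",
) -> ZonalSeries:
    """Forward-model zone curves with optional i.i.d. Gaussian noise.

    Defaults emulate the dissolution start condition: the lamellar zone
    at 80% concentration, water zones empty.  ``t_end`` defaults to
    3/k_trans (the transformation nearly complete).  The default
    ``"log"`` spacing places sample times geometrically between
    t_end/10^4 and t_end so that both the fast zone-filling transient
    (timescale ~1/D) and the slow transformation decay (~1/k_trans) are
    resolved — with well-separated timescales a uniform grid leaves D
    nearly unidentifiable.  ``"linear"`` gives a uniform grid.  Noisy
    values are clipped at zero (concentrations).
    """
    if noise_sd < 0 or k_trans < 0 or d < 0:
        raise ValueError("non-negative inputs required")
    if t_end is None:
        t_end = 3.0 / k_trans if k_trans > 0 else 1.0
    if time_spacing == "log":
        times = np.concatenate([[0.0], np.geomspace(t_end * 1e-4, t_end, n_points - 1)])
    elif time_spacing == "linear":
        times = np.linspace(0.0, t_end, n_points)
    else:
        raise ValueError("time_spacing must be 'log' or 'linear'")
    initial = np.concatenate([[c_s0], np.zeros(n_zones)])
    series = simulate_zonal_ode(k_trans, d, initial, times, volume_ratio)
    if noise_sd > 0:
        # proportional (relative) noise: zone concentrations are
        # bead-count fractions whose error scales with the signal
        rng = np.random.default_rng(seed)
        series = ZonalSeries(
            times=times,
            c_s=np.clip(
                series.c_s * (1.0 + rng.normal(0, noise_sd, len(times))), 0, None
            ),
            c_zones=np.clip(
                series.c_zones * (1.0 + rng.normal(0, noise_sd, series.c_zones.shape)),
                0, None,
            ),
            volume_ratio=volume_ratio,
        )
    return series


def gen_step_concentration_box(
    fraction_left: float,
    box: tuple[float, float, float] = (20.0, 10.0, 10.0),
    seed: int = 0,
    density: float = 3.0,
) -> SystemState:
    """Box with surfactant beads uniform in the left x fraction, water right.

    Single unbonded beads at total density ``density``; the surfactant
    profile is a perfect step, giving closed-form expectations for the
    profile and homogeneity tests (std = c/2 for a half-box step of
    height c).
    """
    if not 0.0 <= fraction_left <= 1.0:
        raise ValueError("fraction_left must be in [0, 1]")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n = int(round(density * box.prod()))
    pos = rng.uniform(0, 1, (n, 3)) * box
    split = fraction_left * box[0]
    species = np.where(pos[:, 0] < split, SPECIES_INDEX["A"], SPECIES_INDEX["W"]).astype(np.int8)
    return SystemState(
        positions=pos,
        velocities=np.zeros((n, 3)),
        species=species,
        molecule_id=np.arange(n, dtype=np.int32),
        box=box,
    )
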