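"""Micelle identification and aggregation-number statistics.

Two surfactant chains belong to the same micelle iff any pair of their
hydrophobic (A) beads lies within a linkage cutoff (default 1 r_c,
minimum image in periodic directions); micelles are the connected
components of that chain graph.  Groups of three or fewer chains count
as free surfactant, not micelles.  Oil molecules carry no linkage of
their own: each is attached to the micelle of its nearest A bead within
the cutoff, or left unassigned.

The per-system size summary reports the mean aggregation number, the
micelle count, the mean micelle volume V (total bead count at unit bead
volume, oil included) and the Stokes-Einstein-style size metric
V^(-1/3), which for a solid sphere is proportional to its diffusion
constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .state import SystemState

__all__ = [
    "MicelleSet",
    "MicelleSummary",
    "find_micelles",
    "micelle_statistics",
    "micelle_composition",
    "size_metric_from_chains",
    "MIN_MICELLE_CHAINS",
]

#: Aggregates with at most this many chains are free surfactant.
MIN_MICELLE_CHAINS = 3


@dataclass
class MicelleSet:
    """Disjoint chain clusters found in one snapshot.

    ``clusters`` holds the molecule ids of the chains of each micelle;
    parallel lists give per-cluster surfactant and oil bead counts and
    the assigned oil molecule ids.  ``free_chains`` are chains in
    groups of <= MIN_MICELLE_CHAINS.
    """

    clusters: list[np.ndarray]
    surfactant_beads: np.ndarray
    oil_beads: np.ndarray
    oil_molecules: list[np.ndarray]
    free_chains: np.ndarray
    total_chains: int

    @property
    def n_micelles(self) -> int:
        return len(self.clusters)

    @property
    def chains_per_micelle(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters])

    def to_frame(self) -> pd.DataFrame:
        """Per-cluster table (id, chains, surfactant/oil beads)."""
        return pd.DataFrame(
            {
                "cluster": np.arange(self.n_micelles),
                "chains": self.chains_per_micelle,
                "surfactant_beads": self.surfactant_beads,
                "oil_beads": self.oil_beads,
            }
        )


@dataclass
class MicelleSummary:
    mean_chains: float
    n_micelles: int
    mean_volume: float
    size_metric: float
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_chains": self.mean_chains,
            "n_micelles": self.n_micelles,
            "mean_volume": self.mean_volume,
            "size_metric": self.size_metric,
        }


def _tree(points: np.ndarray, box: np.ndarray, walled_x: bool) -> cKDTree:
    """KD-tree with periodic y/z (and x unless walled).

    A walled x direction is handled by doubling the x box length passed
    to the tree: all coordinates lie in [0, Lx], so the fictitious wrap
    at 2 Lx can never produce a spurious short pair.
    """
    boxsize = box.astype(float).copy()
    if walled_x:
        boxsize[0] *= 2.0
    pts = np.mod(points, boxsize)
    return cKDTree(pts, boxsize=boxsize)


def find_micelles(state: SystemState, cutoff: float = 1.0) -> MicelleSet:
    """Cluster surfactant chains into micelles by A-bead proximity."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    species = state.species_labels()
    free = ~state.frozen
    is_a = (species == "A") & free
    is_o = (species == "O") & free

    mol = state.molecule_id
    # a chain is any molecule owning at least one A bead that is not pure oil
    a_idx = np.flatnonzero(is_a)
    if len(a_idx) == 0:
        return MicelleSet([], np.zeros(0, int), np.zeros(0, int), [],
                          np.zeros(0, int), 0)
    chain_ids = np.unique(mol[a_idx])
    chain_of = {c: k for k, c in enumerate(chain_ids)}
    n_chains = len(chain_ids)

    tree = _tree(state.positions[a_idx], state.box, state.walled_x)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    ci = np.array([chain_of[m] for m in mol[a_idx]])
    if len(pairs):
        rows = ci[pairs[:, 0]]
        cols = ci[pairs[:, 1]]
        graph = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_chains, n_chains)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n_chains)

    # bead counts per molecule
    mol_beads = pd.Series(mol[free]).value_counts()
    clusters: list[np.ndarray] = []
    surf_beads: list[int] = []
    free_chains: list[int] = []
    label_to_cluster: dict[int, int] = {}
    for lab in np.unique(labels):
        members = chain_ids[labels == lab]
        if len(members) <= MIN_MICELLE_CHAINS:
            free_chains.extend(members.tolist())
            continue
        label_to_cluster[lab] = len(clusters)
        clusters.append(members)
        surf_beads.append(int(mol_beads[members].sum()))

    # oil attachment: nearest A bead within cutoff decides the cluster
    oil_mols: list[list[int]] = [[] for _ in clusters]
    oil_beads = np.zeros(len(clusters), dtype=int)
    o_idx = np.flatnonzero(is_o)
    if len(o_idx) and len(clusters):
        dist, nearest = tree.query(
            np.mod(state.positions[o_idx],
                   _tree_boxsize(state.box, state.walled_x)),
            k=1, distance_upper_bound=cutoff,
        )
        for om in np.unique(mol[o_idx]):
            sel = mol[o_idx] == om
            d = dist[sel]
            if not np.isfinite(d).any():
                continue
            j = int(np.argmin(d))
            a_chain = ci[nearest[sel][j]]
            lab = labels[a_chain]
            if lab not in label_to_cluster:
                continue  # nearest chain is free surfactant
            k = label_to_cluster[lab]
            oil_mols[k].append(int(om))
            oil_beads[k] += int(mol_beads[om])

    return MicelleSet(
        clusters=clusters,
        surfactant_beads=np.array(surf_beads, dtype=int),
        oil_beads=oil_beads,
        oil_molecules=[np.array(m, dtype=int) for m in oil_mols],
        free_chains=np.array(sorted(free_chains), dtype=int),
        total_chains=n_chains,
    )


def _tree_boxsize(box: np.ndarray, walled_x: bool) -> np.ndarray:
    boxsize = box.astype(float).copy()
    if walled_x:
        boxsize[0] *= 2.0
    return boxsize


def micelle_statistics(mset: MicelleSet) -> MicelleSummary:
    """Aggregate size summary; all-zero (flagged) for an empty set."""
    if mset.n_micelles == 0:
        return MicelleSummary(0.0, 0, 0.0, 0.0, empty=True)
    chains = mset.chains_per_micelle
    volumes = mset.surfactant_beads + mset.oil_beads
    mean_v = float(volumes.mean())
    return MicelleSummary(
        mean_chains=float(chains.mean()),
        n_micelles=mset.n_micelles,
        mean_volume=mean_v,
        size_metric=mean_v ** (-1.0 / 3.0),
    )


def size_metric_from_chains(
    mean_chains: float,
    beads_per_chain: int = 6,
    oil_bead_ratio: float = 0.0,
) -> float:
    """Size metric V^(-1/3) from a mean aggregation number.

    The mean micelle volume at unit bead volume is
    ``mean_chains * beads_per_chain * (1 + oil_bead_ratio)``, where
    ``oil_bead_ratio`` is the oil:surfactant bead ratio inside micelles
    (0 for oil-free systems; loading at one part oil to seven parts
    surfactant gives 10/70).  The exponent is exactly 1/3.
    """
    v = mean_chains * beads_per_chain * (1.0 + oil_bead_ratio)
    return v ** (-1.0 / 3.0)


def micelle_composition(mset: MicelleSet, state: SystemState) -> pd.DataFrame:
    """Per-cluster surfactant-type fractions and the mixing index.

    Chains are typed by their bead-count signature (e.g. the two
    six-bead surfactants differ in A-bead count: 3 vs 4).  Returns a
    per-cluster DataFrame of type fractions; ``attrs["mixing_index"]``
    is the std over clusters of the first type's fraction — 0 for
    perfectly even mixing, maximal when clusters are pure.
    """
    species = state.species_labels()
    mol = state.molecule_id
    # chain type = number of A beads in the molecule (distinguishes 3A2BC/4ABC)
    a_count: dict[int, int] = {}
    for c in np.concatenate(mset.clusters) if mset.clusters else []:
        sel = mol == c
        a_count[int(c)] = int(((species == "A") & sel).sum())
    types = sorted(set(a_count.values()))
    rows = []
    for k, members in enumerate(mset.clusters):
        counts = {t: 0 for t in types}
        for c in members:
            counts[a_count[int(c)]] += 1
        total = len(members)
        row = {"cluster": k, "chains": total}
        for t in types:
            row[f"type_{t}A"] = counts[t] / total
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(types) >= 1 and len(df):
        df.attrs["mixing_index"] = float(df[f"type_{types[0]}A"].std(ddof=0))
    else:
        df.attrs["mixing_index"] = 0.0
    return df
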