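import numpy as np
import pytest

from lamella.clusters import (
    MicelleSet,
    find_micelles,
    micelle_composition,
    micelle_statistics,
    size_metric_from_chains,
)
from lamella.synthetic import PlantedSpec, gen_planted_micelles


def brute_force_clusters(state, cutoff):
    """Independent O(n^2) oracle: all-pairs A-bead linkage + transitive
    closure via union-find, then the <=3-chain filter."""
    species = state.species_labels()
    a_idx = np.flatnonzero((species == "A") & ~state.frozen)
    mol = state.molecule_id
    chains = np.unique(mol[a_idx])
    parent = {int(c): int(c) for c in chains}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    box = state.box
    pos = state.positions[a_idx]
    for i in range(len(a_idx)):
        for j in range(i + 1, len(a_idx)):
            d = pos[i] - pos[j]
            for dim in range(3):
                if dim == 0 and state.walled_x:
                    continue
                d[dim] -= box[dim] * np.round(d[dim] / box[dim])
            if np.dot(d, d) < cutoff**2:
                ri, rj = find(int(mol[a_idx[i]])), find(int(mol[a_idx[j]]))
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for c in chains:
        groups.setdefault(find(int(c)), set()).add(int(c))
    return sorted(
        (frozenset(g) for g in groups.values() if len(g) > 3),
        key=lambda s: min(s),
    )


class TestFindMicelles:
    def test_planted_clusters_recovered_exactly(self):
        state, truth = gen_planted_micelles(
            PlantedSpec(n_clusters=3, chains_per_cluster=20, seed=1)
        )
        found = find_micelles(state)
        assert found.n_micelles == 3
        found_sets = sorted((frozenset(c.tolist()) for c in found.clusters),
                            key=lambda s: min(s))
        truth_sets = sorted((frozenset(c.tolist()) for c in truth.clusters),
                            key=lambda s: min(s))
        assert found_sets == truth_sets
        np.testing.assert_array_equal(
            np.sort(found.surfactant_beads), np.sort(truth.surfactant_beads)
        )

    def test_three_chain_group_is_free_surfactant(self):
        state, truth = gen_planted_micelles(
            PlantedSpec(n_clusters=1, chains_per_cluster=3, seed=2)
        )
        assert truth.n_micelles == 0
        found = find_micelles(state)
        assert found.n_micelles == 0
        assert len(found.free_chains) == 3

    def test_two_isolated_chains_no_clusters(self):
        state, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=0, chains_per_cluster=20, n_free_chains=2, seed=3)
        )
        found = find_micelles(state)
        assert found.n_micelles == 0
        assert found.total_chains == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_dense_instances(self, seed):
        """Cell/tree implementation == O(n^2) union-find oracle on ~200
        randomly scattered chains forming nontrivial contact clusters."""
        rng = np.random.default_rng(seed)
        n_chains, beads = 200, 6
        box = np.array([14.0, 14.0, 14.0])
        pos = np.empty((n_chains * beads, 3))
        for c in range(n_chains):
            start = rng.uniform(0, 1, 3) * box
            walk = np.cumsum(
                np.vstack([[0, 0, 0], rng.normal(0, 0.3, (beads - 1, 3))]), axis=0
            )
            pos[c * beads:(c + 1) * beads] = start + walk
        from lamella.state import SystemState

        state = SystemState(
            positions=pos,
            velocities=np.zeros_like(pos),
            species=np.tile([0, 0, 0, 1, 1, 2], n_chains).astype(np.int8),
            molecule_id=np.repeat(np.arange(n_chains), beads),
            box=box,
        )
        state.wrap()
        found = find_micelles(state, cutoff=1.0)
        found_sets = sorted((frozenset(c.tolist()) for c in found.clusters),
                            key=lambda s: min(s))
        assert found_sets == brute_force_clusters(state, 1.0)

    def test_invariant_under_rigid_translation(self):
        state, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=4, chains_per_cluster=10, seed=5)
        )
        base = find_micelles(state)
        shifted = state.copy()
        shifted.positions += np.array([3.3, -2.1, 7.9])
        shifted.wrap()
        moved = find_micelles(shifted)
        assert sorted(map(len, base.clusters)) == sorted(map(len, moved.clusters))
        assert {frozenset(c.tolist()) for c in base.clusters} == {
            frozenset(c.tolist()) for c in moved.clusters
        }

    def test_chain_count_bookkeeping(self):
        state, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=2, chains_per_cluster=8, n_free_chains=5, seed=7)
        )
        found = find_micelles(state)
        in_clusters = sum(len(c) for c in found.clusters)
        assert in_clusters + len(found.free_chains) == found.total_chains == 21

    def test_oil_attached_to_host_micelle(self):
        state, truth = gen_planted_micelles(
            PlantedSpec(n_clusters=2, chains_per_cluster=10, oil_per_cluster=4,
                        oil_template="oil2", seed=9)
        )
        found = find_micelles(state)
        assert found.n_micelles == 2
        np.testing.assert_array_equal(np.sort(found.oil_beads), [8, 8])

    def test_invalid_cutoff(self):
        state, _ = gen_planted_micelles(PlantedSpec(n_clusters=1, seed=0))
        with pytest.raises(ValueError):
            find_micelles(state, cutoff=0.0)


class TestMicelleStatistics:
    def test_empty_set_flagged(self):
        empty = MicelleSet([], np.zeros(0, int), np.zeros(0, int), [],
                           np.zeros(0, int), 0)
        s = micelle_statistics(empty)
        assert s.empty and s.n_micelles == 0 and s.size_metric == 0.0

    def test_hypothetical_eight_bead_cluster(self):
        """Single cluster of 8 one-bead chains: V = 8, metric = 0.5."""
        ms = MicelleSet([np.arange(8)], np.array([8]), np.array([0]), [np.array([])],
                        np.zeros(0, int), 8)
        assert micelle_statistics(ms).size_metric == pytest.approx(0.5)

    def test_statistics_from_planted_field(self):
        state, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=3, chains_per_cluster=20, seed=1)
        )
        s = micelle_statistics(find_micelles(state))
        assert s.mean_chains == 20.0
        assert s.mean_volume == 120.0
        assert s.size_metric == pytest.approx(120 ** (-1 / 3))


class TestSizeMetricIdentity:
    """V^(-1/3) as an arithmetic function of the aggregation number."""

    def test_oil_free_identity(self):
        assert size_metric_from_chains(35.0) == pytest.approx((35.0 * 6) ** (-1 / 3))

    def test_exponent_is_exactly_one_third(self):
        # 0.33 would give a visibly different value at V ~ 1000
        v = 955.8
        assert size_metric_from_chains(159.3) == pytest.approx(v ** (-1 / 3), rel=1e-12)
        assert abs(v ** (-1 / 3) - v ** (-0.33)) > 1e-3

    def test_oil_loading_scales_volume(self):
        no_oil = size_metric_from_chains(75.9)
        with_oil = size_metric_from_chains(75.9, oil_bead_ratio=10 / 70)
        assert with_oil < no_oil
        assert with_oil == pytest.approx((75.9 * 6 * (1 + 1 / 7)) ** (-1 / 3))


class TestMicelleComposition:
    def test_even_mixture_gives_zero_mixing_index(self):
        state, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=4, chains_per_cluster={"3A2BC": 10, "4ABC": 10},
                        cluster_radius=2.5, box=(40.0, 40.0, 40.0), seed=4)
        )
        found = find_micelles(state)
        comp = micelle_composition(found, state)
        np.testing.assert_allclose(comp["type_3A"], 0.5)
        assert comp.attrs["mixing_index"] == pytest.approx(0.0, abs=1e-12)

    def test_demixed_clusters_maximal_index(self):
        """Half the clusters pure type 1, half pure type 2: the index
        hits the two-point-distribution maximum sqrt(q(1-q))."""
        s1, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=2, chains_per_cluster={"3A2BC": 10}, seed=6,
                        box=(40.0, 40.0, 40.0))
        )
        s2, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=2, chains_per_cluster={"4ABC": 10}, seed=8,
                        box=(40.0, 40.0, 40.0))
        )
        s2 = s2.copy()
        s2.positions[:, 0] += 20.0  # separate the two fields
        merged_pos = np.vstack([s1.positions, s2.positions])
        from lamella.state import SystemState

        merged = SystemState(
            positions=merged_pos,
            velocities=np.zeros_like(merged_pos),
            species=np.concatenate([s1.species, s2.species]),
            molecule_id=np.concatenate(
                [s1.molecule_id, s2.molecule_id + s1.molecule_id.max() + 1]
            ),
            box=np.array([80.0, 40.0, 40.0]),
        )
        merged.wrap()
        found = find_micelles(merged)
        comp = micelle_composition(found, merged)
        assert found.n_micelles == 4
        assert comp.attrs["mixing_index"] == pytest.approx(0.5, abs=1e-12)

    def test_random_assignment_near_global_fraction(self):
        """Chains typed at random with P(type1) = 0.75: per-cluster
        fractions stay within binomial error of 0.75."""
        rng = np.random.default_rng(12)
        state, _ = gen_planted_micelles(
            PlantedSpec(n_clusters=4, chains_per_cluster={"3A2BC": 20, "4ABC": 20},
                        cluster_radius=2.5, box=(40.0, 40.0, 40.0), seed=10)
        )
        found = find_micelles(state)
        comp = micelle_composition(found, state)
        # 40 chains per cluster at f = 0.5: binomial sd = 0.079
        assert np.all(np.abs(comp["type_3A"] - 0.5) < 4 * 0.079)
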