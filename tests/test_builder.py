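import numpy as np
import pytest

from lamella.builder import (
    CompositionSpec,
    NotLamellarError,
    build_random_box,
    crop_and_rotate,
    lamellar_order,
    relax_restrained,
    stitch_dissolution_box,
)
from lamella.forcefield import (
    SPECIES_INDEX,
    SimulationParameters,
    build_molecule_templates,
)
from lamella.state import SystemState

from conftest import make_fluid


@pytest.fixture(scope="module")
def templates():
    return {t.name: t for t in build_molecule_templates()}


def planted_lamellae(axis=1, n_layers=4, box_len=10.0, seed=0, n_chains=400,
                     n_water=600):
    """Synthetic lamellar phase: compact surfactant chains centred on
    equally spaced layer planes normal to ``axis``, water between."""
    rng = np.random.default_rng(seed)
    period = box_len / n_layers
    positions, species, mol_ids, bonds = [], [], [], []
    seq = [SPECIES_INDEX[s] for s in "AAABBC"]
    for c in range(n_chains):
        layer = c % n_layers
        center = (layer + 0.5) * period
        base = rng.uniform(0, box_len, 3)
        base[axis] = center + rng.uniform(-0.4, 0.4)
        pos = base + rng.normal(0, 0.15, (6, 3)) * [1, 1, 1]
        positions.append(pos)
        species.append(seq)
        mol_ids.append(np.full(6, c))
        for b in range(5):
            bonds.append((c * 6 + b, c * 6 + b + 1))
    n_surf = n_chains * 6
    wpos = rng.uniform(0, box_len, (n_water, 3))
    wpos[:, axis] = (rng.integers(0, n_layers, n_water) * period
                     + rng.uniform(-0.3, 0.3, n_water)) % box_len
    positions.append(wpos)
    species.append(np.full(n_water, SPECIES_INDEX["W"]))
    mol_ids.append(np.arange(n_chains, n_chains + n_water))
    state = SystemState(
        positions=np.vstack(positions),
        velocities=np.zeros((n_surf + n_water, 3)),
        species=np.concatenate(species),
        molecule_id=np.concatenate(mol_ids),
        box=[box_len] * 3,
        bonds=np.array(bonds, dtype=np.int64),
    )
    state.wrap()
    return state


class TestCompositionSpec:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CompositionSpec({"3A2BC": 0.5, "water": 0.4}, (10, 10, 10))

    def test_study_scale_bead_counts(self, templates):
        """20^3 box at rho = 3: 24,000 beads; 80/20 surfactant/water
        gives 3,200 six-bead chains plus 4,800 water beads."""
        spec = CompositionSpec({"3A2BC": 0.8, "water": 0.2}, (20.0, 20.0, 20.0))
        assert spec.n_beads == 24_000
        counts = spec.molecule_counts(templates)
        assert counts["3A2BC"] == 3_200
        assert counts["water"] == 4_800

    def test_molecule_counts_conserve_beads(self, templates):
        spec = CompositionSpec(
            {"3A2BC": 0.7, "oil3": 0.1, "water": 0.2}, (9.0, 9.0, 9.0)
        )
        counts = spec.molecule_counts(templates)
        total = sum(counts[m] * templates[m].n_beads for m in counts)
        assert total == spec.n_beads

    def test_tiny_fraction_raises(self, templates):
        spec = CompositionSpec(
            {"3A2BC": 0.999, "oil4": 0.001, "water": 0.0}, (4.0, 4.0, 4.0)
        )
        with pytest.raises(ValueError, match="< 1 molecule"):
            spec.molecule_counts(templates)


class TestBuildRandomBox:
    def test_composition_exact_at_molecule_level(self, templates):
        spec = CompositionSpec({"3A2BC": 0.8, "water": 0.2}, (8.0, 8.0, 8.0))
        st = build_random_box(spec, templates, seed=1)
        assert st.n_beads == spec.n_beads
        labels = st.species_labels()
        n_chain_beads = np.isin(labels, ["A", "B", "C"]).sum()
        assert n_chain_beads == spec.molecule_counts(templates)["3A2BC"] * 6
        assert len(st.bonds) == spec.molecule_counts(templates)["3A2BC"] * 5

    def test_pure_water_has_no_bonds(self, templates):
        spec = CompositionSpec({"water": 1.0}, (5.0, 5.0, 5.0))
        st = build_random_box(spec, templates, seed=2)
        assert len(st.bonds) == 0
        assert set(st.species_labels()) == {"W"}

    def test_bond_lengths_start_at_equilibrium(self, templates):
        spec = CompositionSpec({"3A2BC": 0.8, "water": 0.2}, (6.0, 6.0, 6.0))
        st = build_random_box(spec, templates, seed=3)
        d = st.positions[st.bonds[:, 0]] - st.positions[st.bonds[:, 1]]
        d -= st.box * np.round(d / st.box)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 0.45, atol=1e-9)


class TestLamellarDetection:
    def test_planted_normal_detected(self):
        st = planted_lamellae(axis=1, n_layers=4)
        axis, n, amp = lamellar_order(st)
        assert (axis, n) == (1, 4)
        assert amp > 0.5

    def test_isotropic_fluid_not_lamellar(self):
        st = make_fluid(3000, 10.0, seed=5)
        _, _, amp = lamellar_order(st)
        assert amp < 0.1
        with pytest.raises(NotLamellarError, match="not lamellar"):
            crop_and_rotate(st)


class TestCropAndRotate:
    def test_rotates_normal_onto_x(self):
        st = planted_lamellae(axis=1, n_layers=4)
        cropped = crop_and_rotate(st, n_layers=4)
        axis, n, amp = lamellar_order(cropped)
        assert axis == 0
        assert n == 4
        assert amp > 0.5

    def test_crop_keeps_whole_molecules(self):
        st = planted_lamellae(axis=2, n_layers=4)
        cropped = crop_and_rotate(st, n_layers=2)
        assert cropped.box[0] == pytest.approx(5.0)
        # every kept molecule retains its full bead complement
        ids, counts = np.unique(cropped.molecule_id, return_counts=True)
        chain_ids = ids[ids < 400]
        chain_counts = counts[ids < 400]
        assert set(chain_counts) == {6}
        # bonds reference valid beads only
        assert cropped.bonds.min() >= 0
        assert cropped.bonds.max() < cropped.n_beads

    def test_already_aligned_four_layers_identity_up_to_wrap(self):
        st = planted_lamellae(axis=0, n_layers=4)
        cropped = crop_and_rotate(st, n_layers=4)
        assert cropped.n_beads == st.n_beads
        np.testing.assert_allclose(cropped.box, st.box)

    def test_too_many_layers_requested(self):
        st = planted_lamellae(axis=0, n_layers=2)
        with pytest.raises(NotLamellarError, match="periods"):
            crop_and_rotate(st, n_layers=4)


class TestStitch:
    def _slab(self, seed=0):
        """80%-surfactant lamellar stand-in slab at rho = 3, 6 x 6 x 6."""
        st = planted_lamellae(axis=0, n_layers=2, box_len=6.0, seed=seed,
                              n_chains=86, n_water=132)
        return st

    def test_water_column_length_from_end_concentration(self, matrix):
        slab = self._slab()
        params = SimulationParameters(rng_seed=0)
        stitched, span = stitch_dissolution_box(
            slab, matrix, params, seed=1, end_concentration=0.2,
            water_equil_steps=0,
        )
        dissolving = int(slab.species_mask({"A", "B", "C", "O"}).sum())
        expected_len = dissolving / (3.0 * 0.2 * 36.0)
        assert stitched.box[0] == pytest.approx(expected_len)
        assert span == (0.0, 6.0)
        assert stitched.walled_x

    def test_bead_budget_and_walls(self, matrix):
        slab = self._slab()
        params = SimulationParameters(rng_seed=0)
        stitched, _ = stitch_dissolution_box(
            slab, matrix, params, seed=1, water_equil_steps=0
        )
        free = ~stitched.frozen
        rho_eff = free.sum() / np.prod(stitched.box)
        assert rho_eff == pytest.approx(3.0, rel=0.02)
        # frozen W-bead wall rows at both ends
        wall_x = stitched.positions[stitched.frozen, 0]
        assert (wall_x < 1.0).sum() > 0 and (wall_x > stitched.box[0] - 1.0).sum() > 0
        assert set(stitched.species_labels()[stitched.frozen]) == {"W"}
        assert np.all(stitched.molecule_id[stitched.frozen] == -1)

    def test_conservation_through_crop_stitch_relax(self, matrix):
        st = planted_lamellae(axis=0, n_layers=2, box_len=6.0, n_chains=86,
                              n_water=132)
        params = SimulationParameters(rng_seed=1)
        stitched, _ = stitch_dissolution_box(
            st, matrix, params, seed=2, water_equil_steps=0
        )
        n_free_before = int((~stitched.frozen).sum())
        surf_before = int(stitched.species_mask({"A", "B", "C"}).sum())
        relaxed = relax_restrained(stitched, matrix, params, n_steps=200)
        assert int((~relaxed.frozen).sum()) == n_free_before
        assert int(relaxed.species_mask({"A", "B", "C"}).sum()) == surf_before


class TestRelax:
    def test_c_beads_stay_near_anchors(self, matrix):
        st = planted_lamellae(axis=0, n_layers=2, box_len=6.0, n_chains=86,
                              n_water=132)
        params = SimulationParameters(rng_seed=3)
        stitched, _ = stitch_dissolution_box(
            st, matrix, params, seed=3, water_equil_steps=100
        )
        anchors = stitched.positions[stitched.species_mask({"C"}) & ~stitched.frozen].copy()
        relaxed = relax_restrained(stitched, matrix, params, n_steps=400)
        c_after = relaxed.positions[relaxed.species_mask({"C"}) & ~relaxed.frozen]
        d = c_after - anchors
        for dim in (1, 2):
            d[:, dim] -= relaxed.box[dim] * np.round(d[:, dim] / relaxed.box[dim])
        assert np.linalg.norm(d, axis=1).mean() < 0.45

    def test_pure_water_box_just_thermalises(self, matrix):
        st = make_fluid(500, 5.5, seed=8)
        st.walled_x = True
        params = SimulationParameters(rng_seed=4)
        relaxed = relax_restrained(st, matrix, params, n_steps=100)
        assert relaxed.n_beads == st.n_beads
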