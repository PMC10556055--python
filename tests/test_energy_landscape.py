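import numpy as np
import pytest

from clawpore.energy import EnergyParams, OverlapError, pair_energy
from clawpore.panel_landscape import (
    PlacementError,
    compute_landscape,
    interaction_energy,
    place_at_contact,
    stable_states,
    window_stats,
)
from clawpore.synthetic_data import make_ring_stack

from conftest import bead_model, brute_force_energy


class TestEnergyKernel:
    def test_closed_form_coulomb(self):
        """Unit charges 10 A apart with dielectric 15: -9.2624 kJ/mol."""
        params = EnergyParams(sigma=0.5, epsilon=2.0, eps_r=15.0, cutoff=12.0)
        _, e_coul, _ = pair_energy([[0, 0, 0]], [1.0], [[10, 0, 0]], [-1.0], params)
        assert e_coul == pytest.approx(-9.2624, abs=5e-5)
        assert e_coul == pytest.approx(-138.935458 / (15.0 * 1.0), rel=1e-12)

    def test_lj_root_at_sigma(self):
        params = EnergyParams(sigma=4.7)
        e_lj, _, _ = pair_energy([[0, 0, 0]], [0.0], [[4.7, 0, 0]], [0.0], params)
        assert e_lj == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        from conftest import random_bead_pair

        pos_a, q_a, pos_b, q_b = random_bead_pair(12)
        params = EnergyParams()
        got = pair_energy(pos_a, q_a, pos_b, q_b, params)
        want = brute_force_energy(pos_a, q_a, pos_b, q_b, params)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_beyond_cutoff_is_zero(self):
        assert pair_energy([[0, 0, 0]], [1.0], [[50, 0, 0]], [1.0]) == (0, 0, 0)

    def test_overlap_guard(self):
        with pytest.raises(OverlapError):
            pair_energy([[0, 0, 0]], [0.0], [[0.05, 0, 0]], [0.0])

    def test_doubling_dielectric_halves_coulomb(self):
        pos_a, pos_b = [[0, 0, 0]], [[6.0, 0, 0]]
        e1 = pair_energy(pos_a, [1.0], pos_b, [1.0], EnergyParams(eps_r=15.0))
        e2 = pair_energy(pos_a, [1.0], pos_b, [1.0], EnergyParams(eps_r=30.0))
        assert e2[1] == pytest.approx(e1[1] / 2.0, rel=1e-12)
        assert e2[0] == pytest.approx(e1[0], rel=1e-12)


class TestContactPlacement:
    def test_touching_single_beads(self):
        a = bead_model([[0, 0, 0]], radii=[2.0])
        b = bead_model([[0, 0, 0]], radii=[2.0])
        pose = place_at_contact(a, b, 0.0, 0.0, contact_gap=0.0)
        assert pose.center_distance == pytest.approx(4.0, abs=1e-9)

    def test_contact_gap_respected_on_toys(self, monomer_a, monomer_b):
        pose = place_at_contact(monomer_a, monomer_b, 40.0, 255.0, contact_gap=0.5)
        a, b = pose.apply(monomer_a, monomer_b)
        diff = a.positions[:, None] - b.positions[None, :]
        sep = np.sqrt((diff**2).sum(-1)) - a.radii[:, None] - b.radii[None, :]
        assert sep.min() == pytest.approx(0.5, abs=0.01)

    def test_matches_translation_scan_oracle(self, monomer_a, monomer_b):
        pose = place_at_contact(monomer_a, monomer_b, 120.0, 10.0, contact_gap=0.5)
        # brute-force scan of B along +x at 0.01 A
        from clawpore.panel_landscape import _rot_z

        pa = monomer_a.positions @ _rot_z(120.0).T
        pb = monomer_b.positions @ _rot_z(10.0).T
        best = None
        for d in np.arange(1.0, 30.0, 0.01):
            diff = pa[:, None] - (pb + [d, 0, 0])[None, :]
            sep = np.sqrt((diff**2).sum(-1)) - monomer_a.radii[:, None] \
                - monomer_b.radii[None, :]
            if sep.min() >= 0.5:
                best = d
                break
        assert pose.center_distance == pytest.approx(best, abs=0.02)

    def test_global_rotation_invariance(self, monomer_a, monomer_b):
        """The energy of a finished pose is unchanged by a global rigid motion."""
        pose = place_at_contact(monomer_a, monomer_b, 15.0, 300.0)
        a, b = pose.apply(monomer_a, monomer_b)
        e_ref = pair_energy(a.positions, a.charges, b.positions, b.charges)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [31.0, 12.0, -77.0], degrees=True).as_matrix()
        a2 = a.transformed(rotation=rot, translation=[3.0, -4.0, 9.0])
        b2 = b.transformed(rotation=rot, translation=[3.0, -4.0, 9.0])
        e_rot = pair_energy(a2.positions, a2.charges, b2.positions, b2.charges)
        np.testing.assert_allclose(e_rot, e_ref, atol=1e-9)

    def test_no_lateral_overlap_errors(self):
        a = bead_model([[0, 0, 0]], radii=[1.0])
        b = bead_model([[0, 50, 0]], radii=[1.0])
        with pytest.raises(PlacementError):
            place_at_contact(a, b, 0.0, 0.0)


class TestLandscape:
    def test_grid_completeness_and_cell_lookup(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=30.0)
        assert landscape.e_total.shape == (12, 12)
        assert np.all(np.isfinite(landscape.e_total))
        # periodicity of the lookup
        assert landscape.energy_at(390.0, -330.0) == landscape.energy_at(30.0, 30.0)

    def test_vectorized_grid_matches_scalar_path(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=45.0)
        for t1, t2 in [(0, 0), (45, 270), (315, 90)]:
            pose = place_at_contact(monomer_a, monomer_b, t1, t2)
            _, _, e = interaction_energy(monomer_a, monomer_b, pose)
            assert landscape.energy_at(t1, t2) == pytest.approx(e, abs=1e-9)
            i, j = landscape._index(t1), landscape._index(t2)
            assert landscape.center_distances[i, j] == pytest.approx(
                pose.center_distance, abs=1e-9
            )

    def test_azimuthally_symmetric_models_give_flat_landscape(self):
        ring_a, _ = make_ring_stack([5.0], beads_per_ring=36, bead_radius=1.5)
        ring_b, _ = make_ring_stack([5.0], beads_per_ring=36, bead_radius=1.5)
        landscape = compute_landscape(ring_a, ring_b, increment=10.0)
        spread = landscape.e_total.max() - landscape.e_total.min()
        assert spread < 1e-6

    def test_homodimer_exchange_symmetry(self, monomer_a):
        """Swapping the monomers' roles mirrors the landscape: exchanging the
        two copies and viewing the pair from the other side maps cell
        (t1, t2) to (t2 + 180, t1 + 180)."""
        landscape = compute_landscape(monomer_a, monomer_a, increment=30.0)
        for t1 in landscape.thetas[::3]:
            for t2 in landscape.thetas[::3]:
                assert landscape.energy_at(t1, t2) == pytest.approx(
                    landscape.energy_at(t2 + 180.0, t1 + 180.0), abs=1e-6
                )

    def test_increment_must_divide_360(self, monomer_a, monomer_b):
        with pytest.raises(ValueError):
            compute_landscape(monomer_a, monomer_b, increment=7.0)


class TestStableStates:
    def test_sort_and_slice_oracle_small_grid(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=36.0)
        states = stable_states(landscape, percentile=10.0)
        energies = np.sort(landscape.e_total.ravel())
        k = len(energies) // 10
        assert states.count == k
        np.testing.assert_allclose(states.states[:, 2], energies[:k], atol=1e-12)

    def test_full_percentile_returns_all(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=45.0)
        assert stable_states(landscape, percentile=100.0).count == 64

    def test_nesting_in_percentile(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=30.0)
        small = stable_states(landscape, percentile=5.0)
        large = stable_states(landscape, percentile=20.0)
        small_set = {tuple(s[:2]) for s in small.states}
        large_set = {tuple(s[:2]) for s in large.states}
        assert small_set <= large_set


class TestWindowStats:
    def test_mean_matches_direct_summation(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=5.0)
        ws = window_stats(landscape, center=270.0, halfwidth=10.0)
        # direct summation oracle over the half-open window
        members = []
        for i, t1 in enumerate(landscape.thetas):
            for j, t2 in enumerate(landscape.thetas):
                if 260.0 <= t1 < 280.0 and 260.0 <= t2 < 280.0:
                    members.append(landscape.e_total[i, j])
        assert ws.count == len(members) == 16
        assert ws.mean == pytest.approx(np.mean(members), abs=1e-12)

    def test_closed_window_has_one_more_value_per_axis(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=5.0)
        closed = window_stats(landscape, closed=True)
        assert closed.count == 25  # (4+1)^2 at 5 degrees

    def test_constant_landscape_zero_sd(self):
        ring_a, _ = make_ring_stack([5.0], beads_per_ring=36, bead_radius=1.5)
        landscape = compute_landscape(ring_a, ring_a, increment=15.0)
        ws = window_stats(landscape)
        assert ws.sd == pytest.approx(0.0, abs=1e-9)

    def test_halfwidth_bound(self, monomer_a, monomer_b):
        landscape = compute_landscape(monomer_a, monomer_b, increment=45.0)
        with pytest.raises(ValueError):
            window_stats(landscape, halfwidth=180.0)
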