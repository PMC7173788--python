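import numpy as np
import pytest

from mdflow.datamodel import Box
from mdflow.graph_engine import execute_trajectory
from mdflow.hydrate_mcg import (
    build_mcg_graph,
    canonical_ring,
    classified_count,
    filter_guests,
    filter_waters,
    find_links,
    hbonds_filtered,
    reconnect_water,
    register_hydrate,
)

from oracles import enumerate_cycles

OPEN_BOX = Box.open((100, 100, 100))


class TestFilterGuests:
    def test_pair_inside_default_cutoff(self):
        pos = np.array([[0, 0, 0], [8.0, 0, 0]])
        pairs = filter_guests(pos, [0, 1], OPEN_BOX)
        assert pairs.tolist() == [[0, 1]]

    def test_pair_beyond_cutoff_excluded(self):
        pos = np.array([[0, 0, 0], [9.5, 0, 0]])
        assert len(filter_guests(pos, [0, 1], OPEN_BOX)) == 0

    def test_k_close_guests_give_all_pairs(self):
        pos = np.random.default_rng(0).uniform(0, 3, size=(5, 3))
        pairs = filter_guests(pos, np.arange(5), OPEN_BOX)
        assert len(pairs) == 10

    def test_periodic_pair_across_boundary(self):
        box = Box.cubic(30.0)
        pos = np.array([[1.0, 15, 15], [29.0, 15, 15]])
        assert len(filter_guests(pos, [0, 1], box)) == 1


class TestFilterWaters:
    def setup_method(self):
        self.guests = np.array([[0, 0, -4.0], [0, 0, 4.0]])
        self.pairs = np.array([[0, 1]])

    def _run(self, waters, **kw):
        pos = np.vstack([self.guests, np.atleast_2d(waters)])
        return filter_waters(self.pairs, pos, np.arange(2, len(pos)),
                             OPEN_BOX, **kw)

    def test_midpoint_water_is_coordinated(self):
        cw = self._run([0, 0, 0])
        assert cw.selected.tolist() == [2]

    def test_on_axis_beyond_guest_is_not(self):
        cw = self._run([0, 0, 6.0])
        assert cw.selected.size == 0

    @pytest.mark.parametrize("angle, inside", [(44.0, True), (46.0, False)])
    def test_threshold_straddle(self, angle, inside):
        # place the water on the midplane at equal distance from both guests,
        # at the requested half-angle seen from each guest
        r = 4.0 * np.tan(np.deg2rad(angle))
        cw = self._run([r, 0, 0.0])
        assert (cw.selected.size == 1) is inside

    def test_degenerate_pair_skipped_with_warning(self):
        pos = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.warns(UserWarning):
            cw = filter_waters([[0, 1]], pos, [2], OPEN_BOX)
        assert cw.selected.size == 0


def water_row(o, h1, h2):
    return [np.asarray(o, float), np.asarray(h1, float), np.asarray(h2, float)]


class TestHbonds:
    def _table(self, n_water):
        from mdflow.fixtures import _water_table

        return _water_table(n_water, first_mol=1)

    def test_ideal_linear_bond_accepted(self):
        atoms = self._table(2)
        pos = np.vstack(
            water_row([0, 0, 0], [0.9572, 0, 0], [-0.24, 0.93, 0])
            + water_row([2.8, 0, 0], [3.7, 0.3, 0], [2.5, -0.9, 0])
        )
        hb = hbonds_filtered(atoms, pos, OPEN_BOX, [0, 3])
        assert hb.tolist() == [[0, 1, 3]]

    def test_distance_cut_rejects(self):
        atoms = self._table(2)
        pos = np.vstack(
            water_row([0, 0, 0], [0.9572, 0, 0], [-0.24, 0.93, 0])
            + water_row([3.6, 0, 0], [4.5, 0.3, 0], [3.3, -0.9, 0])
        )
        assert len(hbonds_filtered(atoms, pos, OPEN_BOX, [0, 3])) == 0

    def test_donor_angle_cut_rejects(self):
        atoms = self._table(2)
        a35 = np.deg2rad(35.0)
        h1 = 0.9572 * np.array([np.cos(a35), np.sin(a35), 0.0])
        pos = np.vstack(
            water_row([0, 0, 0], h1, [-0.24, -0.93, 0])
            + water_row([2.8, 0, 0], [3.7, 0.3, 0], [3.0, -0.9, 0])
        )
        assert len(hbonds_filtered(atoms, pos, OPEN_BOX, [0, 3])) == 0

    def test_unselected_oxygen_excluded(self):
        atoms = self._table(2)
        pos = np.vstack(
            water_row([0, 0, 0], [0.9572, 0, 0], [-0.24, 0.93, 0])
            + water_row([2.8, 0, 0], [3.7, 0.3, 0], [2.5, -0.9, 0])
        )
        assert len(hbonds_filtered(atoms, pos, OPEN_BOX, [0])) == 0

    def test_roles_are_antisymmetric_per_hydrogen(self, dodecahedron):
        fr = dodecahedron.frames[0]
        oxy = np.flatnonzero(dodecahedron.atoms.element == "O")
        hb = hbonds_filtered(dodecahedron.atoms, fr.positions, fr.box, oxy)
        seen = {(d, h, a) for d, h, a in hb.tolist()}
        assert not any((a, h, d) in seen for d, h, a in seen)


class TestRings:
    def test_single_pentagon(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
        assert find_links(edges, 5) == [(0, 1, 2, 3, 4)]

    def test_hexagon_has_no_pentagon(self):
        edges = [(i, (i + 1) % 6) for i in range(6)]
        assert find_links(edges, 5) == []

    def test_canonical_form_is_rotation_reflection_invariant(self):
        assert canonical_ring([3, 2, 1, 0, 4]) == canonical_ring([0, 1, 2, 3, 4])
        assert canonical_ring([2, 3, 4, 0, 1]) == (0, 1, 2, 3, 4)

    @pytest.mark.parametrize("n", [4, 5, 6])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        nodes = int(rng.integers(8, 25))
        edges = set()
        for _ in range(int(2.0 * nodes)):
            i, j = rng.integers(0, nodes, size=2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        edges = sorted(edges)
        got = find_links(edges, n)
        want = enumerate_cycles(edges, n)
        got_edge_sets = {
            frozenset(
                (min(a, b), max(a, b))
                for a, b in zip(r, r[1:] + r[:1])
            )
            for r in got
        }
        assert got_edge_sets == want

    def test_dodecahedron_faces(self, dodecahedron):
        fr = dodecahedron.frames[0]
        oxy = np.flatnonzero(dodecahedron.atoms.element == "O")
        hb = hbonds_filtered(dodecahedron.atoms, fr.positions, fr.box, oxy)
        edges = reconnect_water(hb)
        assert len(edges) == 30
        assert len(find_links(edges, 5)) == 12
        assert len(find_links(edges, 6)) == 0


class TestReconnect:
    def test_double_hbond_dedupes_to_one_edge(self):
        hb = [(5, 6, 2), (2, 3, 5)]
        assert reconnect_water(hb).tolist() == [[2, 5]]

    def test_empty_input(self):
        assert len(reconnect_water(np.zeros((0, 3), dtype=int))) == 0


class TestRegisterHydrate:
    def test_no_rings_means_no_labels(self):
        from mdflow.hydrate_mcg import CoordinatedWaters

        cw = CoordinatedWaters(np.array([[0, 1]]), [np.array([2, 3])],
                               np.array([2, 3]))
        labels, count = register_hydrate([[0, 1]], cw, [], n_atoms=6)
        assert count == 0 and labels.sum() == 0

    def test_two_disjoint_pairs_get_labels_one_and_two(self):
        from mdflow.hydrate_mcg import CoordinatedWaters

        pairs = np.array([[0, 1], [2, 3]])
        ring_a = (4, 5, 6, 7, 8)
        ring_b = (9, 10, 11, 12, 13)
        cw = CoordinatedWaters(
            pairs,
            [np.array(ring_a), np.array(ring_b)],
            np.arange(4, 14),
        )
        labels, count = register_hydrate(pairs, cw, [ring_a, ring_b], n_atoms=14)
        assert count == 2
        assert labels[0] == labels[1] == 1 and labels[2] == labels[3] == 2
        assert all(labels[list(ring_a)] == 1) and all(labels[list(ring_b)] == 2)

    def test_pairs_sharing_a_guest_share_a_label(self):
        from mdflow.hydrate_mcg import CoordinatedWaters

        pairs = np.array([[0, 1], [1, 2]])
        ring = (3, 4, 5, 6, 7)
        cw = CoordinatedWaters(pairs, [np.array(ring), np.array(ring)],
                               np.array(ring))
        labels, count = register_hydrate(pairs, cw, [ring], n_atoms=8)
        assert count == 2
        assert labels[0] == labels[1] == labels[2] == 1


class TestClassifiedCount:
    def test_counts_molecules_not_atoms(self):
        labels = [1, 1, 0, 1]
        mols = [7, 7, 8, 9]
        assert classified_count(labels, mols) == 2

    def test_zero_labels(self):
        assert classified_count(np.zeros(5)) == 0

    def test_monotone_under_label_additions(self):
        labels = np.zeros(6)
        mols = np.arange(6)
        counts = []
        for i in range(6):
            labels[i] = 1
            counts.append(classified_count(labels, mols))
        assert counts == sorted(counts)


class TestEndToEnd:
    def test_cage_pair_pipeline(self, cage_pair):
        g = build_mcg_graph(guest_sel="resname=MET")
        res = execute_trajectory(g, cage_pair)
        assert res.value(0, "g_register", "mcg_count") == 1
        labels = res.value(0, "g_register", "labels")
        oxygens = np.flatnonzero(cage_pair.atoms.element == "O")
        np.testing.assert_array_equal(np.flatnonzero(labels),
                                      np.concatenate(([0, 1], oxygens)))
        assert res.value(0, "k_count", "count") == 7

    def test_rigid_motion_invariance(self):
        from mdflow.fixtures import gen_cage_pair, _random_rotation

        rot = _random_rotation(np.random.default_rng(4))
        moved = gen_cage_pair(rotation=rot, translation=[3.0, -2.0, 7.0])
        g = build_mcg_graph(guest_sel="resname=MET")
        res = execute_trajectory(g, moved)
        assert res.value(0, "g_register", "mcg_count") == 1
        assert res.value(0, "k_count", "count") == 7

    def test_bulk_water_is_negative(self, bulk_water):
        g = build_mcg_graph(guest_sel="resname=MET")
        res = execute_trajectory(g, bulk_water)
        assert res.value(0, "g_register", "mcg_count") == 0
        assert res.value(0, "k_count", "count") == 0

    def test_separated_guests_yield_nothing(self):
        from mdflow.fixtures import gen_cage_pair

        traj = gen_cage_pair(guest_sep=9.5, ring_radius=2.3)
        g = build_mcg_graph(guest_sel="resname=MET")
        res = execute_trajectory(g, traj)
        assert len(res.value(0, "b_guests", "pairs")) == 0
        assert res.value(0, "g_register", "mcg_count") == 0

    def test_oo_edges_feed_extra_bonds_state(self, cage_pair):
        g = build_mcg_graph(guest_sel="resname=MET")
        res = execute_trajectory(g, cage_pair)
        bonds = res.viz_history[0].extra_bonds
        assert len(bonds) == 5  # the pentagonal O-O ring
        oxygens = set(np.flatnonzero(cage_pair.atoms.element == "O").tolist())
        assert all(i in oxygens and j in oxygens for i, j in bonds)
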