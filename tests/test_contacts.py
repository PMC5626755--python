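"""Native contacts, Q/Qs, contact counts, occupancy and SASA."""

import numpy as np
import pytest

from stardynet import contacts, trajio
from stardynet.trajio import AtomSelection, Trajectory


def sel(n):
    return AtomSelection("all", np.arange(n))


class TestNativeContacts:
    def test_all_pairs_within_exclusion(self, structure_factory):
        s = structure_factory([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        native = contacts.native_contacts(s, sel(3), cutoff=8.0, exclusion=2)
        assert len(native) == 0

    def test_single_qualifying_pair(self, structure_factory):
        s = structure_factory([[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0]])
        native = contacts.native_contacts(s, sel(4), cutoff=8.0, exclusion=2)
        assert len(native) == 1
        assert tuple(native.pairs[0]) == (0, 3)
        assert native.native_distances[0] == pytest.approx(6.0)

    def test_boundary_exactly_at_cutoff_included(self, structure_factory):
        s = structure_factory([[0, 0, 0], [8.0, 0, 0]],
                              resseqs=[1, 10])
        native = contacts.native_contacts(s, sel(2), cutoff=8.0, exclusion=2)
        assert len(native) == 1

    def test_cross_chain_pairs_not_excluded(self, structure_factory):
        # same residue_seq on different chains is a valid contact pair
        s = structure_factory([[0, 0, 0], [3, 0, 0]], resseqs=[5, 5],
                              chains=["A", "B"])
        native = contacts.native_contacts(s, sel(2), cutoff=8.0, exclusion=2)
        assert len(native) == 1


class TestQSeries:
    def make_native(self, structure_factory, coords, resseqs=None):
        s = structure_factory(coords, resseqs=resseqs)
        native = contacts.native_contacts(s, sel(len(coords)), cutoff=8.0,
                                          exclusion=2)
        return s, native

    def test_reference_frame_is_one(self, structure_factory):
        rng = np.random.default_rng(0)
        s, native = self.make_native(structure_factory,
                                     rng.uniform(0, 8, (8, 3)))
        traj = Trajectory(s, s.coords[None])
        q, qs = contacts.q_series(traj, native)
        assert q[0] == 1.0
        assert qs[0] == pytest.approx(1.0, abs=1e-12)

    def test_stretched_to_three_cutoffs(self, structure_factory):
        s, native = self.make_native(
            structure_factory, [[0, 0, 0], [0, 4, 0], [4, 0, 0], [4, 4, 0]])
        traj = Trajectory(s, (3.0 * s.coords)[None])
        q, qs = contacts.q_series(traj, native)
        assert q[0] == 0.0
        assert qs[0] < 0.01

    def test_sigma_displacement_gives_exp_half(self, structure_factory):
        s = structure_factory([[0, 0, 0], [6, 0, 0]], resseqs=[1, 10])
        native = contacts.native_contacts(s, sel(2), cutoff=8.0, exclusion=2)
        sigma = contacts.qs_sigma(9)  # (1+9)^0.15
        frame = s.coords.copy()
        frame[1, 0] += float(sigma)
        traj = Trajectory(s, frame[None])
        _, qs = contacts.q_series(traj, native)
        assert qs[0] == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_bounds(self, structure_factory, toy_complex):
        ca = trajio.select(toy_complex, "name CA")
        native = contacts.native_contacts(toy_complex, ca)
        rng = np.random.default_rng(1)
        frames = toy_complex.coords[None] + 0.5 * rng.standard_normal(
            (5, toy_complex.n_atoms, 3))
        q, qs = contacts.q_series(Trajectory(toy_complex, frames), native)
        assert np.all((q >= 0) & (q <= 1))
        assert np.all((qs >= 0) & (qs <= 1))


class TestContactCounts:
    def test_pair_within_cutoff(self, structure_factory):
        s = structure_factory([[0, 0, 0], [5, 0, 0]], resseqs=[1, 10])
        traj = Trajectory(s, np.repeat(s.coords[None], 3, axis=0))
        counts = contacts.contact_count_series(
            traj, sel(2), sel(2), cutoff=6.0, exclusion=2)
        np.testing.assert_array_equal(counts, [1, 1, 1])

    def test_pair_outside_cutoff(self, structure_factory):
        s = structure_factory([[0, 0, 0], [6.5, 0, 0]], resseqs=[1, 10])
        traj = Trajectory(s, s.coords[None])
        counts = contacts.contact_count_series(
            traj, sel(2), sel(2), cutoff=6.0, exclusion=2)
        assert counts[0] == 0

    def test_matches_brute_force(self, structure_factory):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 12, (15, 3))
        s = structure_factory(coords, resseqs=list(range(1, 16)))
        frames = coords[None] + 0.3 * rng.standard_normal((10, 15, 3))
        traj = Trajectory(s, frames)
        a = AtomSelection("a", np.arange(8))
        b = AtomSelection("b", np.arange(4, 15))
        counts = contacts.contact_count_series(traj, a, b, cutoff=6.0,
                                               exclusion=2)
        for f in range(10):
            brute = 0
            seen = set()
            for i in a.resolved_ids:
                for j in b.resolved_ids:
                    if i == j or (min(i, j), max(i, j)) in seen:
                        continue
                    seen.add((min(i, j), max(i, j)))
                    if abs(i - j) <= 2:  # resseq == index + 1, same chain
                        continue
                    if np.linalg.norm(frames[f, i] - frames[f, j]) <= 6.0:
                        brute += 1
            assert counts[f] == brute

    def test_symmetric_in_selection_order(self, structure_factory):
        rng = np.random.default_rng(3)
        s = structure_factory(rng.uniform(0, 10, (10, 3)))
        traj = Trajectory(s, s.coords[None])
        a = AtomSelection("a", np.arange(6))
        b = AtomSelection("b", np.arange(4, 10))
        ab = contacts.contact_count_series(traj, a, b, 6.0, 2)
        ba = contacts.contact_count_series(traj, b, a, 6.0, 2)
        np.testing.assert_array_equal(ab, ba)

    def test_monotone_in_cutoff(self, structure_factory):
        rng = np.random.default_rng(4)
        s = structure_factory(rng.uniform(0, 10, (12, 3)))
        traj = Trajectory(s, s.coords[None])
        c6 = contacts.contact_count_series(traj, sel(12), sel(12), 6.0, 2)
        c12 = contacts.contact_count_series(traj, sel(12), sel(12), 12.0, 2)
        assert np.all(c12 >= c6)


class TestOccupancy:
    def test_always_present_flagged(self, structure_factory):
        s = structure_factory([[0, 0, 0], [3, 0, 0]])
        traj = Trajectory(s, np.repeat(s.coords[None], 4, axis=0))
        table = contacts.interface_occupancy(
            traj, [("pair", [0], [1])], cutoff=4.5)
        assert table.occupancy[0] == 1.0
        assert table.flagged[0]

    def test_threshold_boundary_closed(self, structure_factory):
        s = structure_factory([[0, 0, 0], [3, 0, 0]])
        frames = np.repeat(s.coords[None], 8, axis=0)
        frames[6:, 1, 0] = 50.0  # absent in 2 of 8 frames
        traj = Trajectory(s, frames)
        table = contacts.interface_occupancy(
            traj, [("pair", [0], [1])], cutoff=4.5, threshold=0.75)
        assert table.occupancy[0] == pytest.approx(0.75)
        assert table.flagged[0]

    def test_matches_brute_force_on_toy(self, toy_ensemble):
        traj = toy_ensemble
        top = traj.topology
        rna = np.flatnonzero(
            np.asarray(top.chain_ids, dtype=object) == "B")[:4]
        prot = np.flatnonzero(
            np.asarray(top.chain_ids, dtype=object) == "A")[:10]
        table = contacts.interface_occupancy(
            traj, [("x", rna, prot)], cutoff=4.5)
        brute = np.zeros(traj.n_frames, dtype=bool)
        for f in range(traj.n_frames):
            dmin = min(
                np.linalg.norm(traj.frames[f, i] - traj.frames[f, j])
                for i in rna for j in prot
            )
            brute[f] = dmin <= 4.5
        assert table.occupancy[0] == pytest.approx(brute.mean())


class TestSasa:
    def test_isolated_atom_analytic_sphere(self, structure_factory):
        s = structure_factory([[0, 0, 0]], names=["CA"], elements=["C"])
        areas, per_res = contacts.sasa(s, probe_radius=1.4, n_points=960)
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert areas[0] == pytest.approx(exact, rel=0.01)
        assert per_res[("A", 1)] == pytest.approx(exact, rel=0.01)

    def test_coincident_atoms_fully_occlude(self, structure_factory):
        s = structure_factory([[0, 0, 0], [0, 0, 0]], names=["C1", "C2"],
                              resseqs=[1, 2], elements=["C", "C"])
        areas, _ = contacts.sasa(s, n_points=960)
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert areas.sum() == pytest.approx(exact, rel=0.02)

    def test_two_atoms_vs_independent_oracle(self, structure_factory):
        import mdtraj

        d = 3.0
        s = structure_factory([[0, 0, 0], [d, 0, 0]], names=["C1", "C2"],
                              resseqs=[1, 2], elements=["C", "C"])
        areas, _ = contacts.sasa(s, n_points=960)
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("ALA", chain)
        for name in ("C1", "C2"):
            top.add_atom(name, mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(s.coords[None] / 10.0, top)
        oracle = mdtraj.shrake_rupley(t, probe_radius=0.14,
                                      n_sphere_points=960)[0] * 100.0
        assert areas.sum() == pytest.approx(oracle.sum(), rel=0.02)

    def test_monotone_during_approach(self, structure_factory):
        prev = np.inf
        for d in [7.0, 5.0, 4.0, 3.0, 2.0, 1.0]:
            s = structure_factory([[0, 0, 0], [d, 0, 0]], names=["C1", "C2"],
                                  resseqs=[1, 2], elements=["C", "C"])
            total = contacts.sasa(s, n_points=480)[0].sum()
            assert total <= prev + 1e-9
            prev = total

    def test_unknown_element_rejected(self, structure_factory):
        s = structure_factory([[0, 0, 0]], names=["XX1"], elements=["Xx"])
        with pytest.raises(ValueError, match="radius"):
            contacts.sasa(s)
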