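"""Energy terms: closed forms, analytic forces, invariances."""

import numpy as np
import pytest

from chaperone_cg import dynamics, energy
from chaperone_cg.cg_model import (AMINO_ACID, BeadRecord, CGStructure,
                                   CGTopology, NativeContactSet,
                                   assign_charges, extract_native_contacts,
                                   protein_topology)
from chaperone_cg.energy import ForceFieldParams

from conftest import random_protein


def central_difference_check(fn, positions, h=1e-6, rtol=1e-5):
    """Assert analytic forces match −∇U to ``rtol`` (relative to the
    largest numerical force component)."""
    pos = np.array(positions, float)
    _, forces = fn(pos)
    num = np.zeros_like(forces)
    for i in range(len(pos)):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += h
            pm = pos.copy()
            pm[i, d] -= h
            num[i, d] = -(fn(pp)[0] - fn(pm)[0]) / (2 * h)
    scale = max(np.abs(num).max(), 1e-10)
    assert np.abs(forces - num).max() / scale < rtol


@pytest.fixture()
def charged_chain(rng):
    s = assign_charges(random_protein(rng, n=14))
    topo = protein_topology(s)
    topo.contacts = extract_native_contacts(s, heavy_atom_cutoff=9.0)
    return s, topo


class TestClosedForms:
    def test_bond_stretch_quarter(self):
        # U = k (b - b0)^2 with k = 100: a 0.5 Å stretch costs 25
        s = CGStructure()
        s.beads.append(BeadRecord("A", 1, AMINO_ACID, "ALA", (0, 0, 0)))
        s.beads.append(BeadRecord("A", 2, AMINO_ACID, "ALA", (4.3, 0, 0)))
        topo = CGTopology(bonds=[(0, 1, 3.8)])
        ff = ForceFieldParams(k_bond=100.0)
        e, _ = energy.bonded_energy_forces(s.positions, topo, ff)
        assert e == pytest.approx(25.0)

    def test_contact_minimum_and_zero_crossing(self):
        contacts = NativeContactSet()
        contacts.add(0, 1, 6.0, 2.0, "intra_protein")
        at = lambda r: energy.contact_energy_forces(
            np.array([[0.0, 0, 0], [r, 0, 0]]), contacts)[0]
        assert at(6.0) == pytest.approx(-2.0)
        assert at(6.0 * (5.0 / 6.0) ** 0.5) == pytest.approx(0.0, abs=1e-10)
        assert abs(at(60.0)) < 1e-4 * 2.0
        # zero net force at the minimum
        _, f = energy.contact_energy_forces(
            np.array([[0.0, 0, 0], [6.0, 0, 0]]), contacts)
        assert np.abs(f).max() < 1e-12

    def test_contact_overlap_rejected(self):
        contacts = NativeContactSet()
        contacts.add(0, 1, 6.0, 1.0, "intra_protein")
        with pytest.raises(ValueError, match="overlap"):
            energy.contact_energy_forces(np.zeros((2, 3)), contacts)

    def test_excluded_volume_cutoff_and_monotonicity(self, forcefield):
        pairs = np.array([[0, 1]])
        at = lambda r: energy.excluded_volume_energy_forces(
            np.array([[0.0, 0, 0], [r, 0, 0]]), forcefield, pairs=pairs)[0]
        assert at(forcefield.ev_cutoff + 0.1) == 0.0
        rs = np.linspace(0.5 * forcefield.sigma_ev,
                         forcefield.ev_cutoff - 1e-3, 30)
        es = [at(r) for r in rs]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_debye_length_at_physiological_salt(self):
        lam = ForceFieldParams(ionic_strength=0.3).debye_length()
        assert 5.5 <= lam <= 5.6

    def test_screening_stronger_at_higher_salt(self):
        pos = np.array([[0.0, 0, 0], [7.0, 0, 0]])
        q = np.array([1.0, -1.0])
        e300 = energy.debye_huckel_energy_forces(
            pos, q, ForceFieldParams(ionic_strength=0.30))[0]
        e350 = energy.debye_huckel_energy_forces(
            pos, q, ForceFieldParams(ionic_strength=0.35))[0]
        assert abs(e350) < abs(e300)

    def test_neutral_system_has_no_electrostatics(self, forcefield, rng):
        pos = rng.normal(scale=10, size=(20, 3))
        e, f = energy.debye_huckel_energy_forces(pos, np.zeros(20),
                                                 forcefield)
        assert e == 0.0 and np.abs(f).max() == 0.0


class TestForces:
    def test_bonded_forces_match_central_differences(self, charged_chain,
                                                     forcefield, rng):
        s, topo = charged_chain
        pos = s.positions + rng.normal(scale=0.3, size=(s.n_beads, 3))
        central_difference_check(
            lambda p: energy.bonded_energy_forces(p, topo, forcefield), pos)

    def test_contact_forces_match_central_differences(self, charged_chain,
                                                      forcefield, rng):
        s, topo = charged_chain
        pos = s.positions + rng.normal(scale=0.3, size=(s.n_beads, 3))
        central_difference_check(
            lambda p: energy.contact_energy_forces(p, topo.contacts,
                                                   forcefield), pos)

    def test_nonbonded_forces_match_central_differences(self, charged_chain,
                                                        forcefield, rng):
        s, topo = charged_chain
        pos = s.positions + rng.normal(scale=0.3, size=(s.n_beads, 3))
        ev_excl, dh_excl = energy.nonbonded_exclusions(s, topo)
        central_difference_check(
            lambda p: energy.excluded_volume_energy_forces(
                p, forcefield, exclusions=ev_excl), pos)
        central_difference_check(
            lambda p: energy.debye_huckel_energy_forces(
                p, s.charges, forcefield, exclusions=dh_excl), pos)

    def test_restraint_forces_match_central_differences(self, rng):
        pos = rng.normal(scale=4.0, size=(8, 3))
        restraints = [
            dynamics.PositionAnchor.to_point(pos, [0, 3], (1.0, 2.0, 3.0),
                                             2.0),
            dynamics.Torus(center=(0, 0, 0), axis=(0, 0, 1),
                           major_radius=10.0, tube_radius=5.0,
                           strength=30.0),
            dynamics.Umbrella(group_a=[0, 1, 2], group_b=[5, 6, 7],
                              d0=5.0, k=1.0),
            dynamics.SphericalConfinement(radius=4.0, k=0.5),
        ]
        for r in restraints:
            central_difference_check(lambda p, r=r: r.energy_forces(p), pos)


class TestInvariances:
    def test_energy_invariant_under_rigid_motion(self, charged_chain,
                                                 forcefield, rng):
        s, topo = charged_chain
        rep0, _ = energy.total_energy_forces(s, topo, forcefield)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng)
        moved = rot.apply(s.positions) + np.array([11.0, -5.0, 3.0])
        rep1, _ = energy.total_energy_forces(s, topo, forcefield,
                                             positions=moved)
        assert rep1.total == pytest.approx(rep0.total, rel=1e-8)

    def test_report_total_is_sum_of_parts(self, charged_chain, forcefield):
        s, topo = charged_chain
        rep, _ = energy.total_energy_forces(s, topo, forcefield)
        parts = (rep.bonded + rep.contact + rep.excluded_volume
                 + rep.electrostatic + rep.restraint)
        assert rep.total == pytest.approx(parts)

    def test_kernel_agrees_with_reference_path(self, charged_chain,
                                               forcefield):
        """The neighbour-list MD kernel and the O(N²) reference
        implementation must produce identical per-term energies."""
        s, topo = charged_chain
        params = dynamics.SimulationParams(n_steps=500, snapshot_stride=100,
                                           seed=7)
        traj, _ = dynamics.run_simulation(s, topo, params,
                                          forcefield=forcefield)
        for frame in (0, traj.n_frames - 1):
            rep, _ = energy.total_energy_forces(
                s, topo, forcefield, positions=traj.positions[frame])
            np.testing.assert_allclose(
                traj.energies[frame, :4],
                [rep.bonded, rep.contact, rep.excluded_volume,
                 rep.electrostatic], rtol=1e-9, atol=1e-9)

    def test_brute_force_pair_sum_on_random_gas(self, forcefield, rng):
        """Vectorised pair-list EV equals an explicit double loop."""
        pos = rng.uniform(0, 30, size=(100, 3))
        e_fast, _ = energy.excluded_volume_energy_forces(pos, forcefield,
                                                         exclusions=set())
        e_slow = 0.0
        rc, sig = forcefield.ev_cutoff, forcefield.sigma_ev
        shift = (sig / rc) ** 12
        fshift = 12.0 * shift / rc
        for i in range(100):
            for j in range(i + 1, 100):
                r = np.linalg.norm(pos[i] - pos[j])
                if r < rc:
                    e_slow += forcefield.epsilon_ev * (
                        (sig / r) ** 12 - shift + fshift * (r - rc))
        assert e_fast == pytest.approx(e_slow, rel=1e-12)


class TestGroupEnergy:
    def test_far_groups_interact_negligibly(self, rng, forcefield):
        s = assign_charges(random_protein(rng, n=10))
        far = random_protein(rng, n=10, chain="B").translated((600, 0, 0))
        merged = s.merged_with(assign_charges(far))
        topo = protein_topology(merged)
        e = energy.group_interaction_energy(
            merged.positions, merged, topo, forcefield,
            np.arange(10), np.arange(10, 20))
        assert abs(e) < 1e-10

    def test_partition_additivity(self, mini_system):
        sys_ = mini_system
        pos = sys_.structure.positions
        A = sys_.groups["dimer_proximal"]
        B = np.concatenate([sys_.groups["tetramer"],
                            sys_.groups["dimer_distal"]])
        B1, B2 = sys_.groups["tetramer"], sys_.groups["dimer_distal"]
        args = (pos, sys_.structure, sys_.topology, sys_.forcefield)
        whole = energy.group_interaction_energy(*args, A, B)
        split = (energy.group_interaction_energy(*args, A, B1)
                 + energy.group_interaction_energy(*args, A, B2))
        assert whole == pytest.approx(split, rel=1e-9)

    def test_overlapping_groups_rejected(self, rng, forcefield):
        s = assign_charges(random_protein(rng))
        topo = protein_topology(s)
        with pytest.raises(ValueError, match="disjoint"):
            energy.group_interaction_energy(s.positions, s, topo,
                                            forcefield, [0, 1], [1, 2])

    def test_wrapped_dimer_binds_attractively(self, mini_system):
        sys_ = mini_system
        rest = np.setdiff1d(np.arange(sys_.structure.n_beads),
                            sys_.groups["dimer_proximal"])
        e = energy.group_interaction_energy(
            sys_.structure.positions, sys_.structure, sys_.topology,
            sys_.forcefield, sys_.groups["dimer_proximal"], rest)
        assert e < 0
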