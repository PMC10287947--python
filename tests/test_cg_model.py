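"""Coarse-graining, native contacts, charges and constructs."""

import numpy as np
import pytest
import biotite.structure as struc

from chaperone_cg import cg_model
from chaperone_cg.cg_model import (AMINO_ACID, BASE, PHOSPHATE, SUGAR,
                                   BeadRecord, CGStructure,
                                   assign_charges, build_ideal_bdna,
                                   coarse_grain_dna, coarse_grain_protein,
                                   extract_native_contacts, make_construct,
                                   protein_topology)

from conftest import random_protein


def _atom(chain, res_id, res_name, name, xyz, element="C"):
    a = struc.Atom(np.asarray(xyz, float), chain_id=chain, res_id=res_id,
                   res_name=res_name, atom_name=name, element=element)
    return a


def _protein_atoms(chain="A", n=3, start=1, spacing=3.8, with_ca=True):
    atoms = []
    for k in range(n):
        rid = start + k
        x = k * spacing
        if with_ca or rid != start + 1:
            atoms.append(_atom(chain, rid, "ALA", "CA", (x, 0, 0)))
        atoms.append(_atom(chain, rid, "ALA", "CB", (x, 1.5, 0)))
        atoms.append(_atom(chain, rid, "ALA", "N", (x - 1.2, 0.5, 0),
                           element="N"))
    return struc.array(atoms)


def _dna_atoms(seq1="AT", chains=("X", "Y")):
    """Minimal two-strand atomic duplex (P, sugar C1', base N1)."""
    comp = {"A": "DT", "T": "DA", "C": "DG", "G": "DC"}
    atoms = []
    n = len(seq1)
    for s, cid in enumerate(chains):
        for k in range(n):
            rid = k + 1
            base = "D" + seq1[k] if s == 0 else comp[seq1[n - 1 - k]]
            x = k * 3.4 + s * 12.0
            if k > 0:
                atoms.append(_atom(cid, rid, base, "P", (x, 8.9, 0),
                                   element="P"))
                atoms.append(_atom(cid, rid, base, "OP1", (x, 9.5, 1),
                                   element="O"))
            atoms.append(_atom(cid, rid, base, "C1'", (x, 6.9, 0)))
            atoms.append(_atom(cid, rid, base, "O4'", (x, 7.3, 1),
                               element="O"))
            atoms.append(_atom(cid, rid, base, "N1", (x, 2.8, 0),
                               element="N"))
            atoms.append(_atom(cid, rid, base, "C2", (x, 2.0, 1)))
    return struc.array(atoms)


class TestCoarseGrainProtein:
    def test_one_bead_per_residue_at_ca(self):
        atoms = _protein_atoms(n=3)
        s = coarse_grain_protein(atoms, "A")
        assert s.n_beads == 3
        np.testing.assert_allclose(
            s.positions, [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        assert all(b.bead_kind == AMINO_ACID for b in s.beads)
        assert [b.residue_index for b in s.beads] == [1, 2, 3]

    def test_globular_construct_spans_printed_range(self):
        # a chain numbered 74..365 yields 292 beads
        atoms = _protein_atoms(n=292, start=74)
        s = coarse_grain_protein(atoms, "A")
        assert s.n_beads == 292
        assert s.beads[0].residue_index == 74
        assert s.beads[-1].residue_index == 365

    def test_missing_ca_names_residue(self):
        atoms = _protein_atoms(n=3, with_ca=False)
        with pytest.raises(ValueError, match="residue 2"):
            coarse_grain_protein(atoms, "A")

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain_protein(_protein_atoms(), [])


class TestCoarseGrainDNA:
    def test_one_bp_duplex_has_four_beads(self):
        s = coarse_grain_dna(_dna_atoms("A"))
        # no 5' phosphates: 2 strands x (sugar + base)
        assert s.n_beads == 4
        kinds = sorted(b.bead_kind for b in s.beads)
        assert kinds == [BASE, BASE, SUGAR, SUGAR]

    def test_bead_count_follows_five_prime_rule(self):
        s = coarse_grain_dna(_dna_atoms("ATGC"))
        assert s.n_beads == 2 * (3 * 4 - 1)

    def test_unequal_strands_rejected(self):
        atoms = _dna_atoms("AT")
        atoms = atoms[~((atoms.chain_id == "Y") & (atoms.res_id == 2))]
        with pytest.raises(ValueError, match="strand lengths differ"):
            coarse_grain_dna(atoms)

    def test_unknown_base_rejected(self):
        atoms = _dna_atoms("A")
        atoms.res_name[:] = "DX"
        with pytest.raises(ValueError, match="unknown base"):
            coarse_grain_dna(atoms)


class TestIdealBDNA:
    def test_bead_count_147_bp(self):
        s, _ = build_ideal_bdna("A" * 147)
        assert s.n_beads == 2 * (3 * 147 - 1) == 880

    def test_end_to_end_rise(self):
        s, _ = build_ideal_bdna("ACGTACGTAC")  # 10 bp

        def bp_center(m):
            beads = [i for i, b in enumerate(s.beads)
                     if b.bead_kind == BASE and (
                         (b.chain_id == "DI" and b.residue_index == m + 1)
                         or (b.chain_id == "DJ"
                             and b.residue_index == 10 - m))]
            return s.positions[beads].mean(axis=0)

        d = np.linalg.norm(bp_center(9) - bp_center(0))
        assert d == pytest.approx(9 * 3.38, abs=1e-6)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            build_ideal_bdna("AXT")
        with pytest.raises(ValueError):
            build_ideal_bdna("")

    def test_duplex_charge_follows_phosphate_rule(self):
        s, _ = build_ideal_bdna("ACGTACGTAC")
        s = assign_charges(s)
        assert s.charges.sum() == pytest.approx(-18.0)


class TestNativeContacts:
    def test_far_chains_share_no_contacts(self):
        s = CGStructure()
        s.beads.append(BeadRecord("A", 1, AMINO_ACID, "ALA", (0, 0, 0)))
        s.beads.append(BeadRecord("B", 1, AMINO_ACID, "ALA", (100, 0, 0)))
        assert len(extract_native_contacts(s, heavy_atom_cutoff=6.5)) == 0

    def test_matches_brute_force_all_pairs(self, toy_helix, rng):
        for s in (toy_helix[0], random_protein(rng, n=40)):
            cutoff, sep = 7.0, 4
            got = extract_native_contacts(s, heavy_atom_cutoff=cutoff,
                                          min_seq_sep=sep).pairs()
            pos = s.positions
            expected = set()
            for i in range(s.n_beads):
                for j in range(i + 1, s.n_beads):
                    same = s.beads[i].chain_id == s.beads[j].chain_id
                    if same and j - i < sep:
                        continue
                    if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                        expected.add((i, j))
            assert got == expected

    def test_helix_contacts_are_i_i_plus_4(self, toy_helix):
        s, topo = toy_helix
        assert topo.contacts.pairs() == {(i, i + 4) for i in range(16)}

    def test_flexible_beads_carry_no_contacts(self, rng):
        s = random_protein(rng, n=20)
        s.set_flexible("A", 1, 10)
        contacts = extract_native_contacts(s, heavy_atom_cutoff=8.0)
        flexible = set(range(10))
        assert all(c.i not in flexible and c.j not in flexible
                   for c in contacts)

    def test_mini_nucleosome_every_wrapped_bp_anchored(self, mini_system):
        hd = mini_system.topology.contacts.by_class("histone_dna")
        bead_to_bp = {int(i): bp
                      for bp, beads in mini_system.bp_bead_map.items()
                      for i in beads}
        covered = {bead_to_bp.get(c.i, bead_to_bp.get(c.j)) for c in hd}
        wrap = set(range(mini_system.entry_bp, mini_system.exit_bp + 1))
        assert wrap <= covered


class TestCharges:
    def test_polyglycine_is_neutral(self):
        s = CGStructure()
        for i in range(10):
            s.beads.append(BeadRecord("A", i + 1, AMINO_ACID, "GLY",
                                      (3.8 * i, 0, 0)))
        assert assign_charges(s).charges.sum() == 0.0

    def test_assignment_is_idempotent(self, rng):
        s = assign_charges(random_protein(rng))
        np.testing.assert_array_equal(assign_charges(s).charges, s.charges)

    def test_unknown_residue_warns_and_zeroes(self):
        s = CGStructure()
        s.beads.append(BeadRecord("A", 1, AMINO_ACID, "XYZ", (0, 0, 0)))
        with pytest.warns(UserWarning, match="XYZ"):
            out = assign_charges(s)
        assert out.charges[0] == 0.0

    def test_scale_factor_applies_uniformly(self, rng):
        s = random_protein(rng)
        half = assign_charges(s, scale=0.5)
        full = assign_charges(s)
        np.testing.assert_allclose(half.charges, 0.5 * full.charges)


class TestConstructs:
    def _chain(self, n=120, start=1):
        s = CGStructure()
        for k in range(n):
            s.beads.append(BeadRecord("H", start + k, AMINO_ACID, "ALA",
                                      (3.8 * k, 0, 0)))
        return s

    def test_truncation_range_arithmetic(self):
        # keep 16..105 out of 1..128 -> 90 beads
        s = self._chain(n=128)
        out = make_construct(s, {"H": (16, 105)}, label="dNC")
        assert out.n_beads == 90
        assert out.metadata["construct"] == "dNC"
        assert out.beads[0].residue_index == 16

    def test_keep_full_range_is_identity(self):
        s = self._chain(n=30)
        out = make_construct(s, {"H": (1, 30)})
        np.testing.assert_array_equal(out.positions, s.positions)

    def test_empty_construct_rejected(self):
        with pytest.raises(ValueError):
            make_construct(self._chain(10), {"H": (900, 950)})

    def test_construct_then_extract_commutes(self, rng):
        s = random_protein(rng, n=30)
        topo = protein_topology(s)
        topo.contacts = extract_native_contacts(s, heavy_atom_cutoff=8.0)
        kept, new_topo = make_construct(s, {"A": (5, 20)}, topology=topo)
        direct = extract_native_contacts(kept, heavy_atom_cutoff=8.0)
        assert new_topo.contacts.pairs() == direct.pairs()

    def test_topology_terms_outside_range_dropped(self):
        s = self._chain(n=10)
        topo = protein_topology(s)
        kept, new_topo = make_construct(s, {"H": (1, 5)}, topology=topo)
        new_topo.validate(kept.n_beads)
        assert len(new_topo.bonds) == 4


class TestTopology:
    def test_bonded_exclusions_reach_1_4(self, toy_helix):
        _, topo = toy_helix
        excl = topo.bonded_exclusions()
        assert (0, 1) in excl and (0, 2) in excl and (0, 3) in excl
        assert (0, 4) not in excl

    def test_validate_rejects_bad_indices(self):
        topo = cg_model.CGTopology(bonds=[(0, 99, 3.8)])
        with pytest.raises(ValueError):
            topo.validate(10)

    def test_dihedrals_skip_near_collinear_native_quadruples(self):
        s = self._straight_chain()
        topo = protein_topology(s)
        assert topo.dihedrals == []

    @staticmethod
    def _straight_chain():
        s = CGStructure()
        for k in range(6):
            s.beads.append(BeadRecord("A", k + 1, AMINO_ACID, "ALA",
                                      (3.8 * k, 0, 0)))
        return s
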