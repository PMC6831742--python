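"""Parsers, bond perception and DFS ring detection."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

import chargekit as ck
from chargekit import Atom, Bond, Molecule, ParseError

from conftest import carbon_skeleton, pdb_atom_line, random_connected_graph


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

class TestParsePdb:
    def test_single_atom_no_bonds(self):
        mol = ck.parse_pdb(pdb_atom_line(1, "C1", 0, 0, 0, "C"))
        assert mol.n_atoms == 1
        assert mol.bonds == []
        assert mol.atoms[0].element == "C"

    def test_bond_perceived_at_covalent_distance(self):
        text = "\n".join([
            pdb_atom_line(1, "C1", 0, 0, 0, "C"),
            pdb_atom_line(2, "C2", 1.54, 0, 0, "C"),
        ])
        mol = ck.parse_pdb(text)
        assert len(mol.bonds) == 1  # 1.54 <= 0.76 + 0.76 + 0.45

    def test_conect_bonds_used_when_present(self):
        text = "\n".join([
            pdb_atom_line(1, "C1", 0, 0, 0, "C"),
            pdb_atom_line(2, "C2", 8.0, 0, 0, "C"),  # far beyond perception
            "CONECT    1    2",
        ])
        mol = ck.parse_pdb(text)
        assert mol.bonds == [Bond(0, 1, 1)]

    def test_unsupported_element_named_in_error(self):
        with pytest.raises(ParseError, match="Se"):
            ck.parse_pdb(pdb_atom_line(1, "SE1", 0, 0, 0, "Se"))

    def test_malformed_record_reports_line_number(self):
        text = pdb_atom_line(1, "C1", 0, 0, 0, "C") + "\nATOM  garbage"
        with pytest.raises(ParseError, match="line 2"):
            ck.parse_pdb(text)

    def test_element_fallback_from_atom_name(self):
        line = pdb_atom_line(1, "CL1", 0, 0, 0, "  ")
        mol = ck.parse_pdb(line)
        assert mol.atoms[0].element == "Cl"

    def test_no_atoms_rejected(self):
        with pytest.raises(ParseError):
            ck.parse_pdb("REMARK nothing here\nEND")

    def test_round_trip_preserves_graph(self, synthetic_corpus_small):
        for mol in synthetic_corpus_small[:10]:
            back = ck.parse_pdb(ck.write_pdb(mol))
            assert back.n_atoms == mol.n_atoms
            assert back.elements == mol.elements
            assert {(b.i, b.j) for b in back.bonds} == {(b.i, b.j) for b in mol.bonds}


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

ETHANE_SDF = """ethane
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


class TestParseSdf:
    def test_ethane(self):
        mol = ck.parse_sdf(ETHANE_SDF)
        assert mol.n_atoms == 2
        assert mol.bonds == [Bond(0, 1, 1)]

    def test_benzene_order4_maps_to_aromatic(self, benzene_sdf):
        mol = ck.parse_sdf(benzene_sdf)
        aromatic = [b for b in mol.bonds if b.aromatic]
        assert len(aromatic) == 6
        assert all(b.order == 1 for b in aromatic)

    def test_zero_atom_molecule_rejected(self):
        text = "empty\n\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n"
        with pytest.raises(ParseError):
            ck.parse_sdf(text)

    def test_truncated_blocks_rejected(self):
        text = "bad\n\n\n  3  1  0  0  0  0  0  0  0  0999 V2000\n" + \
            "    0.0000    0.0000    0.0000 C   0\nM  END\n"
        with pytest.raises(ParseError):
            ck.parse_sdf(text)

    def test_round_trip_exact(self, synthetic_corpus_small):
        """parse_sdf(write_sdf(mol)) reproduces atoms, bonds, orders."""
        for mol in synthetic_corpus_small[:25]:
            back = ck.parse_sdf(ck.write_sdf(mol))
            assert back.elements == mol.elements
            assert [(b.i, b.j, b.order, b.aromatic) for b in sorted(back.bonds, key=lambda b: (b.i, b.j))] == \
                   [(b.i, b.j, b.order, b.aromatic) for b in sorted(mol.bonds, key=lambda b: (b.i, b.j))]
            np.testing.assert_allclose(back.coords_array(), mol.coords_array(), atol=5e-5)


# ---------------------------------------------------------------------------
# SMILES
# ---------------------------------------------------------------------------

class TestParseSmiles:
    def test_methane_implicit_hydrogens(self):
        mol = ck.parse_smiles("C")
        assert mol.n_atoms == 5
        assert sorted(mol.elements) == ["C", "H", "H", "H", "H"]
        assert len(mol.bonds) == 4

    def test_cyclohexane_ring_closure(self):
        mol = ck.parse_smiles("C1CCCCC1")
        assert mol.elements.count("C") == 6
        assert mol.elements.count("H") == 12
        rings = ck.find_rings(mol)
        assert rings.n_rings == 1 and len(rings.rings[0]) == 6

    @pytest.mark.parametrize("bad", ["C(", "C)", "C1CC", "C/C=C/C", "[C@H](N)C"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ParseError):
            ck.parse_smiles(bad)

    def test_charged_bracket_atom(self):
        mol = ck.parse_smiles("[NH4+]")
        assert mol.elements.count("H") == 4
        assert mol.atoms[0].formal_charge == 1

    @pytest.mark.parametrize("smiles", ["CCO", "CC(=O)O", "C#N", "c1ccccc1", "CC(C)Cl", "O=P(O)(O)O"])
    def test_formula_matches_rdkit(self, smiles):
        from rdkit import Chem
        ours = ck.parse_smiles(smiles)
        ref = Chem.AddHs(Chem.MolFromSmiles(smiles))
        ref_counts: dict[str, int] = {}
        for a in ref.GetAtoms():
            ref_counts[a.GetSymbol()] = ref_counts.get(a.GetSymbol(), 0) + 1
        our_counts = {e: ours.elements.count(e) for e in set(ours.elements)}
        assert our_counts == ref_counts
        assert len(ours.bonds) == ref.GetNumBonds()


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

class TestPerceiveBonds:
    def make_pair(self, d):
        return [Atom(0, "C", np.zeros(3)), Atom(1, "C", np.array([d, 0.0, 0.0]))]

    def test_bond_within_radius_sum(self):
        assert len(ck.perceive_bonds(self.make_pair(1.54))) == 1

    def test_no_bond_beyond_cutoff(self):
        assert ck.perceive_bonds(self.make_pair(3.0)) == []

    def test_no_bond_below_clash_floor(self):
        assert ck.perceive_bonds(self.make_pair(0.1)) == []

    def test_missing_coords_rejected(self):
        with pytest.raises(ck.MoleculeError):
            ck.perceive_bonds([Atom(0, "C", None), Atom(1, "C", np.zeros(3))])

    def test_valence_cap_drops_longest(self):
        # central C with five neighbors in range: H (valence 1) keeps only 1
        atoms = [Atom(0, "H", np.zeros(3))]
        for k in range(3):
            ang = 2 * np.pi * k / 3
            atoms.append(Atom(k + 1, "C", np.array([1.1 * np.cos(ang), 1.1 * np.sin(ang), 0.0])))
        bonds = ck.perceive_bonds(atoms)
        assert sum(1 for b in bonds if 0 in (b.i, b.j)) == 1

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(3)
        atoms = [Atom(k, "C", rng.uniform(0, 6, 3)) for k in range(8)]
        bonds = {(b.i, b.j) for b in ck.perceive_bonds(atoms)}
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        permuted = [Atom(k, "C", atoms[perm[k]].coords) for k in range(8)]
        bonds_p = {(b.i, b.j) for b in ck.perceive_bonds(permuted)}
        mapped = {tuple(sorted((inv[i], inv[j]))) for i, j in bonds}
        assert bonds_p == {(min(i, j), max(i, j)) for i, j in mapped}


# ---------------------------------------------------------------------------
# Ring perception
# ---------------------------------------------------------------------------

class TestFindRings:
    def test_linear_pentane_acyclic(self):
        mol = carbon_skeleton(5, [(k, k + 1) for k in range(4)])
        rings = ck.find_rings(mol)
        assert rings.n_rings == 0
        assert (rings.atom_ring_count == 0).all()

    def test_benzene_single_six_ring(self):
        mol = carbon_skeleton(6, [(k, (k + 1) % 6) for k in range(6)])
        rings = ck.find_rings(mol)
        assert rings.n_rings == 1
        assert len(rings.rings[0]) == 6
        assert (rings.atom_min_ring_size == 6).all()
        assert (rings.atom_max_ring_size == 6).all()

    def test_naphthalene_fused_system(self):
        edges = [(k, (k + 1) % 6) for k in range(6)]          # first ring
        edges += [(0, 6), (6, 7), (7, 8), (8, 9), (9, 1)]      # fused second ring
        mol = carbon_skeleton(10, edges)
        rings = ck.find_rings(mol)
        assert rings.n_rings == 2  # |E| - |V| + 1 = 11 - 10 + 1
        assert len(rings.ring_systems) == 1
        assert rings.ring_systems[0].n_rings == 2
        assert rings.ring_systems[0].n_atoms == 10

    def test_disconnected_components_counted_per_component(self):
        edges = [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]
        mol = carbon_skeleton(6, edges)
        assert ck.find_rings(mol).n_rings == 2  # |E|-|V|+C = 6-6+2

    def test_cycle_count_law_random_graphs(self):
        """Basis size equals |E| - |V| + 1 on random connected graphs."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, edges = random_connected_graph(rng)
            mol = carbon_skeleton(n, edges)
            rings = ck.find_rings(mol)
            assert rings.n_rings == len(edges) - n + 1

    def test_rings_are_simple_cycles_of_the_graph(self):
        """Every basis ring appears in a brute-force cycle enumeration."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            n, edges = random_connected_graph(rng, max_nodes=10)
            mol = carbon_skeleton(n, edges)
            g = nx.Graph(edges)
            g.add_nodes_from(range(n))
            all_cycles = {frozenset(c) for c in nx.simple_cycles(g)}
            for ring in ck.find_rings(mol).rings:
                assert frozenset(ring) in all_cycles

    def test_determinism(self):
        mol = carbon_skeleton(10, [(k, (k + 1) % 6) for k in range(6)] +
                              [(0, 6), (6, 7), (7, 8), (8, 9), (9, 1)])
        assert ck.find_rings(mol).rings == ck.find_rings(mol).rings


# ---------------------------------------------------------------------------
# Molecule invariants
# ---------------------------------------------------------------------------

class TestMoleculeInvariants:
    def test_valence_cap_enforced(self):
        atoms = [Atom(k, "O", np.array([float(k), 0, 0])) for k in range(4)]
        bonds = [Bond(0, 1), Bond(0, 2), Bond(0, 3)]  # O with 3 bonds
        with pytest.raises(ck.MoleculeError, match="valence"):
            Molecule("bad", atoms, bonds)

    def test_duplicate_bond_rejected(self):
        atoms = [Atom(0, "C", np.zeros(3)), Atom(1, "C", np.array([1.5, 0, 0]))]
        with pytest.raises(ck.MoleculeError, match="duplicate"):
            Molecule("bad", atoms, [Bond(0, 1), Bond(1, 0)])

    def test_self_loop_rejected(self):
        with pytest.raises(ck.MoleculeError):
            Bond(2, 2)

    def test_unsupported_element_rejected(self):
        with pytest.raises(ck.MoleculeError, match="Xe"):
            Atom(0, "Xe", np.zeros(3))


class TestEmbedding:
    def test_bonded_atoms_at_bond_length(self, ethanol):
        mol = ck.embed_coordinates(ethanol)
        assert mol.coords_approximate
        for b in mol.bonds:
            d = np.linalg.norm(mol.atoms[b.i].coords - mol.atoms[b.j].coords)
            assert d == pytest.approx(1.5, abs=1e-9)

    def test_deterministic(self, ethanol):
        a = ck.embed_coordinates(ethanol).coords_array()
        b = ck.embed_coordinates(ethanol).coords_array()
        np.testing.assert_array_equal(a, b)
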