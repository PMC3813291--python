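"""Molecular graph parsing, valence bookkeeping and canonical hashing."""

import itertools
import random

import networkx as nx
import pytest
from rdkit import Chem

from fragrank import (
    MolecularGraph,
    SdfFormatError,
    SmilesParseError,
    UnsupportedElementError,
    anonymize,
    canonical_hash,
    parse_smiles,
    read_sdf,
)
from fragrank.chem_graph import Atom, Bond


class TestParseSmiles:
    @pytest.mark.parametrize(
        "smiles, n_heavy, total_h",
        [
            ("c1ccccc1", 6, 6),  # benzene: 1 H per carbon
            ("c1ccc2ncccc2c1", 10, 7),  # quinoline
            ("C1CC1C(=O)O", 6, 6),  # carboxyl OH contributes 1 of the 6
            ("C", 1, 4),
            ("CC(N)=O", 4, 5),
        ],
    )
    def test_atom_and_hydrogen_counts(self, smiles, n_heavy, total_h):
        m = parse_smiles(smiles)
        assert m.num_atoms == n_heavy
        assert sum(a.implicit_h for a in m.atoms) == total_h

    def test_carboxyl_oxygen_gets_the_hydrogen(self):
        m = parse_smiles("C1CC1C(=O)O")
        o_hs = sorted(a.implicit_h for a in m.atoms if a.element == "O")
        assert o_hs == [0, 1]

    def test_pi_marker_defaults_to_zero(self, quinoline):
        assert all(a.pi_marker == 0 for a in quinoline.atoms)

    def test_malformed_string_names_position(self):
        with pytest.raises(SmilesParseError) as exc:
            parse_smiles("CC?C")
        assert exc.value.position == 2

    def test_unclosed_ring_rejected(self):
        with pytest.raises(SmilesParseError):
            parse_smiles("C1CC")

    def test_empty_string_rejected(self):
        with pytest.raises(SmilesParseError):
            parse_smiles("   ")

    def test_unsupported_element(self):
        with pytest.raises(UnsupportedElementError) as exc:
            parse_smiles("C[Si](C)(C)C")
        assert exc.value.element == "Si"

    def test_charged_atom_parsed(self):
        m = parse_smiles("C[N+](C)(C)C")
        charges = [a.formal_charge for a in m.atoms]
        assert charges.count(1) == 1

    def test_valence_sum_consistency(self):
        """Sum of standard valences = 2 x Kekulé bond-order sum + total
        implicit hydrogens, for neutral C/N/O/S molecules."""
        valence = {"C": 4, "N": 3, "O": 2, "S": 2}
        for smi in ["c1ccccc1", "c1ccc2ncccc2c1", "CC(N)=O", "O=c1cc[nH]cn1",
                    "c1ccsc1", "CCO", "C1CNCCN1"]:
            m = parse_smiles(smi)
            lhs = sum(valence[a.element] for a in m.atoms)
            rhs = 2 * sum(b.order for b in m.bonds) + sum(
                a.implicit_h for a in m.atoms
            )
            assert lhs == rhs, smi


class TestMolecularGraphInvariants:
    def test_self_bond_rejected(self):
        with pytest.raises(ValueError, match="self-bond"):
            MolecularGraph(atoms=[Atom("C")], bonds=[Bond(0, 0)])

    def test_duplicate_bond_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MolecularGraph(
                atoms=[Atom("C"), Atom("C")], bonds=[Bond(0, 1), Bond(1, 0)]
            )

    def test_out_of_range_bond_rejected(self):
        with pytest.raises(ValueError, match="out-of-range"):
            MolecularGraph(atoms=[Atom("C")], bonds=[Bond(0, 3)])

    def test_molecular_formula_hill_order(self, quinoline):
        assert quinoline.molecular_formula() == "C9H7N"


class TestReadSdf:
    def _molblock(self, smiles):
        return Chem.MolToMolBlock(Chem.MolFromSmiles(smiles))

    def test_single_record(self, tmp_path):
        p = tmp_path / "one.sdf"
        p.write_text(self._molblock("c1ccccc1") + "$$$$\n")
        mols = read_sdf(p)
        assert len(mols) == 1 and mols[0].num_atoms == 6

    def test_two_records(self, tmp_path):
        p = tmp_path / "two.sdf"
        p.write_text(
            self._molblock("c1ccccc1") + "$$$$\n"
            + self._molblock("CCO") + "$$$$\n"
        )
        assert len(read_sdf(p)) == 2

    def test_explicit_hydrogens_folded(self, tmp_path):
        mol = Chem.AddHs(Chem.MolFromSmiles("C"))
        p = tmp_path / "methane.sdf"
        p.write_text(Chem.MolToMolBlock(mol) + "$$$$\n")
        m = read_sdf(p)[0]
        assert m.num_atoms == 1 and m.atoms[0].implicit_h == 4

    def test_empty_file(self, tmp_path, caplog):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        with caplog.at_level("WARNING", logger="fragrank"):
            assert read_sdf(p) == []
        assert "no records" in caplog.text

    def test_truncated_record_errors_with_index(self, tmp_path):
        p = tmp_path / "bad.sdf"
        p.write_text("garbage\nnot a molfile\n$$$$\n")
        with pytest.raises(SdfFormatError) as exc:
            read_sdf(p)
        assert exc.value.index == 0


class TestAnonymize:
    def test_quinoline_isoquinoline_same_hash(self, quinoline, isoquinoline):
        assert anonymize(quinoline).hash == anonymize(isoquinoline).hash

    def test_benzene_cyclohexane_same_topology(self, benzene):
        assert anonymize(benzene).hash == anonymize(parse_smiles("C1CCCCC1")).hash

    def test_different_node_count_different_hash(self, benzene):
        picoline = parse_smiles("Cc1ccccn1")
        assert anonymize(benzene).hash != anonymize(picoline).hash

    def test_attributes_dropped(self, quinoline):
        g = anonymize(quinoline)
        assert g.num_nodes == 10 and len(g.edges) == 11


class TestCanonicalHash:
    def test_deterministic(self):
        g = nx.gnp_random_graph(10, 0.4, seed=7)
        h1 = canonical_hash(10, g.edges())
        h2 = canonical_hash(10, list(g.edges()))
        assert h1 == h2

    def test_path_vs_star(self):
        p4 = [(0, 1), (1, 2), (2, 3)]
        s4 = [(0, 1), (0, 2), (0, 3)]
        assert canonical_hash(4, p4) != canonical_hash(4, s4)

    def test_relabel_invariance_random_graphs(self):
        rng = random.Random(42)
        for _ in range(40):
            n = rng.randint(2, 14)
            g = nx.gnp_random_graph(n, 0.35, seed=rng.randint(0, 10**6))
            perm = list(range(n))
            rng.shuffle(perm)
            g2 = nx.relabel_nodes(g, dict(enumerate(perm)))
            assert canonical_hash(n, g.edges()) == canonical_hash(n, g2.edges())

    def test_agrees_with_isomorphism_oracle(self):
        """Equal hash iff isomorphic, on a library of small graphs checked
        pairwise against VF2."""
        rng = random.Random(0)
        graphs = [
            nx.gnp_random_graph(rng.randint(2, 12), rng.choice([0.2, 0.4, 0.6]),
                                seed=rng.randint(0, 10**6))
            for _ in range(80)
        ]
        graphs += [nx.star_graph(9), nx.cycle_graph(10), nx.empty_graph(8),
                   nx.petersen_graph(), nx.complete_bipartite_graph(3, 3)]
        hashes = [canonical_hash(g.number_of_nodes(), g.edges()) for g in graphs]
        for (i, g1), (j, g2) in itertools.combinations(enumerate(graphs), 2):
            iso = (
                g1.number_of_nodes() == g2.number_of_nodes()
                and nx.is_isomorphic(g1, g2)
            )
            assert (hashes[i] == hashes[j]) == iso
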