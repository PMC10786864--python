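import numpy as np
import pytest

from conftest import ca_chain, single_atom_chain
from oracles import allpairs_contacts
from ppirep.interfaces import (atomic_contacts, enumerate_interfaces,
                               extract_interface, filter_fda_ligands,
                               ligand_at_interface, write_binding_table,
                               write_interface_table)
from ppirep.structure import (Atom, Chain, Residue, StructureModel, VdwTable,
                              parse_structure)
from ppirep.synthetic import make_complex, plant_ligand


class TestAtomicContacts:
    @pytest.mark.parametrize("distance,expected", [
        (3.85, 1),   # C-C threshold is 1.70 + 1.70 + 0.5 = 3.90
        (3.95, 0),
        (3.90, 0),   # strict inequality
    ])
    def test_carbon_pair_threshold(self, vdw, distance, expected):
        a = single_atom_chain("A", [0, 0, 0])
        b = single_atom_chain("B", [distance, 0, 0])
        assert len(atomic_contacts(a, b, vdw)) == expected

    def test_element_radii_enter_threshold(self, vdw):
        # C-O threshold 1.70 + 1.52 + 0.5 = 3.72
        a = single_atom_chain("A", [0, 0, 0], element="C")
        b = single_atom_chain("B", [3.8, 0, 0], element="O")
        assert atomic_contacts(a, b, vdw) == []
        b2 = single_atom_chain("B", [3.7, 0, 0], element="O")
        assert len(atomic_contacts(a, b2, vdw)) == 1

    def test_empty_chain_rejected(self, vdw):
        with pytest.raises(ValueError):
            atomic_contacts(Chain("A"), single_atom_chain("B", [0, 0, 0]), vdw)

    @pytest.mark.parametrize("seed", range(10))
    def test_grid_equals_all_pairs_oracle(self, vdw, seed):
        """KD-tree accelerated contacts match the O(n^2) scan exactly."""
        rng = np.random.default_rng(seed)
        elements = np.array(["C", "N", "O", "S"])

        def random_chain(cid, offset):
            residues = []
            for r in range(50):
                atoms = [Atom(name=f"X{k}", element=str(rng.choice(elements)),
                              coord=rng.uniform(0, 25, size=3) + offset)
                         for k in range(4)]
                residues.append(Residue("ALA", r + 1, atoms=atoms))
            return Chain(cid, residues)

        a = random_chain("A", 0.0)
        b = random_chain("B", rng.uniform(0, 6))
        got = {(c.residue_a, c.residue_b): c.min_dist
               for c in atomic_contacts(a, b, vdw)}
        expected = allpairs_contacts(a, b, vdw)
        assert got.keys() == expected.keys()
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_symmetry(self, vdw, two_chain_model):
        a, b = two_chain_model.chains
        fwd = {(c.residue_a, c.residue_b) for c in atomic_contacts(a, b, vdw)}
        rev = {(c.residue_b, c.residue_a) for c in atomic_contacts(b, a, vdw)}
        assert fwd == rev and fwd


class TestExtractInterface:
    @pytest.mark.parametrize("n_contacts,is_interface", [(5, True), (4, False)])
    def test_five_residue_boundary(self, vdw, n_contacts, is_interface):
        text, _ = make_complex(10, 10, n_contacts, seed=0)
        model = parse_structure(text, entry_id="TOY1")
        iface = extract_interface("TOY1", *model.chains, vdw)
        assert (iface is not None) == is_interface

    def test_asymmetric_sides_rejected(self, vdw):
        # 5 residues on one side but only 4 on the other: B residue 1
        # touches A residues 1 and 2
        a = ca_chain("A", [[0, 0, 0], [3.0, 0, 0], [9, 0, 0], [15, 0, 0],
                           [21, 0, 0]])
        b = ca_chain("B", [[1.5, 3.0, 0], [9, 3.5, 0], [15, 3.5, 0],
                           [21, 3.5, 0]])
        contacts = atomic_contacts(a, b, vdw)
        assert len({c.residue_a for c in contacts}) == 5
        assert len({c.residue_b for c in contacts}) == 4
        assert extract_interface("X", a, b, vdw) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_residue_sets_recovered(self, vdw, seed):
        text, truth = make_complex(20, 20, 7, seed=seed)
        model = parse_structure(text, entry_id=truth["entry_id"])
        iface = extract_interface(truth["entry_id"], *model.chains, vdw)
        assert iface.residues_a == truth["residues_a"]
        assert iface.residues_b == truth["residues_b"]
        assert {(c.residue_a, c.residue_b) for c in iface.contacts} == \
            truth["contacts"]

    def test_residue_sets_derived_from_contacts(self, vdw, two_chain_model):
        iface = extract_interface("FIX1", *two_chain_model.chains, vdw)
        assert iface.residues_a == {c.residue_a for c in iface.contacts}
        assert iface.residues_b == {c.residue_b for c in iface.contacts}

    def test_min_residue_monotonicity(self, vdw):
        text, _ = make_complex(12, 12, 6, seed=1)
        model = parse_structure(text, entry_id="TOY1")
        at1 = enumerate_interfaces(model, vdw, min_residues=1)
        at5 = enumerate_interfaces(model, vdw, min_residues=5)
        assert len(at5) <= len(at1)


class TestEnumerateInterfaces:
    def test_single_chain_empty(self, vdw):
        model = StructureModel("S", [ca_chain("A", [[0, 0, 0]] )])
        assert enumerate_interfaces(model, vdw) == []

    def test_three_chains_one_touching_pair(self, vdw):
        a = ca_chain("A", [[i * 6.0, 0, 0] for i in range(6)])
        b = ca_chain("B", [[i * 6.0, 3.5, 0] for i in range(6)])
        c = ca_chain("C", [[i * 6.0, 100.0, 0] for i in range(6)])
        model = StructureModel("TRI", [c, b, a])  # unsorted on purpose
        ifaces = enumerate_interfaces(model, vdw)
        assert [f.id for f in ifaces] == ["TRI_A_B"]
        n = len(model.chains)
        assert len(ifaces) <= n * (n - 1) // 2


class TestLigandAtInterface:
    def _setup(self, at_interface, distance, side="a", seed=0):
        text, truth = make_complex(12, 12, 6, seed=seed)
        text, truth = plant_ligand(text, truth, at_interface=at_interface,
                                   distance=distance, side=side, seed=seed)
        model = parse_structure(text, entry_id=truth["entry_id"])
        vdw = VdwTable()
        iface = extract_interface(truth["entry_id"], model.chain("A"),
                                  model.chain("B"), vdw)
        return model, iface, truth

    def test_ligand_within_cutoff_reported(self):
        model, iface, truth = self._setup(True, 4.0)
        bindings = ligand_at_interface(model, iface)
        assert len(bindings) == 1
        assert bindings[0].contact_residues == \
            truth["ligands"][0]["contact_residues"]

    def test_ligand_beyond_cutoff_ignored(self):
        model, iface, _ = self._setup(True, 6.0)
        assert ligand_at_interface(model, iface) == []

    @pytest.mark.parametrize("distance,expected", [(4.999, 1), (5.001, 0)])
    def test_cutoff_boundary(self, distance, expected):
        model, iface, _ = self._setup(True, distance)
        assert len(ligand_at_interface(model, iface)) == expected

    def test_off_interface_not_reported(self):
        model, iface, _ = self._setup(False, 4.0)
        assert ligand_at_interface(model, iface) == []

    def test_bridging_ligand_bound_both_sides(self):
        model, iface, truth = self._setup(True, 4.0, side="both")
        bindings = ligand_at_interface(model, iface)
        assert bindings[0].bound_side == "both"
        assert {s for s, _ in bindings[0].contact_residues} == \
            {"chain_a", "chain_b"}


class TestFdaFilter:
    def _binding(self, code):
        from ppirep.interfaces import LigandBinding
        return LigandBinding(code, ("L", 1, ""), "X_A_B", "chain_a",
                             frozenset({("chain_a", (1, ""))}))

    def test_cryo_additives_always_removed(self):
        bindings = [self._binding(c) for c in ("GOL", "IPA", "TPV")]
        kept = filter_fda_ligands(bindings, {"GOL", "IPA", "TPV"})
        assert [b.ligand_code for b in kept] == ["TPV"]

    def test_non_fda_code_removed(self):
        kept = filter_fda_ligands([self._binding("ZZZ")], {"TPV"})
        assert kept == []

    def test_empty_code_set_warns_and_empties(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            assert filter_fda_ligands([self._binding("TPV")], set()) == []
        assert any("empty" in r.message for r in caplog.records)


def test_tables_round_readable(vdw, two_chain_model):
    iface = extract_interface("FIX1", *two_chain_model.chains, vdw)
    table = write_interface_table([iface])
    header, row = table.strip().splitlines()
    assert header.split("\t")[0] == "interface_id"
    assert row.split("\t")[0] == iface.id
    assert write_binding_table([]).strip().startswith("ligand_code")
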