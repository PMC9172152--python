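import pytest

from molkit import (StructureError, break_bond, condense, ecfp, find_targets,
                    hydrolyse, ketoreduce, parse_smiles, split_disconnected,
                    write_smiles)
from molkit.reactions import TargetDefinition, add_atom, make_bond, remove_atom
from molkit.substructure import structures_match

PEPTIDE_BOND = TargetDefinition("C(=O)NC", (0, 2), "peptide bond")


class TestTargetDefinition:
    def test_index_outside_substructure_rejected(self):
        with pytest.raises(ValueError):
            TargetDefinition("CC", (0, 5)).substructure()

    def test_unbonded_pair_rejected(self):
        with pytest.raises(ValueError):
            TargetDefinition("CCC", (0, 2)).substructure()

    def test_three_indices_rejected(self):
        with pytest.raises(ValueError):
            TargetDefinition("CCC", (0, 1, 2))


class TestFindTargets:
    def test_one_peptide_bond_in_n_methylacetamide(self):
        targets = find_targets(PEPTIDE_BOND, parse_smiles("CC(=O)NC"))
        assert len(targets) == 1
        structure = parse_smiles("CC(=O)NC")
        targets = find_targets(PEPTIDE_BOND, structure)
        bond = targets[0]
        assert structure.atom(bond.atom1).element == "C"
        assert structure.atom(bond.atom2).element == "N"

    def test_no_motif_no_targets(self):
        assert find_targets(PEPTIDE_BOND, parse_smiles("CCO")) == []

    def test_two_amides_in_a_diketopiperazine(self):
        targets = find_targets(PEPTIDE_BOND,
                               parse_smiles("O=C1CNC(=O)CN1"))
        assert len(targets) == 2

    def test_atom_target_returns_atoms(self):
        defn = TargetDefinition("C(=O)O", (0,), "carboxyl carbon")
        atoms = find_targets(defn, parse_smiles("OC(=O)CCC(=O)O"))
        assert len(atoms) == 2
        assert all(a.element == "C" for a in atoms)


class TestPrimitiveEdits:
    def test_break_central_bond_of_butane_gives_two_ethanes(self):
        s = parse_smiles("CCCC")
        bond = s.bond_between(1, 2)
        break_bond(s, bond)
        pieces = split_disconnected(s)
        assert len(pieces) == 2
        ethane = parse_smiles("CC")
        assert all(structures_match(p, ethane) for p in pieces)

    def test_add_atom_satisfies_open_valence(self):
        s = parse_smiles("[CH3]")
        assert s.atom(0).unpaired == 1
        add_atom(s, 0, "H")
        assert s.atom(0).unpaired == 0
        assert s.hydrogen_count(0) == 4

    def test_remove_ring_atom_caps_both_open_valences(self):
        s = parse_smiles("C1CCCCC1")
        remove_atom(s, 0)
        assert structures_match(s, parse_smiles("CCCCC"))

    def test_make_bond_strips_hydrogens(self):
        s = parse_smiles("CCCCC")
        make_bond(s, 0, 4)
        assert structures_match(s, parse_smiles("C1CCCC1"))

    def test_uncapped_edit_defers_validation(self):
        s = parse_smiles("CCCC")
        break_bond(s, s.bond_between(1, 2), cap=None)
        # the two fragments now have unpaired electrons; refresh tolerates
        # them (sub-valence), and capping restores full valence
        add_atom(s, 1, "H")
        add_atom(s, 2, "H")
        assert all(a.unpaired == 0 for a in s.heavy_atoms())


class TestSplit:
    def test_connected_molecule_stays_whole(self):
        pieces = split_disconnected(parse_smiles("CCO"))
        assert len(pieces) == 1

    def test_dot_components_split_apart(self):
        pieces = split_disconnected(parse_smiles("CC.O.[Na+]"))
        assert len(pieces) == 3

    def test_atom_sets_partition_the_input(self):
        s = parse_smiles("CC.OCC.N")
        pieces = split_disconnected(s)
        union = sorted(idx for p in pieces for idx in p.atoms)
        assert union == sorted(s.atoms)

    def test_annotations_preserved(self):
        s = parse_smiles("CC.O")
        s.annotate("origin", None)
        s.set_annotation(0, "origin", "tagged")
        pieces = split_disconnected(s)
        tagged = [p for p in pieces if 0 in p.atoms][0]
        assert tagged.get_annotation(0, "origin") == "tagged"


class TestHydrolysisCondensation:
    def test_amide_hydrolysis_gives_acid_and_amine(self):
        structure = parse_smiles("CC(=O)NC")
        target = find_targets(PEPTIDE_BOND, structure)[0]
        acid, amine = hydrolyse(structure, target)
        assert structures_match(acid, parse_smiles("CC(=O)O"))
        assert structures_match(amine, parse_smiles("NC"))

    def test_condensation_inverts_hydrolysis(self):
        structure = parse_smiles("CC(=O)NC")
        target = find_targets(PEPTIDE_BOND, structure)[0]
        acyl_carbon, amide_nitrogen = target.atom1, target.atom2
        acid, amine = hydrolyse(structure, target)
        rebuilt = condense(acid, acyl_carbon, amine, amide_nitrogen)
        assert structures_match(rebuilt, structure)

    def test_ester_hydrolysis(self):
        ester = parse_smiles("CC(=O)OCC")
        defn = TargetDefinition("C(=O)OC", (0, 2), "ester bond")
        target = find_targets(defn, ester)[0]
        acid, alcohol = hydrolyse(ester, target)
        assert structures_match(acid, parse_smiles("CC(=O)O"))
        assert structures_match(alcohol, parse_smiles("OCC"))

    def test_plain_cc_bond_is_not_hydrolysable(self):
        s = parse_smiles("CCCC")
        with pytest.raises(StructureError):
            hydrolyse(s, s.bond_between(1, 2))

    def test_round_trip_on_fixture_amides(self):
        for i in range(10):
            smiles = f"CC{'C' * (i % 3)}C(=O)NC{'C' * (i % 4)}"
            structure = parse_smiles(smiles)
            target = find_targets(PEPTIDE_BOND, structure)[0]
            acid, amine = hydrolyse(structure, target)
            rebuilt = condense(acid, target.atom1, amine, target.atom2)
            assert structures_match(rebuilt, structure), smiles


class TestKetoreduction:
    BETA_KETO = TargetDefinition("CC(=O)C", (1, 2), "beta-keto bond")

    def test_reduction_yields_a_hydroxyl(self):
        substrate = parse_smiles("CC(=O)CC(=O)O")  # acetoacetic acid
        targets = find_targets(self.BETA_KETO, substrate)
        assert len(targets) == 1
        product = ketoreduce(substrate, targets[0])
        assert structures_match(product, parse_smiles("CC(O)CC(=O)O"))

    def test_product_is_annotated_for_highlighting(self):
        substrate = parse_smiles("CC(=O)CC(=O)O")
        target = find_targets(self.BETA_KETO, substrate)[0]
        product = ketoreduce(substrate, target)
        marked = [i for i in product.atoms
                  if product.get_annotation(i, "reduced")]
        elements = sorted(product.atom(i).element for i in marked)
        assert elements == ["C", "H", "H", "O"]

    def test_reapplying_to_the_product_fails(self):
        substrate = parse_smiles("CC(=O)CC")
        target = find_targets(self.BETA_KETO, substrate)[0]
        product = ketoreduce(substrate, target)
        with pytest.raises(StructureError):
            ketoreduce(product, target)

    def test_product_fingerprint_differs_from_substrate(self):
        substrate = parse_smiles("CC(=O)CC(=O)O")
        target = find_targets(self.BETA_KETO, substrate)[0]
        product = ketoreduce(substrate, target)
        assert ecfp(product).identifiers != ecfp(substrate).identifiers

    def test_non_carbonyl_target_rejected(self):
        s = parse_smiles("CC=CC")
        bond = next(b for b in s.bonds.values() if b.type == "double")
        with pytest.raises(StructureError):
            ketoreduce(s, bond)


class TestValidationInvariant:
    def test_every_builtin_output_revalidates(self):
        structure = parse_smiles("CC(=O)NCC(=O)OC")
        for defn in (PEPTIDE_BOND,
                     TargetDefinition("C(=O)OC", (0, 2), "ester")):
            for target in find_targets(defn, structure):
                for product in hydrolyse(structure, target):
                    product.refresh()
                    assert write_smiles(product)
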