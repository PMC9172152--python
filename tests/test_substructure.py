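import itertools

import pytest

from molkit import find_substructure_matches, parse_smiles
from molkit.substructure import structures_match


# ---------------------------------------------------------------- oracle
# Exhaustive embedding enumeration, written independently of the matcher:
# try every injective assignment of query heavy atoms to parent heavy atoms
# compatible with element/charge/aromaticity and bond types.

def _oracle_embeddings(sub, sup):
    sub_atoms = [a for a in sub.heavy_atoms()]
    sup_atoms = [a.index for a in sup.heavy_atoms()]
    sub_bonds = [
        b for b in sub.bonds.values()
        if sub.atom(b.atom1).is_heavy() and sub.atom(b.atom2).is_heavy()
    ]
    results = []
    for assignment in itertools.permutations(sup_atoms, len(sub_atoms)):
        mapping = {a.index: t for a, t in zip(sub_atoms, assignment)}
        ok = True
        for a, t in zip(sub_atoms, assignment):
            other = sup.atom(t)
            if (a.element, a.charge, a.aromatic) != (other.element,
                                                     other.charge,
                                                     other.aromatic):
                ok = False
                break
        if not ok:
            continue
        for bond in sub_bonds:
            sup_bond = sup.bond_between(mapping[bond.atom1],
                                        mapping[bond.atom2])
            if sup_bond is None or sup_bond.type != bond.type:
                ok = False
                break
        if ok:
            results.append(mapping)
    return results


def _oracle_parity(order_a, order_b):
    positions = [order_a.index(x) for x in order_b]
    swaps = 0
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if positions[i] > positions[j]:
                swaps += 1
    return swaps % 2


def _oracle_chiral_ok(sub, sup, mapping):
    for atom in sub.heavy_atoms():
        if atom.chiral is None or len(atom.chiral_order) != 4:
            continue
        target = sup.atom(mapping[atom.index])
        if target.chiral is None:
            return False
        sup_h = [a.index for a in sup.neighbours(target) if a.is_hydrogen()]
        mapped = []
        for nb in atom.chiral_order:
            if sub.atom(nb).is_hydrogen():
                if not sup_h:
                    return False
                mapped.append(sup_h.pop(0))
            else:
                mapped.append(mapping[nb])
        if set(mapped) != set(target.chiral_order):
            return False
        parity = _oracle_parity(target.chiral_order, mapped)
        if (atom.chiral == target.chiral) == bool(parity):
            return False
    return True


def _oracle_atom_sets(sub, sup, chiral=True):
    sets = set()
    for mapping in _oracle_embeddings(sub, sup):
        if chiral and not _oracle_chiral_ok(sub, sup, mapping):
            continue
        sets.add(frozenset(mapping.values()))
    return sets


ORACLE_PAIRS = [
    ("C(=O)NC", "CC(=O)NC"),
    ("C(=O)NC", "O=C1CNC(=O)CN1"),       # diketopiperazine, two amides
    ("C", "C"),
    ("CC", "CCC"),
    ("CCC", "C1CCCCC1"),
    ("c1ccccc1", "c1ccc2ccccc2c1"),
    ("CO", "OCC(O)CO"),
    ("C=C", "C=CC=C"),
    ("C(F)F", "FC(F)(F)C"),
    ("N[C@@H](C)C(=O)O", "N[C@@H](C)C(=O)O"),
    ("N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O"),   # epimer
    ("NC(C)C(=O)O", "N[C@@H](C)C(=O)O"),       # undefined query stereo
    ("CC(N)C", "CC(N)CC(N)C"),
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("sub_smiles, sup_smiles", ORACLE_PAIRS)
    def test_matches_equal_exhaustive_enumeration(self, sub_smiles,
                                                  sup_smiles):
        sub = parse_smiles(sub_smiles)
        sup = parse_smiles(sup_smiles)
        for chiral in (True, False):
            ours = {m.atoms for m in find_substructure_matches(
                sub, sup, match_chiral=chiral, match_cis_trans=False)}
            oracle = _oracle_atom_sets(sub, sup, chiral=chiral)
            assert ours == oracle, (sub_smiles, sup_smiles, chiral)

    def test_matches_equal_oracle_on_generated_pairs(self, fixture_smiles):
        # small-molecule pairs drawn from the seeded fixture batch
        small = [s for s in fixture_smiles
                 if len(parse_smiles(s).heavy_atoms()) <= 10][:8]
        fragments = ["C", "CC", "CO", "C=C", "CCC", "c1ccccc1", "N", "O"]
        for sup_smiles in small:
            sup = parse_smiles(sup_smiles)
            for sub_smiles in fragments:
                sub = parse_smiles(sub_smiles)
                ours = {m.atoms for m in find_substructure_matches(
                    sub, sup, match_cis_trans=False)}
                assert ours == _oracle_atom_sets(sub, sup), (sub_smiles,
                                                             sup_smiles)


class TestExamples:
    def test_amide_in_n_methylacetamide(self):
        matches = find_substructure_matches(parse_smiles("C(=O)NC"),
                                            parse_smiles("CC(=O)NC"))
        assert len(matches) == 1

    def test_identity_match(self):
        assert len(find_substructure_matches(parse_smiles("C"),
                                             parse_smiles("C"))) == 1

    def test_epimeric_centre_blocks_chiral_match(self):
        sub = parse_smiles("N[C@@H](C)C(=O)O")
        sup = parse_smiles("N[C@H](C)C(=O)O")
        assert find_substructure_matches(sub, sup, match_chiral=True) == []
        assert len(find_substructure_matches(sub, sup,
                                             match_chiral=False)) == 1

    def test_undefined_query_matches_defined_parent_not_vice_versa(self):
        plain = parse_smiles("NC(C)C(=O)O")
        defined = parse_smiles("N[C@@H](C)C(=O)O")
        assert len(find_substructure_matches(plain, defined)) == 1
        assert find_substructure_matches(defined, plain) == []

    def test_cis_query_rejects_trans_parent(self):
        cis = parse_smiles("F/C=C\\F")
        trans = parse_smiles("F/C=C/F")
        assert find_substructure_matches(cis, trans) == []
        assert len(find_substructure_matches(cis, trans,
                                             match_cis_trans=False)) == 1
        assert len(find_substructure_matches(cis, cis)) == 1

    def test_undefined_query_stereo_bond_matches_defined_parent(self):
        plain = parse_smiles("FC=CF")
        trans = parse_smiles("F/C=C/F")
        assert len(find_substructure_matches(plain, trans)) == 1
        assert find_substructure_matches(trans, plain) == []

    def test_chiral_matches_subset_of_achiral(self, parsed_corpus):
        sub = parse_smiles("N[C@@H](C)C(=O)O")
        for sup in parsed_corpus.values():
            with_chiral = {m.atoms for m in find_substructure_matches(
                sub, sup, match_chiral=True)}
            without = {m.atoms for m in find_substructure_matches(
                sub, sup, match_chiral=False)}
            assert with_chiral <= without

    def test_all_mappings_flag_keeps_symmetry_equivalents(self):
        sub = parse_smiles("CC")
        sup = parse_smiles("CC")
        one = find_substructure_matches(sub, sup)
        every = find_substructure_matches(sub, sup, all_mappings=True)
        assert len(one) == 1
        assert len(every) == 2


class TestStructuresMatch:
    def test_same_molecule_different_spelling(self):
        assert structures_match(parse_smiles("OCC"), parse_smiles("CCO"))

    def test_different_molecules(self):
        assert not structures_match(parse_smiles("CCO"), parse_smiles("CCN"))

    def test_enantiomers_differ_with_stereo_on(self):
        left = parse_smiles("N[C@H](C)C(=O)O")
        right = parse_smiles("N[C@@H](C)C(=O)O")
        assert not structures_match(left, right)
        assert structures_match(left, right, check_chirality=False)


class TestHighlight:
    def test_no_matches_leaves_the_render_unchanged(self):
        from molkit.drawing import render_svg
        from molkit.substructure import highlight_matches

        sup = parse_smiles("CC(=O)NC")
        plain = render_svg(highlight_matches(sup, [], "#00ff00"))
        import molkit.drawing as drawing_module
        base = render_svg(drawing_module.draw_molecule(sup))
        assert plain == base

    def test_single_match_recolours_its_atoms_and_bonds(self):
        from molkit.substructure import highlight_matches

        sup = parse_smiles("CC(=O)NC")
        matches = find_substructure_matches(parse_smiles("C(=O)NC"), sup)
        drawing = highlight_matches(sup, matches, "#ff0000")
        assert len(drawing.atom_colours) == 4
        assert set(drawing.atom_colours.values()) == {"#ff0000"}
        assert len(drawing.bond_colours) == 3

    def test_two_substructure_sets_two_colours(self):
        from molkit.drawing import render_svg
        from molkit.substructure import highlight_matches

        sup = parse_smiles("NCC(=O)NCC(=O)O")
        amide = find_substructure_matches(parse_smiles("C(=O)N"), sup)
        acid = find_substructure_matches(parse_smiles("C(=O)O"), sup)
        drawing = highlight_matches(sup, [amide, acid],
                                    ["#0000ff", "#00aa00"])
        svg = render_svg(drawing)
        assert "#0000ff" in svg and "#00aa00" in svg

    def test_unknown_colour_name_rejected(self):
        from molkit.substructure import highlight_matches

        sup = parse_smiles("CC")
        with pytest.raises(ValueError, match="colour"):
            highlight_matches(sup, [], "notacolour")
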