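import math

import numpy as np
import pytest

from molkit import parse_smiles
from molkit.drawing import (Drawing, DrawOptions, assign_wedges,
                            classify_rings, detect_clashes, draw_molecule,
                            finetune, layout, render_png, render_svg,
                            write_molfile)
from molkit.rings import kekulise


def _draw(smiles, **options):
    return draw_molecule(parse_smiles(smiles), DrawOptions(**options))


def _bond_vectors(drawing, centre):
    return [drawing.positions[nb.index] - drawing.positions[centre]
            for nb in drawing.structure.heavy_neighbours(centre)]


class TestClassifyRings:
    def test_cyclohexane_is_simple(self):
        ring_class = classify_rings(parse_smiles("C1CCCCC1"))
        assert list(ring_class.labels.values()) == ["simple"]

    def test_naphthalene_rings_overlap(self):
        ring_class = classify_rings(parse_smiles("c1ccc2ccccc2c1"))
        assert list(ring_class.labels.values()) == ["overlapping"] * 2

    def test_norbornane_is_bridged(self):
        ring_class = classify_rings(parse_smiles("C1CC2CCC1C2"))
        assert "bridged" in ring_class.labels.values()
        assert len(ring_class.bridged_systems) == 1

    def test_spiro_rings_are_overlapping(self):
        ring_class = classify_rings(parse_smiles("C1CCC2(CC1)CCCC2"))
        assert list(ring_class.labels.values()) == ["overlapping"] * 2


class TestLayout:
    def test_ethane_atoms_one_bond_length_apart(self):
        drawing = _draw("CC")
        distance = np.linalg.norm(drawing.positions[0] - drawing.positions[1])
        assert distance == pytest.approx(1.0, abs=1e-6)

    def test_neopentane_branches_at_right_angles(self):
        drawing = _draw("CC(C)(C)C")
        vectors = _bond_vectors(drawing, 1)
        assert len(vectors) == 4
        angles = sorted(
            round(math.degrees(math.acos(np.clip(
                np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)),
                -1, 1))))
            for i, a in enumerate(vectors) for b in vectors[i + 1:])
        assert angles == [90, 90, 90, 90, 180, 180]

    def test_chain_angles_near_120_degrees(self):
        drawing = _draw("CCCC")
        for centre in (1, 2):
            a, b = _bond_vectors(drawing, centre)
            angle = math.degrees(math.acos(np.clip(
                np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)),
                -1, 1)))
            assert angle == pytest.approx(120, abs=1)

    def test_bonded_distances_near_one(self, parsed_corpus):
        for smiles, structure in parsed_corpus.items():
            drawing = draw_molecule(structure)
            for bond in drawing.drawn_bonds():
                if {bond.atom1, bond.atom2} & drawing.kamada_kawai_atoms:
                    continue
                d = np.linalg.norm(drawing.positions[bond.atom1]
                                   - drawing.positions[bond.atom2])
                assert 0.8 <= d <= 1.2, (smiles, bond)

    def test_amino_group_drawn_cis_to_methyl(self):
        drawing = _draw("C/C=C(\\N)/C")
        s = drawing.structure
        bond = next(b for b in s.bonds.values() if b.type == "double")
        axis = drawing.positions[bond.atom2] - drawing.positions[bond.atom1]
        methyl = drawing.positions[0] - drawing.positions[bond.atom1]
        nitrogen = next(a.index for a in s.heavy_atoms()
                        if a.element == "N")
        amino = drawing.positions[nitrogen] - drawing.positions[bond.atom2]
        cross = lambda a, b: a[0] * b[1] - a[1] * b[0]
        assert np.sign(cross(axis, methyl)) == np.sign(cross(axis, amino))

    def test_declared_stereo_geometry_across_corpus(self, parsed_corpus):
        for smiles, structure in parsed_corpus.items():
            drawing = draw_molecule(structure)
            s = drawing.structure
            for bond in s.bonds.values():
                if bond.cis_trans is None or bond.stereo_atoms is None:
                    continue
                r1, r2 = bond.stereo_atoms
                if r1 not in drawing.positions or r2 not in drawing.positions:
                    continue
                axis = drawing.positions[bond.atom2] \
                    - drawing.positions[bond.atom1]
                v1 = drawing.positions[r1] - drawing.positions[bond.atom1]
                v2 = drawing.positions[r2] - drawing.positions[bond.atom2]
                s1 = np.sign(axis[0] * v1[1] - axis[1] * v1[0])
                s2 = np.sign(axis[0] * v2[1] - axis[1] * v2[0])
                same = s1 == s2
                assert same == (bond.cis_trans == "cis"), smiles


def _manual_drawing(smiles, coordinates):
    structure = kekulise(parse_smiles(smiles)) \
        if parse_smiles(smiles).aromatic_systems else parse_smiles(smiles)
    positions = {i: np.array(c, dtype=float)
                 for i, c in enumerate(coordinates)}
    return Drawing(structure=structure, positions=positions,
                   options=DrawOptions())


class TestDetectClashes:
    def test_non_neighbours_below_threshold_clash(self):
        drawing = _manual_drawing("CCC", [(0, 0), (1, 0), (0.3, 0.0)])
        assert detect_clashes(drawing) == [(0, 2)]

    def test_bonded_pair_exempt(self):
        drawing = _manual_drawing("CC", [(0, 0), (0.3, 0)])
        assert detect_clashes(drawing) == []

    def test_boundary_is_strictly_less_than(self):
        # mean bond length 1.0 after including the 0-1 and 1-2 bonds
        drawing = _manual_drawing(
            "CCC", [(0.0, 0.0), (1.0, 0.0), (0.0, 0.5)])
        mean = drawing.mean_bond_length()
        threshold = 0.5 * mean
        d02 = np.linalg.norm(drawing.positions[0] - drawing.positions[2])
        if abs(d02 - threshold) < 1e-9:
            assert detect_clashes(drawing) == []


class TestFinetune:
    def test_folded_chain_unfolds(self):
        # hexane folded back onto itself: atoms 4,5 overlap atoms 1,0
        coords = [(0, 0), (1, 0), (1.5, 0.87), (1, 1.73), (0.95, 0.1),
                  (0.05, 0.08)]
        drawing = _manual_drawing("CCCCCC", coords)
        before = len(detect_clashes(drawing))
        assert before >= 2
        finetune(drawing)
        assert len(detect_clashes(drawing)) == 0

    def test_clash_inside_rigid_ring_left_unchanged(self):
        coords = [(0, 0), (1, 0), (1.3, 0.9), (0.5, 1.5), (-0.3, 0.9),
                  (0.45, 0.45)]
        drawing = _manual_drawing("C1CCCC1C", coords[:6])
        # every bond on any clash path is cyclic except the exocyclic methyl
        before = detect_clashes(drawing)
        finetune(drawing)
        assert len(detect_clashes(drawing)) <= len(before)

    def test_idempotent_on_clash_free_drawing(self):
        drawing = _draw("CCCCCC")
        assert detect_clashes(drawing) == []
        positions = {i: p.copy() for i, p in drawing.positions.items()}
        finetune(drawing)
        for idx, pos in positions.items():
            assert np.allclose(pos, drawing.positions[idx])

    def test_never_increases_clashes_on_fixture_batch(self, fixture_smiles):
        for smiles in fixture_smiles:
            structure = parse_smiles(smiles)
            working = kekulise(structure) if structure.aromatic_systems \
                else structure
            drawing = layout(working, DrawOptions(finetune=False))
            before = len(detect_clashes(drawing))
            finetune(drawing)
            assert len(detect_clashes(drawing)) <= before, smiles


class TestWedges:
    def test_alanine_gets_exactly_one_wedge(self):
        drawing = _draw("N[C@@H](C)C(=O)O")
        assert len(drawing.wedges) == 1
        direction, centre = next(iter(drawing.wedges.values()))
        assert direction in ("up", "down")
        assert drawing.structure.atom(centre).chiral is not None

    def test_achiral_molecule_gets_no_wedges(self):
        assert _draw("CC(=O)NC").wedges == {}

    def test_ring_stereocentre_wedges_the_exocyclic_bond(self):
        drawing = _draw("C[C@H]1CCCCC1")
        assert len(drawing.wedges) == 1
        bond_idx, (direction, centre) = next(iter(drawing.wedges.items()))
        bond = drawing.structure.bond(bond_idx)
        methyl = bond.other(centre)
        assert len(drawing.structure.heavy_neighbours(methyl)) == 1

    def test_wedge_parity_matches_external_reader(self, parsed_corpus):
        rdkit_chem = pytest.importorskip("rdkit.Chem")

        def canon(smi):
            mol = rdkit_chem.MolFromSmiles(smi)
            return rdkit_chem.MolToSmiles(mol, isomericSmiles=True)

        for smiles, structure in parsed_corpus.items():
            if "@" not in smiles:
                continue
            drawing = draw_molecule(structure)
            mol = rdkit_chem.MolFromMolBlock(write_molfile(drawing))
            assert mol is not None, smiles
            got = rdkit_chem.MolToSmiles(mol, isomericSmiles=True)
            assert got == canon(smiles), smiles


class TestRender:
    def test_benzene_svg_has_lines_and_no_text(self):
        svg = render_svg(_draw("c1ccccc1"))
        assert svg.count("<line") == 9  # 3 single + 3 double bonds
        assert "<text" not in svg

    def test_custom_atom_colour_appears_on_its_glyph(self):
        drawing = _draw("c1ccncc1")
        nitrogen = next(a.index for a in drawing.structure.heavy_atoms()
                        if a.element == "N")
        drawing.atom_colours[nitrogen] = "#ff0000"
        svg = render_svg(drawing)
        assert svg.count('fill="#ff0000"') == 1

    def test_bond_length_to_font_ratio_constant_across_drawings(self):
        import re

        ratios = []
        for smiles in ("CCO", "c1ccc2ccccc2c1C(=O)O"):
            drawing = _draw(smiles)
            svg = render_svg(drawing)
            font = float(re.search(r'font-size="([\d.]+)"', svg).group(1))
            scale = drawing.options.scale
            ratios.append(drawing.mean_bond_length() * scale / font)
        assert ratios[0] == pytest.approx(ratios[1], rel=0.05)

    def test_png_written_and_loadable(self, tmp_path):
        from PIL import Image

        target = tmp_path / "mol.png"
        render_png(_draw("CC(=O)O"), str(target))
        with Image.open(target) as image:
            assert image.size[0] > 10 and image.size[1] > 10

    def test_hydrogens_shown_on_demand(self):
        hidden = _draw("C")
        shown = _draw("C", show_hydrogens=True)
        assert len(hidden.positions) == 1
        assert len(shown.positions) == 5


class TestMolfile:
    def test_ethanol_counts_line(self):
        text = write_molfile(_draw("CCO"))
        counts = text.splitlines()[3]
        assert counts.startswith("  3  2")

    def test_chiral_centre_writes_one_wedge_flag(self):
        text = write_molfile(_draw("N[C@@H](C)C(=O)O"))
        bond_lines = [line for line in text.splitlines()
                      if len(line) == 21 and line[:3].strip().isdigit()]
        flags = [int(line[9:12]) for line in bond_lines]
        assert sorted(f for f in flags if f) in ([1], [6])

    def test_charges_written_as_chg_lines(self):
        text = write_molfile(_draw("C[N+](=O)[O-]"))
        chg = [line for line in text.splitlines() if line.startswith("M  CHG")]
        assert len(chg) == 1
        assert " 4" in chg[0] or "-1" in chg[0]

    def test_round_trip_with_external_reader(self, parsed_corpus):
        rdkit_chem = pytest.importorskip("rdkit.Chem")

        def canon(smi):
            return rdkit_chem.MolToSmiles(rdkit_chem.MolFromSmiles(smi),
                                          isomericSmiles=True)

        failures = []
        for smiles, structure in parsed_corpus.items():
            drawing = draw_molecule(structure)
            mol = rdkit_chem.MolFromMolBlock(write_molfile(drawing))
            if mol is None or rdkit_chem.MolToSmiles(
                    mol, isomericSmiles=True) != canon(smiles):
                failures.append(smiles)
        assert failures == []

    def test_too_many_atoms_rejected(self):
        drawing = _draw("CC")
        drawing.positions = {i: np.array([float(i), 0.0])
                             for i in range(1000)}
        with pytest.raises(Exception):
            write_molfile(drawing)
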