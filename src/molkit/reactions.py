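"""Reactions as chemically validated graph edits.

Reaction targets are defined by a substructure SMILES plus one atom index
(atom target) or two bonded atom indices (bond target); occurrences are found
by substructure search and come back oriented the way the definition was
written. Primitive edits (break/make bonds, add/remove atoms) cap freed
valences with hydrogen by default; pass ``cap=None`` to chain several edits
before one validation pass. Built-ins: hydrolysis, condensation and
ketoreduction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_graph import BOND_ORDER, Bond, Structure, refresh_structure
from .errors import StructureError
from .smiles import parse_smiles
from .substructure import find_substructure_matches


@dataclass(frozen=True)
class TargetDefinition:
    """A reaction target inside a substructure.

    ``indices`` holds one heavy-atom index (atom target) or two (bond
    target), counting the substructure's heavy atoms in SMILES order.
    """

    smiles: str
    indices: tuple[int, ...]
    name: str = ""

    def __post_init__(self):
        if len(self.indices) not in (1, 2):
            raise ValueError("a target needs one or two atom indices")

    def substructure(self) -> Structure:
        sub = parse_smiles(self.smiles)
        heavy = sorted(a.index for a in sub.heavy_atoms())
        for index in self.indices:
            if index >= len(heavy):
                raise ValueError(
                    f"index {index} outside the substructure "
                    f"({len(heavy)} heavy atoms)")
        if len(self.indices) == 2:
            a, b = (heavy[i] for i in self.indices)
            if sub.bond_between(a, b) is None:
                raise ValueError("bond target atoms are not bonded in the "
                                 "substructure")
        return sub


@dataclass
class BondTarget:
    """A bond occurrence, oriented as (first, second) definition indices."""

    bond: Bond
    atom1: int
    atom2: int


def find_targets(definition: TargetDefinition, structure: Structure,
                 match_chiral: bool = True, match_cis_trans: bool = True):
    """All occurrences of the defined atom or bond in a superstructure.

    Returns a list of Atom objects for atom targets, or of
    :class:`BondTarget` for bond targets (one per substructure match).
    """
    sub = definition.substructure()
    heavy = sorted(a.index for a in sub.heavy_atoms())
    matches = find_substructure_matches(
        sub, structure, match_chiral=match_chiral,
        match_cis_trans=match_cis_trans)
    results = []
    for match in matches:
        if len(definition.indices) == 1:
            mapped = match.atom_map[heavy[definition.indices[0]]]
            results.append(structure.atom(mapped))
        else:
            a = match.atom_map[heavy[definition.indices[0]]]
            b = match.atom_map[heavy[definition.indices[1]]]
            bond = structure.bond_between(a, b)
            if bond is not None:
                results.append(BondTarget(bond, a, b))
    return results


# ------------------------------------------------------------ primitive edits

def break_bond(structure: Structure, bond: Bond | BondTarget,
               cap: str | None = "H") -> Structure:
    """Remove a bond; freed valence slots are capped (H per order unit by
    default). With ``cap=None`` validation is deferred to the caller."""
    if isinstance(bond, BondTarget):
        bond = bond.bond
    order = BOND_ORDER.get(bond.type)
    if order is None:
        raise StructureError(StructureError.BONDING,
                             "cannot break an aromatic bond directly; "
                             "kekulise first")
    atoms = bond.atoms()
    structure.remove_bond(bond)
    if cap:
        for idx in atoms:
            for _ in range(order):
                capper = structure.add_atom(cap)
                structure.add_bond(idx, capper.index, "single")
        refresh_structure(structure)
    return structure


def make_bond(structure: Structure, atom1: int, atom2: int,
              bond_type: str = "single", strip_hydrogens: bool = True
              ) -> Structure:
    """Create a bond; by default one hydrogen per order unit is removed from
    each end to keep valences legal."""
    order = BOND_ORDER[bond_type]
    if strip_hydrogens:
        for idx in (atom1, atom2):
            hydrogens = [a for a in structure.neighbours(idx)
                         if a.is_hydrogen()]
            if len(hydrogens) < order:
                raise StructureError(
                    StructureError.BONDING,
                    "not enough hydrogens to free the required valence")
            for h in hydrogens[:order]:
                structure.remove_atom(h)
    structure.add_bond(atom1, atom2, bond_type)
    if strip_hydrogens:
        refresh_structure(structure)
    return structure


def add_atom(structure: Structure, to_atom: int, element: str,
             bond_type: str = "single", validate: bool = True) -> Structure:
    """Attach a new atom to an existing one."""
    atom = structure.add_atom(element)
    structure.add_bond(to_atom, atom.index, bond_type)
    if validate:
        refresh_structure(structure)
    return structure


def remove_atom(structure: Structure, atom: int,
                cap: str | None = "H") -> Structure:
    """Delete an atom; each broken bond's open valence is capped."""
    severed = [(b.other(atom), BOND_ORDER.get(b.type, 1))
               for b in structure.bonds_of(atom)]
    for idx, _order in severed:  # hydrogens leave with their atom
        if structure.atom(idx).is_hydrogen():
            structure.remove_atom(idx)
    severed = [(idx, order) for idx, order in severed
               if idx in structure.atoms]
    structure.remove_atom(atom)
    if cap:
        for idx, order in severed:
            if structure.atom(idx).is_hydrogen():
                continue
            for _ in range(order):
                capper = structure.add_atom(cap)
                structure.add_bond(idx, capper.index, "single")
        refresh_structure(structure)
    return structure


def split_disconnected(structure: Structure) -> list[Structure]:
    """One Structure per connected component; indices and annotations are
    preserved."""
    components = structure.connected_components()
    if len(components) == 1:
        whole = structure.deep_copy()
        whole.refresh()
        return [whole]
    pieces = []
    for component in sorted(components, key=min):
        piece = Structure()
        piece.annotation_names = dict(structure.annotation_names)
        for idx in sorted(component):
            atom = structure.atom(idx)
            clone = piece.add_atom(atom.element, charge=atom.charge,
                                   aromatic=atom.aromatic, chiral=atom.chiral,
                                   explicit_h=atom.explicit_h, index=idx)
            clone.chiral_order = list(atom.chiral_order)
            clone.annotations = dict(atom.annotations)
        added = set()
        for idx in component:
            for bond in structure.bonds_of(idx):
                if bond.index in added:
                    continue
                added.add(bond.index)
                clone = piece.add_bond(bond.atom1, bond.atom2, bond.type,
                                       index=bond.index)
                clone.cis_trans = bond.cis_trans
                clone.stereo_atoms = bond.stereo_atoms
                clone.annotations = dict(bond.annotations)
        piece.refresh()
        pieces.append(piece)
    return pieces


# --------------------------------------------------------------- built-ins

def _acyl_orientation(structure: Structure, bond: Bond | BondTarget
                      ) -> tuple[Bond, int, int]:
    if isinstance(bond, BondTarget):
        return bond.bond, bond.atom1, bond.atom2
    return bond, bond.atom1, bond.atom2


def hydrolyse(structure: Structure, bond: Bond | BondTarget
              ) -> list[Structure]:
    """Split a hydrolysable single bond with water: OH goes to the side named
    first in the target definition, H to the leaving side."""
    working = structure.deep_copy()
    raw, first, second = _acyl_orientation(structure, bond)
    target = working.bond_between(first, second)
    if target is None or target.type != "single":
        raise StructureError(StructureError.BONDING,
                             "hydrolysis needs an existing single bond")
    first_atom = working.atom(first)
    second_atom = working.atom(second)
    acyl_like = any(
        b.type == "double" and working.atom(b.other(first)).element in
        ("O", "S")
        for b in working.bonds_of(first)
    )
    if not (acyl_like and second_atom.element in ("N", "O", "S")):
        raise StructureError(StructureError.BONDING,
                             f"bond {first_atom.element}-{second_atom.element}"
                             " is not hydrolysable")
    working.remove_bond(target)
    hydroxyl_o = working.add_atom("O")
    working.add_bond(first, hydroxyl_o.index, "single")
    hydroxyl_h = working.add_atom("H")
    working.add_bond(hydroxyl_o.index, hydroxyl_h.index, "single")
    leaving_h = working.add_atom("H")
    working.add_bond(second, leaving_h.index, "single")
    refresh_structure(working)
    pieces = split_disconnected(working)
    pieces.sort(key=lambda p: 0 if first in p.atoms else 1)
    return pieces


def condense(structure1: Structure, atom1: int, structure2: Structure,
             atom2: int) -> Structure:
    """Join two molecules with loss of water: a hydroxyl leaves ``atom1``, a
    hydrogen leaves ``atom2``, and a single bond is formed."""
    s1 = structure1.deep_copy()
    s2 = structure2.deep_copy()
    hydroxyl = None
    for nb in s1.neighbours(atom1):
        if nb.element != "O":
            continue
        bond = s1.bond_between(atom1, nb.index)
        if bond.type != "single":
            continue
        if any(a.is_hydrogen() for a in s1.neighbours(nb)):
            hydroxyl = nb
            break
    if hydroxyl is None:
        raise StructureError(StructureError.BONDING,
                             "no hydroxyl available for condensation")
    hydrogen = next((a for a in s2.neighbours(atom2) if a.is_hydrogen()),
                    None)
    if hydrogen is None:
        raise StructureError(StructureError.BONDING,
                             "no hydrogen available for condensation")
    for h in list(s1.neighbours(hydroxyl)):
        if h.is_hydrogen():
            s1.remove_atom(h)
            break
    s1.remove_atom(hydroxyl)
    s2.remove_atom(hydrogen)
    # merge s2 into s1 under fresh indices
    offset = s1._next_atom
    index_map = {}
    for idx in sorted(s2.atoms):
        atom = s2.atom(idx)
        clone = s1.add_atom(atom.element, charge=atom.charge,
                            aromatic=atom.aromatic, chiral=atom.chiral,
                            explicit_h=atom.explicit_h, index=offset + idx)
        clone.annotations = dict(atom.annotations)
        index_map[idx] = clone.index
    for bond in sorted(s2.bonds.values(), key=lambda b: b.index):
        clone = s1.add_bond(index_map[bond.atom1], index_map[bond.atom2],
                            bond.type)
        clone.cis_trans = bond.cis_trans
        if bond.stereo_atoms:
            clone.stereo_atoms = (index_map[bond.stereo_atoms[0]],
                                  index_map[bond.stereo_atoms[1]])
    for idx, atom in s2.atoms.items():
        if atom.chiral_order:
            s1.atom(index_map[idx]).chiral_order = [
                index_map[n] for n in atom.chiral_order]
    s1.add_bond(atom1, index_map[atom2], "single")
    for name, default in s2.annotation_names.items():
        if name not in s1.annotation_names:
            s1.annotation_names[name] = default
    refresh_structure(s1)
    return s1


def ketoreduce(structure: Structure, carbonyl_bond: Bond | BondTarget,
               annotation: str = "reduced") -> Structure:
    """Reduce a C=O double bond to a hydroxyl group.

    The pi electrons are removed, the bond becomes single, the carbon and
    oxygen are rehybridised to sp3 and each gains one hydrogen. The new
    hydroxyl group is annotated (``annotation=True``) for highlighting. The
    stereochemistry of the new alcohol carbon is left undefined.
    """
    raw, first, second = _acyl_orientation(structure, carbonyl_bond)
    working = structure.deep_copy()
    bond = working.bond_between(first, second)
    if bond is None or bond.type != "double":
        raise StructureError(StructureError.BONDING,
                             "ketoreduction target must be a double bond")
    elements = {working.atom(first).element, working.atom(second).element}
    if elements != {"C", "O"}:
        raise StructureError(StructureError.BONDING,
                             "ketoreduction target must be a C=O bond")
    bond.type = "single"
    carbon = first if working.atom(first).element == "C" else second
    oxygen = second if carbon == first else first
    new_atoms = []
    for idx in (carbon, oxygen):
        h = working.add_atom("H")
        working.add_bond(idx, h.index, "single")
        new_atoms.append(h.index)
    refresh_structure(working)
    if annotation not in working.annotation_names:
        working.annotate(annotation, False)
    for idx in (carbon, oxygen, *new_atoms):
        working.set_annotation(idx, annotation, True)
    bond.annotations[annotation] = True
    ch_bond = working.bond_between(carbon, new_atoms[0])
    oh_bond = working.bond_between(oxygen, new_atoms[1])
    for marked in (ch_bond, oh_bond):
        if marked is not None:
            marked.annotations[annotation] = True
    return working
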