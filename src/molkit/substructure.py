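"""Stereo-aware substructure matching with cheap pre-filters.

Matching proceeds in five stages, hydrogens ignored throughout:

1. element-count screen — every element of the query must be present in the
   parent in sufficient quantity;
2. local-environment screen — each query atom needs at least one parent atom
   with the same element/charge/aromaticity whose (bond type, neighbour
   element) multiset contains the query atom's;
3. seeded depth-first embedding ignoring stereo, starting from the query
   atom with the rarest connectivity signature in the parent;
4. tetrahedral-centre orientation check per embedding;
5. double-bond cis/trans check per embedding.

A query with undefined stereo matches a parent with defined stereo, but a
defined query stereocentre or stereobond never matches an undefined parent
one. Embeddings that cover the same parent atom set are collapsed to one
match unless all mappings are requested.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .chem_graph import Atom, Structure


@dataclass
class Match:
    """An injective, adjacency-preserving map of query atoms onto parent atoms."""

    atom_map: dict[int, int]
    bonds: set[int] = field(default_factory=set)  # parent bond indices

    @property
    def atoms(self) -> frozenset[int]:
        return frozenset(self.atom_map.values())


def _bond_compatible(sub_type: str, super_type: str) -> bool:
    return sub_type == super_type


def _atom_compatible(sub_atom: Atom, super_atom: Atom) -> bool:
    return (sub_atom.element == super_atom.element
            and sub_atom.charge == super_atom.charge
            and sub_atom.aromatic == super_atom.aromatic)


def _neighbour_profile(structure: Structure, atom: Atom) -> Counter:
    profile: Counter = Counter()
    for bond in structure.bonds_of(atom):
        other = structure.atom(bond.other(atom.index))
        if other.is_hydrogen():
            continue
        profile[(bond.type, other.element)] += 1
    return profile


def _signature(structure: Structure, atom: Atom) -> tuple:
    profile = _neighbour_profile(structure, atom)
    return (atom.element, sum(profile.values()),
            tuple(sorted(profile.items())))


def _element_screen(sub: Structure, sup: Structure) -> bool:
    need = Counter(a.element for a in sub.heavy_atoms())
    have = Counter(a.element for a in sup.heavy_atoms())
    return all(have[element] >= count for element, count in need.items())


def _environment_screen(sub: Structure, sup: Structure
                        ) -> dict[int, list[int]] | None:
    """Candidate parent atoms per query atom, or None when some query atom
    has no candidate at all."""
    candidates: dict[int, list[int]] = {}
    sup_heavy = sup.heavy_atoms()
    for sub_atom in sub.heavy_atoms():
        profile = _neighbour_profile(sub, sub_atom)
        pool = []
        for sup_atom in sup_heavy:
            if not _atom_compatible(sub_atom, sup_atom):
                continue
            sup_profile = _neighbour_profile(sup, sup_atom)
            if all(sup_profile[key] >= count
                   for key, count in profile.items()):
                pool.append(sup_atom.index)
        if not pool:
            return None
        candidates[sub_atom.index] = pool
    return candidates


def _pick_seed(sub: Structure, sup: Structure) -> int:
    """The query atom whose connectivity signature is rarest in the parent."""
    sup_signatures = Counter(
        _signature(sup, atom) for atom in sup.heavy_atoms())
    best = None
    for atom in sorted(sub.heavy_atoms(), key=lambda a: a.index):
        rarity = sup_signatures[_signature(sub, atom)]
        if best is None or rarity < best[0]:
            best = (rarity, atom.index)
    return best[1]


def _embeddings(sub: Structure, sup: Structure,
                candidates: dict[int, list[int]], seed: int
                ) -> list[dict[int, int]]:
    """All injective adjacency-preserving embeddings (stereo ignored)."""
    order = [seed]
    seen = {seed}
    # BFS order from the seed keeps each new atom adjacent to a mapped one
    queue = [seed]
    while queue:
        current = queue.pop(0)
        for nb in sorted(sub.heavy_neighbours(current), key=lambda a: a.index):
            if nb.index not in seen:
                seen.add(nb.index)
                order.append(nb.index)
                queue.append(nb.index)
    for atom in sub.heavy_atoms():  # disconnected query components
        if atom.index not in seen:
            seen.add(atom.index)
            order.append(atom.index)

    results: list[dict[int, int]] = []
    mapping: dict[int, int] = {}
    used: set[int] = set()

    def extend(position: int) -> None:
        if position == len(order):
            results.append(dict(mapping))
            return
        sub_idx = order[position]
        anchors = [
            (nb.index, sub.bond_between(sub_idx, nb.index))
            for nb in sub.heavy_neighbours(sub_idx)
            if nb.index in mapping
        ]
        pool = candidates[sub_idx]
        if anchors:
            anchor_idx, _ = anchors[0]
            pool = [a.index for a in sup.heavy_neighbours(mapping[anchor_idx])
                    if a.index in set(candidates[sub_idx])]
        for sup_idx in pool:
            if sup_idx in used:
                continue
            ok = True
            for nb_idx, sub_bond in anchors:
                sup_bond = sup.bond_between(sup_idx, mapping[nb_idx])
                if sup_bond is None or not _bond_compatible(sub_bond.type,
                                                            sup_bond.type):
                    ok = False
                    break
            if not ok:
                continue
            mapping[sub_idx] = sup_idx
            used.add(sup_idx)
            extend(position + 1)
            del mapping[sub_idx]
            used.discard(sup_idx)

    extend(0)
    return results


def _permutation_parity(reference: list[int], observed: list[int]) -> int:
    positions = [reference.index(x) for x in observed]
    swaps = 0
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if positions[i] > positions[j]:
                swaps += 1
    return swaps % 2


def _chirality_matches(sub: Structure, sup: Structure,
                       mapping: dict[int, int]) -> bool:
    for sub_atom in sub.heavy_atoms():
        if sub_atom.chiral is None:
            continue
        if len(sub_atom.chiral_order) != 4:
            continue
        sup_atom = sup.atom(mapping[sub_atom.index])
        if sup_atom.chiral is None or len(sup_atom.chiral_order) != 4:
            return False  # defined query stereo needs defined parent stereo
        # map the query's neighbour order into parent atoms; hydrogens act
        # as phantom lowest-priority neighbours
        sup_h = [a.index for a in sup.neighbours(sup_atom)
                 if a.is_hydrogen()]
        mapped: list[int] = []
        for nb in sub_atom.chiral_order:
            if sub.atom(nb).is_hydrogen():
                if not sup_h:
                    return False
                mapped.append(sup_h.pop(0))
            else:
                target = mapping.get(nb)
                if target is None:
                    # unmapped heavy query neighbour cannot happen: chiral
                    # centres require 4 mapped/hydrogen neighbours
                    return False
                mapped.append(target)
        if set(mapped) != set(sup_atom.chiral_order):
            # the parent centre has neighbours outside the match (e.g. a
            # heavy atom standing where the query has a hydrogen): compare
            # is only possible when the remaining slots pair up one-to-one
            extra_sup = [x for x in sup_atom.chiral_order if x not in mapped]
            free_slots = [i for i, x in enumerate(mapped) if x not in
                          sup_atom.chiral_order]
            if len(extra_sup) != len(free_slots):
                return False
            for slot, replacement in zip(free_slots, extra_sup):
                mapped[slot] = replacement
        parity = _permutation_parity(sup_atom.chiral_order, mapped)
        same_label = sub_atom.chiral == sup_atom.chiral
        if same_label == bool(parity):
            return False
    return True


def _cis_trans_matches(sub: Structure, sup: Structure,
                       mapping: dict[int, int]) -> bool:
    for sub_bond in sub.bonds.values():
        if sub_bond.type != "double" or sub_bond.cis_trans is None:
            continue
        if sub_bond.stereo_atoms is None:
            continue
        a1, a2 = mapping.get(sub_bond.atom1), mapping.get(sub_bond.atom2)
        if a1 is None or a2 is None:
            continue
        sup_bond = sup.bond_between(a1, a2)
        if sup_bond is None or sup_bond.cis_trans is None \
                or sup_bond.stereo_atoms is None:
            return False
        r1, r2 = sub_bond.stereo_atoms
        m1, m2 = mapping.get(r1), mapping.get(r2)
        if m1 is None or m2 is None:
            return False
        # align ends of the parent bond with the query bond
        if sup_bond.atom1 == a1:
            sup_r1, sup_r2 = sup_bond.stereo_atoms
        else:
            sup_r2, sup_r1 = sup_bond.stereo_atoms
        flips = 0
        for mapped_ref, sup_ref, end in ((m1, sup_r1, a1), (m2, sup_r2, a2)):
            if mapped_ref == sup_ref:
                continue
            # the mapped reference must at least be a substituent of the end
            if sup.bond_between(end, mapped_ref) is None:
                return False
            flips += 1
        effective = sup_bond.cis_trans
        if flips % 2:
            effective = "trans" if effective == "cis" else "cis"
        if effective != sub_bond.cis_trans:
            return False
    return True


def find_substructure_matches(sub: Structure, sup: Structure,
                              match_chiral: bool = True,
                              match_cis_trans: bool = True,
                              all_mappings: bool = False) -> list[Match]:
    """All occurrences of ``sub`` in ``sup`` (hydrogens ignored).

    By default one match is returned per covered parent atom set;
    ``all_mappings`` keeps every symmetry-equivalent embedding.
    """
    if not sub.heavy_atoms():
        return []
    if not _element_screen(sub, sup):
        return []
    candidates = _environment_screen(sub, sup)
    if candidates is None:
        return []
    seed = _pick_seed(sub, sup)
    embeddings = _embeddings(sub, sup, candidates, seed)
    matches: list[Match] = []
    seen_sets: set[frozenset[int]] = set()
    for mapping in embeddings:
        if match_chiral and not _chirality_matches(sub, sup, mapping):
            continue
        if match_cis_trans and not _cis_trans_matches(sub, sup, mapping):
            continue
        atom_set = frozenset(mapping.values())
        if not all_mappings and atom_set in seen_sets:
            continue
        seen_sets.add(atom_set)
        bonds = set()
        for sub_bond in sub.bonds.values():
            s1, s2 = mapping.get(sub_bond.atom1), mapping.get(sub_bond.atom2)
            if s1 is None or s2 is None:
                continue
            sup_bond = sup.bond_between(s1, s2)
            if sup_bond is not None:
                bonds.add(sup_bond.index)
        matches.append(Match(atom_map=mapping, bonds=bonds))
    matches.sort(key=lambda m: sorted(m.atom_map.values()))
    return matches


def structures_match(a: Structure, b: Structure,
                     check_chirality: bool = True,
                     check_cis_trans: bool = True) -> bool:
    """Whole-molecule graph isomorphism with labels, charge and stereo,
    realised as a size-equal substructure match in both directions."""
    heavy_a, heavy_b = a.heavy_atoms(), b.heavy_atoms()
    if len(heavy_a) != len(heavy_b) or len(a.atoms) != len(b.atoms):
        return False

    def heavy_bonds(s: Structure) -> int:
        return sum(1 for bond in s.bonds.values()
                   if s.atom(bond.atom1).is_heavy()
                   and s.atom(bond.atom2).is_heavy())

    if heavy_bonds(a) != heavy_bonds(b):
        return False
    forward = find_substructure_matches(a, b, match_chiral=check_chirality,
                                        match_cis_trans=check_cis_trans)
    if not forward:
        return False
    backward = find_substructure_matches(b, a, match_chiral=check_chirality,
                                         match_cis_trans=check_cis_trans)
    return bool(backward)


def highlight_matches(structure: Structure, matches, colours,
                      options=None):
    """Render-ready drawing with matched atoms/bonds recoloured.

    ``matches`` may be a single Match, a list of Matches, or a list of lists
    (one per substructure set); ``colours`` a single colour or a list aligned
    with the outer grouping. Later colours win on overlaps.
    """
    from . import drawing as drawing_module

    provided = [colours] if isinstance(colours, str) else list(colours)
    for colour in provided:
        drawing_module.parse_colour(colour)  # fail fast on unknown names
    if isinstance(matches, Match):
        groups = [[matches]]
    elif matches and isinstance(matches[0], Match):
        groups = [list(matches)]
    else:
        groups = [list(g) for g in matches]
    if isinstance(colours, str):
        colour_list = [colours] * len(groups)
    else:
        colour_list = list(colours)
        if len(colour_list) < len(groups):
            raise ValueError("fewer colours than substructure sets")
    drawing = drawing_module.draw_molecule(structure, options)
    for group, colour in zip(groups, colour_list):
        for match in group:
            for sup_idx in match.atom_map.values():
                drawing.atom_colours[sup_idx] = colour
            for bond_idx in match.bonds:
                drawing.bond_colours[bond_idx] = colour
    return drawing
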