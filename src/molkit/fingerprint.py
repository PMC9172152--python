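"""Extended-connectivity fingerprints (ECFP), Tanimoto similarity and
bit-vector featurisation.

Each heavy atom starts from a 32-bit identifier hashed from seven local
invariants (heavy-neighbour count, valence, atomic number, atomic weight,
charge, hydrogen-neighbour count, ring membership). Identifiers are then
iteratively rehashed with the sorted identifiers of direct neighbours and a
bond-order tag, for ``radius`` rounds (default 2, i.e. ECFP-4). Chiral
centres mix in a canonical handedness tag once their neighbours are
distinguishable. Duplicate identifiers and identifiers that cover the same
atom-set substructure are removed.

Hashes are truncated SHA-256 digests of a canonical byte serialisation, so
fingerprints are stable across runs and platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import periodic, rings
from .chem_graph import Structure

_BOND_TAG = {"single": 1, "double": 2, "triple": 3, "quadruple": 4,
             "aromatic": 5}


def _hash32(parts: tuple) -> int:
    payload = repr(parts).encode("utf8")
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big")


@dataclass
class Fingerprint:
    """A set of 32-bit substructure identifiers with provenance."""

    identifiers: set[int] = field(default_factory=set)
    # identifier -> (central atom index, radius, frozenset of atom indices)
    provenance: dict[int, tuple[int, int, frozenset[int]]] = field(
        default_factory=dict)

    def __len__(self) -> int:
        return len(self.identifiers)

    def __contains__(self, identifier: int) -> bool:
        return identifier in self.identifiers


def initial_atom_invariant(structure: Structure, atom) -> int:
    """Stable 32-bit hash of the seven ECFP atom invariants."""
    atom = structure.atom(atom) if isinstance(atom, int) else atom
    heavy = len(structure.heavy_neighbours(atom))
    hydrogens = structure.hydrogen_count(atom)
    in_ring = rings.atom_in_ring(structure, atom.index)
    weight = round(periodic.atomic_weight(atom.element), 2)
    return _hash32((
        heavy,
        atom.valency,
        atom.atomic_number,
        f"{weight:.2f}",
        atom.charge,
        hydrogens,
        int(in_ring),
    ))


def _environment_atoms(structure: Structure, center: int,
                       radius: int) -> frozenset[int]:
    """Heavy atoms within graph distance ``radius`` of the centre."""
    frontier = {center}
    seen = {center}
    for _ in range(radius):
        new = set()
        for idx in frontier:
            for nb in structure.heavy_neighbours(idx):
                if nb.index not in seen:
                    new.add(nb.index)
        seen |= new
        frontier = new
    return frozenset(seen)


def _chiral_tag(structure: Structure, atom, ids: dict[int, int]) -> int | None:
    """Canonical handedness (1 or 2) independent of input atom order, or
    None while neighbours are not yet distinguishable."""
    if atom.chiral is None or len(atom.chiral_order) != 4:
        return None
    ranked = []
    for nb in atom.chiral_order:
        if nb not in structure.atoms:
            return None
        nb_atom = structure.atom(nb)
        ranked.append(-1 if nb_atom.is_hydrogen() else ids.get(nb, -1))
    if len(set(ranked)) != len(ranked):
        return None
    reference = [n for _, n in sorted(zip(ranked, atom.chiral_order))]
    swaps = 0
    order = [reference.index(n) for n in atom.chiral_order]
    for i in range(4):
        for j in range(i + 1, 4):
            if order[i] > order[j]:
                swaps += 1
    clockwise = atom.chiral == "clockwise"
    if swaps % 2:
        clockwise = not clockwise
    return 1 if clockwise else 2


def ecfp(structure: Structure, radius: int = 2) -> Fingerprint:
    """ECFP fingerprint of a validated structure (radius 2 = ECFP-4)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    heavy = sorted(a.index for a in structure.heavy_atoms())
    ids = {idx: initial_atom_invariant(structure, idx) for idx in heavy}
    # environments: (identifier, centre, radius, atom set)
    environments: list[tuple[int, int, int, frozenset[int]]] = [
        (ids[idx], idx, 0, frozenset((idx,))) for idx in heavy
    ]
    for r in range(1, radius + 1):
        updated = {}
        for idx in heavy:
            atom = structure.atom(idx)
            pairs = []
            for bond in structure.bonds_of(idx):
                other = structure.atom(bond.other(idx))
                if other.is_hydrogen():
                    continue
                pairs.append((_BOND_TAG[bond.type], ids[other.index]))
            pairs.sort()
            parts: tuple = (r, ids[idx], tuple(pairs))
            tag = _chiral_tag(structure, atom, ids)
            if tag is not None:
                parts = parts + (tag,)
            updated[idx] = _hash32(parts)
            environments.append(
                (updated[idx], idx, r, _environment_atoms(structure, idx, r)))
        ids = updated
    # dedup: drop equal identifiers, and distinct identifiers covering the
    # same atom set (keep the one generated at smaller radius, then the
    # smaller identifier)
    best_for_set: dict[frozenset[int], tuple[int, int, int, frozenset[int]]] = {}
    for env in environments:
        identifier, _centre, r, atom_set = env
        current = best_for_set.get(atom_set)
        if current is None or (r, identifier) < (current[2], current[0]):
            best_for_set[atom_set] = env
    fingerprint = Fingerprint()
    for env in best_for_set.values():
        identifier, centre, r, atom_set = env
        fingerprint.identifiers.add(identifier)
        existing = fingerprint.provenance.get(identifier)
        if existing is None or (r, len(atom_set)) < (existing[1],
                                                     len(existing[2])):
            fingerprint.provenance[identifier] = (centre, r, atom_set)
    return fingerprint


def tanimoto(a: Fingerprint | set[int], b: Fingerprint | set[int]) -> float:
    """Jaccard/Tanimoto similarity |A n B| / |A u B| (1.0 for two empties)."""
    set_a = a.identifiers if isinstance(a, Fingerprint) else set(a)
    set_b = b.identifiers if isinstance(b, Fingerprint) else set(b)
    if not set_a and not set_b:
        return 1.0
    return len(set_a & set_b) / len(set_a | set_b)


def tanimoto_distance(a, b) -> float:
    return 1.0 - tanimoto(a, b)


def _fragment_smiles(structure: Structure, atom_set: frozenset[int]) -> str:
    """A loose SMILES-like serialisation of an induced heavy-atom subgraph,
    used in fingerprint legends (no valence completion is implied)."""
    atoms = sorted(atom_set)
    symbol_for = {"double": "=", "triple": "#", "quadruple": "$",
                  "single": "", "aromatic": ""}
    # pre-pass: spanning tree + back edges so ring digits appear at both ends
    tree: dict[int, list[int]] = {}
    back_edges: dict[int, list[int]] = {}
    visited: set[int] = set()

    def explore(idx: int, parent: int | None) -> None:
        visited.add(idx)
        tree[idx] = []
        for bond in structure.bonds_of(idx):
            other = bond.other(idx)
            if other not in atom_set or other == parent:
                continue
            if other in visited:
                if idx not in back_edges.get(other, ()):
                    back_edges.setdefault(idx, []).append(other)
                    back_edges.setdefault(other, []).append(idx)
            else:
                tree[idx].append(other)
                explore(other, idx)

    roots = []
    for idx in atoms:
        if idx not in visited:
            roots.append(idx)
            explore(idx, None)

    digit_of: dict[frozenset[int], int] = {}
    counter = [0]

    def emit(idx: int) -> str:
        atom = structure.atom(idx)
        token = atom.element.lower() if atom.aromatic else atom.element
        if atom.element not in periodic.ORGANIC_SUBSET or atom.charge:
            charge = ""
            if atom.charge:
                sign = "+" if atom.charge > 0 else "-"
                charge = sign if abs(atom.charge) == 1 else f"{atom.charge:+d}"
            token = f"[{token}{charge}]"
        text = token
        for other in back_edges.get(idx, ()):
            key = frozenset((idx, other))
            if key not in digit_of:
                counter[0] += 1
                digit_of[key] = counter[0]
            bond = structure.bond_between(idx, other)
            text += symbol_for[bond.type] + str(digit_of[key] % 10)
        children = tree.get(idx, [])
        for i, child in enumerate(children):
            bond = structure.bond_between(idx, child)
            sub = symbol_for[bond.type] + emit(child)
            text += f"({sub})" if i < len(children) - 1 else sub
        return text

    return ".".join(emit(root) for root in roots)


def to_bit_vectors(structures: list[Structure], length: int = 1024,
                   radius: int = 2):
    """Fold fingerprints into fixed-length 0/1 rows plus a legend.

    Returns ``(matrix, legend)``: an ``(n, length)`` int array with bit ``i``
    set iff some identifier is congruent to ``i`` modulo ``length``, and a
    dict mapping each set bit to a representative substructure string.
    """
    if length <= 0:
        raise ValueError("bit-vector length must be positive")
    matrix = np.zeros((len(structures), length), dtype=np.int8)
    legend: dict[int, str] = {}
    for row, structure in enumerate(structures):
        fingerprint = ecfp(structure, radius=radius)
        for identifier in fingerprint.identifiers:
            bit = identifier % length
            matrix[row, bit] = 1
            if bit not in legend:
                _centre, _r, atom_set = fingerprint.provenance[identifier]
                legend[bit] = _fragment_smiles(structure, atom_set)
    return matrix, legend
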