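"""Ring perception: simple-cycle enumeration, SSSR, aromaticity, kekulisation.

Aromaticity follows a per-cycle Hueckel test applied recursively over the
SSSR: a candidate cycle must consist of sp2 atoms (or sp3 atoms with a
delocalisable lone pair), and is aromatic when the number of in-cycle double
bonds (counting locally kekulised aromatic stretches) plus contributed lone
pairs is odd — equivalent to 4n+2 pi electrons. Marking one cycle aromatic
can enable a neighbouring cycle in the next round; iteration stops when the
aromatic cycle count is stable. Kekulisation assigns alternating double
bonds through a maximum matching (Edmonds blossom) over pi-contributing
atoms of each aromatic system.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .chem_graph import AromaticSystem, Structure
from .errors import StructureError

#: Abort cycle enumeration beyond this many cycles (fullerene-like inputs).
DEFAULT_CYCLE_CEILING = 10 ** 6
_STEP_CEILING = 10 ** 7


class CycleOverflowError(StructureError):
    def __init__(self, ceiling: int):
        super().__init__(
            StructureError.BONDING,
            f"simple-cycle count exceeds the enumeration ceiling ({ceiling}); "
            "highly recursive cage structures are not supported")


@dataclass
class RingSet:
    """All ring information of one structure."""

    simple_cycles: list[tuple[int, ...]] = field(default_factory=list)
    sssr: list[tuple[int, ...]] = field(default_factory=list)
    aromatic_cycles: list[tuple[int, ...]] = field(default_factory=list)
    atom_rings: dict[int, list[int]] = field(default_factory=dict)  # atom -> sssr ids

    def atom_in_ring(self, atom_index: int) -> bool:
        return bool(self.atom_rings.get(atom_index))

    def bond_in_ring(self, structure: Structure, bond) -> bool:
        ring_ids_1 = set(self.atom_rings.get(bond.atom1, ()))
        ring_ids_2 = set(self.atom_rings.get(bond.atom2, ()))
        for rid in ring_ids_1 & ring_ids_2:
            ring = self.sssr[rid]
            k = len(ring)
            for i in range(k):
                a, b = ring[i], ring[(i + 1) % k]
                if {a, b} == {bond.atom1, bond.atom2}:
                    return True
        # A bond may be cyclic without being in an SSSR ring edge list only
        # in exotic bridged systems; fall back to the simple cycles.
        for cycle in self.simple_cycles:
            k = len(cycle)
            for i in range(k):
                if {cycle[i], cycle[(i + 1) % k]} == {bond.atom1, bond.atom2}:
                    return True
        return False


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Canonical form up to rotation and reflection: start at the smallest
    atom and walk toward its smaller neighbour."""
    k = len(cycle)
    start = cycle.index(min(cycle))
    forward = tuple(cycle[(start + i) % k] for i in range(k))
    backward = tuple(cycle[(start - i) % k] for i in range(k))
    return min(forward, backward)


def enumerate_simple_cycles(structure: Structure,
                            ceiling: int = DEFAULT_CYCLE_CEILING
                            ) -> list[tuple[int, ...]]:
    """Every elementary cycle of length >= 3, once up to rotation/reflection.

    Each cycle is found rooted at its smallest atom index by a depth-first
    search confined to atoms with larger indices; the two traversal
    directions are collapsed by requiring the second atom to be smaller than
    the last.
    """
    adjacency = {
        idx: sorted(n.index for n in structure.neighbours(idx))
        for idx in structure.atoms
    }
    cycles: list[tuple[int, ...]] = []
    steps = 0
    for root in sorted(structure.atoms):
        path = [root]
        on_path = {root}

        def dfs(current: int) -> None:
            nonlocal steps
            steps += 1
            if steps > _STEP_CEILING or len(cycles) > ceiling:
                raise CycleOverflowError(ceiling)
            for nb in adjacency[current]:
                if nb == root and len(path) >= 3:
                    if path[1] < path[-1]:
                        cycles.append(tuple(path))
                elif nb > root and nb not in on_path:
                    path.append(nb)
                    on_path.add(nb)
                    dfs(nb)
                    path.pop()
                    on_path.remove(nb)

        dfs(root)
    return [_canonical_cycle(list(c)) for c in cycles]


def _cycle_bond_mask(structure: Structure, cycle: tuple[int, ...]) -> int:
    mask = 0
    k = len(cycle)
    for i in range(k):
        bond = structure.bond_between(cycle[i], cycle[(i + 1) % k])
        if bond is None:
            raise StructureError(StructureError.BONDING,
                                 "cycle references a missing bond")
        mask |= 1 << bond.index
    return mask


def cyclomatic_number(structure: Structure) -> int:
    components = structure.connected_components()
    return len(structure.bonds) - len(structure.atoms) + len(components)


def find_sssr(structure: Structure,
              simple_cycles: list[tuple[int, ...]] | None = None
              ) -> list[tuple[int, ...]]:
    """Smallest set of smallest rings: a minimum cycle basis chosen greedily
    smallest-first from the simple cycles, ties broken by the
    lexicographically smallest sorted atom tuple."""
    if simple_cycles is None:
        simple_cycles = enumerate_simple_cycles(structure)
    target = cyclomatic_number(structure)
    if target <= 0:
        return []
    ordered = sorted(simple_cycles, key=lambda c: (len(c), tuple(sorted(c))))
    basis: list[int] = []  # reduced bond masks
    chosen: list[tuple[int, ...]] = []
    for cycle in ordered:
        vector = _cycle_bond_mask(structure, cycle)
        for reduced in basis:
            vector = min(vector, vector ^ reduced)
        if vector:
            basis.append(vector)
            chosen.append(cycle)
            if len(chosen) == target:
                break
    return chosen


def ensure_ring_data(structure: Structure) -> RingSet:
    """Compute (or return cached) ring information for a structure."""
    if structure.ring_data is None:
        cycles = enumerate_simple_cycles(structure)
        sssr = find_sssr(structure, cycles)
        atom_rings: dict[int, list[int]] = {}
        for rid, ring in enumerate(sssr):
            for atom in ring:
                atom_rings.setdefault(atom, []).append(rid)
        # atoms cyclic but outside the chosen basis rings still count as
        # in-ring for invariants/fingerprints
        for cycle in cycles:
            for atom in cycle:
                atom_rings.setdefault(atom, [])
        structure.ring_data = RingSet(simple_cycles=cycles, sssr=sssr,
                                      atom_rings=atom_rings)
    return structure.ring_data


def atom_in_ring(structure: Structure, atom_index: int) -> bool:
    rings = ensure_ring_data(structure)
    return any(atom_index in cycle for cycle in rings.simple_cycles)


# --------------------------------------------------------------- aromaticity

def _cycle_bonds(structure: Structure, cycle: tuple[int, ...]):
    k = len(cycle)
    return [structure.bond_between(cycle[i], cycle[(i + 1) % k]) for i in range(k)]


def _atom_is_candidate(structure: Structure, atom) -> bool:
    if atom.aromatic_pi or atom.aromatic_lone_pair:
        return True
    if atom.hybridisation == "sp2":
        return True
    return atom.hybridisation == "sp3" and atom.lone_pairs >= 1


def _huckel_count(structure: Structure, cycle: tuple[int, ...]) -> int | None:
    """Double bonds (after local kekulisation of aromatic stretches) plus
    contributed lone pairs, or None when the cycle cannot be aromatic."""
    atoms = [structure.atom(i) for i in cycle]
    if any(not _atom_is_candidate(structure, a) for a in atoms):
        return None
    bonds = _cycle_bonds(structure, cycle)
    if any(b is None for b in bonds):
        return None
    used: set[int] = set()
    doubles = 0
    for bond in bonds:
        if bond.type == "double":
            doubles += 1
            used.add(bond.atom1)
            used.add(bond.atom2)
        elif bond.type not in ("single", "aromatic"):
            return None  # triple/quadruple bonds break planarity
    # local kekulisation of aromatic stretches: a maximum matching over the
    # unused pi-capable atoms along the cycle gives the double-bond count
    capable = [
        a.index for a in atoms
        if a.index not in used and a.aromatic_pi
    ]
    if capable:
        position = {idx: i for i, idx in enumerate(capable)}
        adjacency: list[list[int]] = [[] for _ in capable]
        for bond in bonds:
            if bond.type != "aromatic":
                continue
            if bond.atom1 in position and bond.atom2 in position:
                adjacency[position[bond.atom1]].append(position[bond.atom2])
                adjacency[position[bond.atom2]].append(position[bond.atom1])
        match = maximum_matching(len(capable), adjacency)
        doubles += sum(1 for m in match if m != -1) // 2
        used.update(capable[i] for i, m in enumerate(match) if m != -1)
    lone_pair_donors = 0
    for atom in atoms:
        if atom.index in used or atom.aromatic_pi:
            continue
        if atom.aromatic_lone_pair:
            lone_pair_donors += 1
        elif atom.hybridisation == "sp3" and atom.lone_pairs >= 1:
            lone_pair_donors += 1  # at most one lone pair per atom counts
    return doubles + lone_pair_donors


def _mark_aromatic(structure: Structure, cycle: tuple[int, ...]) -> None:
    bonds = _cycle_bonds(structure, cycle)
    for bond in bonds:
        if bond.type == "double":
            for idx in (bond.atom1, bond.atom2):
                atom = structure.atom(idx)
                if not atom.aromatic_pi:
                    atom.aromatic_pi = 1
                    atom.pi_count = max(0, atom.pi_count - 1)
        bond.type = "aromatic"
        bond.aromatic = True
    for idx in cycle:
        atom = structure.atom(idx)
        atom.aromatic = True
        if not atom.aromatic_pi and not atom.aromatic_lone_pair:
            if atom.hybridisation == "sp3" and atom.lone_pairs >= 1:
                atom.aromatic_lone_pair = 1  # promoted into a p orbital


def detect_aromaticity(structure: Structure) -> RingSet:
    """Recursive per-cycle Hueckel perception; fills aromatic systems."""
    rings = ensure_ring_data(structure)
    aromatic: list[tuple[int, ...]] = []
    pending = list(rings.sssr)
    for _round in range(max(1, len(rings.sssr))):
        newly = []
        for cycle in pending:
            count = _huckel_count(structure, cycle)
            if count is not None and count % 2 == 1:
                newly.append(cycle)
        if not newly:
            break
        for cycle in newly:
            _mark_aromatic(structure, cycle)
            aromatic.append(cycle)
        pending = [c for c in pending if c not in aromatic]
    rings.aromatic_cycles = aromatic
    _resolve_unperceived_aromatic_bonds(structure, aromatic)
    structure.aromatic_systems = _build_aromatic_systems(structure, aromatic)
    structure.aromaticity_done = True
    return rings


def _resolve_unperceived_aromatic_bonds(structure: Structure,
                                        aromatic: list[tuple[int, ...]]) -> None:
    """Demote input-aromatic bonds that join two aromatic rings without being
    in a ring themselves (biphenyl-style); reject rings that were written
    aromatic but fail the Hueckel test."""
    aromatic_bond_ids: set[int] = set()
    for cycle in aromatic:
        for bond in _cycle_bonds(structure, cycle):
            aromatic_bond_ids.add(bond.index)
    rings = structure.ring_data
    for bond in structure.bonds.values():
        if bond.type != "aromatic" or bond.index in aromatic_bond_ids:
            continue
        if rings is not None and rings.bond_in_ring(structure, bond):
            raise StructureError(StructureError.BONDING,
                                 "aromatic ring fails the Hueckel test")
        bond.type = "single"
        bond.aromatic = False


def _build_aromatic_systems(structure: Structure,
                            aromatic: list[tuple[int, ...]]
                            ) -> list[AromaticSystem]:
    if not aromatic:
        return []
    bond_sets = []
    for cycle in aromatic:
        bond_sets.append({b.index for b in _cycle_bonds(structure, cycle)})
    parent = list(range(len(aromatic)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(aromatic)):
        for j in range(i + 1, len(aromatic)):
            if bond_sets[i] & bond_sets[j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(aromatic)):
        groups.setdefault(find(i), []).append(i)
    systems = []
    for members in groups.values():
        atoms: set[int] = set()
        bonds: set[int] = set()
        for m in members:
            atoms.update(aromatic[m])
            bonds.update(bond_sets[m])
        electrons = 0
        for idx in atoms:
            atom = structure.atom(idx)
            electrons += atom.aromatic_pi + 2 * atom.aromatic_lone_pair
        systems.append(AromaticSystem(atoms, bonds, electrons))
    return systems


# --------------------------------------------------------- maximum matching

def maximum_matching(n: int, adjacency: list[list[int]]) -> list[int]:
    """Maximum cardinality matching in a general graph (Edmonds blossom).

    ``adjacency`` maps vertex 0..n-1 to neighbour lists; returns ``match``
    with match[v] = partner or -1.
    """
    match = [-1] * n
    p = [-1] * n
    base = list(range(n))
    used = [False] * n
    blossom = [False] * n

    def lca(a: int, b: int) -> int:
        visited = [False] * n
        while True:
            a = base[a]
            visited[a] = True
            if match[a] == -1:
                break
            a = p[match[a]]
        while True:
            b = base[b]
            if visited[b]:
                return b
            b = p[match[b]]

    def mark_path(v: int, b: int, child: int) -> None:
        while base[v] != b:
            blossom[base[v]] = True
            blossom[base[match[v]]] = True
            p[v] = child
            child = match[v]
            v = p[match[v]]

    def find_path(root: int) -> int:
        for i in range(n):
            used[i] = False
            p[i] = -1
            base[i] = i
        used[root] = True
        queue = deque([root])
        while queue:
            v = queue.popleft()
            for to in adjacency[v]:
                if base[v] == base[to] or match[v] == to:
                    continue
                if to == root or (match[to] != -1 and p[match[to]] != -1):
                    curbase = lca(v, to)
                    for i in range(n):
                        blossom[i] = False
                    mark_path(v, curbase, to)
                    mark_path(to, curbase, v)
                    for i in range(n):
                        if blossom[base[i]]:
                            base[i] = curbase
                            if not used[i]:
                                used[i] = True
                                queue.append(i)
                elif p[to] == -1:
                    p[to] = v
                    if match[to] == -1:
                        return to
                    used[match[to]] = True
                    queue.append(match[to])
        return -1

    for v in range(n):
        if match[v] == -1:
            u = find_path(v)
            while u != -1:
                pv = p[u]
                ppv = match[pv]
                match[u] = pv
                match[pv] = u
                u = ppv
    return match


def kekulise(structure: Structure) -> Structure:
    """Return a copy in which every aromatic system carries alternating
    single/double bonds via a maximum matching over pi-contributing atoms."""
    kekulised = structure.deep_copy()
    for system in list(kekulised.aromatic_systems):
        pi_atoms = sorted(
            idx for idx in system.atoms if kekulised.atom(idx).aromatic_pi
        )
        position = {idx: i for i, idx in enumerate(pi_atoms)}
        adjacency: list[list[int]] = [[] for _ in pi_atoms]
        for bond_idx in system.bonds:
            bond = kekulised.bond(bond_idx)
            if bond.atom1 in position and bond.atom2 in position:
                adjacency[position[bond.atom1]].append(position[bond.atom2])
                adjacency[position[bond.atom2]].append(position[bond.atom1])
        match = maximum_matching(len(pi_atoms), adjacency)
        if any(m == -1 for m in match):
            raise StructureError(StructureError.BONDING,
                                 "kekulisation failed: no perfect matching "
                                 "over pi-contributing atoms")
        matched_pairs = {
            frozenset((pi_atoms[i], pi_atoms[m]))
            for i, m in enumerate(match)
        }
        for bond_idx in system.bonds:
            bond = kekulised.bond(bond_idx)
            if frozenset((bond.atom1, bond.atom2)) in matched_pairs:
                bond.type = "double"
            else:
                bond.type = "single"
            bond.aromatic = True  # record of the perceived system
        for idx in system.atoms:
            atom = kekulised.atom(idx)
            atom.aromatic_pi = 0
            atom.aromatic_lone_pair = 0
    kekulised.aromatic_systems = []
    ring_data = kekulised.ring_data  # topology unchanged by retyping bonds
    kekulised._invalidate_caches()
    kekulised.refresh(perceive_aromaticity=False)
    kekulised.ring_data = ring_data
    return kekulised
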