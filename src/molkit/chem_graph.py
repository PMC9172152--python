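"""Core molecular graph: atoms, bonds, electron bookkeeping and validation.

A :class:`Structure` is an undirected labelled graph whose nodes are
:class:`Atom` objects (hydrogens included, as real nodes) and whose edges are
:class:`Bond` objects. Electron shells are kept per heavy atom so that
valence validation is a physical statement — an atom can only form as many
bonds as it can supply unpaired electrons for, after excitation within its
valence shell. Aromatic electrons are not localised on atoms; they live in
:class:`AromaticSystem` pools.
"""

from __future__ import annotations

import copy
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

from .errors import StructureError
from . import periodic

BOND_ORDER = {"single": 1, "double": 2, "triple": 3, "quadruple": 4}

HYBRIDISATION_BY_STERIC = {0: "s", 1: "s", 2: "sp", 3: "sp2", 4: "sp3",
                           5: "sp3d", 6: "sp3d2"}


class Orbital:
    """One atomic orbital: at most two electrons, each tagged with a role.

    Roles: 'core' (non-valence), 'lone' (valence lone pair), 'sigma', 'pi'
    and 'aromatic' (delegated to an aromatic system pool).
    """

    __slots__ = ("n", "subshell", "electrons")

    def __init__(self, n: int, subshell: str):
        self.n = n
        self.subshell = subshell
        self.electrons: list[str] = []

    @property
    def occupancy(self) -> int:
        return len(self.electrons)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Orbital({self.n}{self.subshell}:{self.electrons})"


class ElectronConfiguration:
    """Electron shells of one atom, with bonding roles assigned.

    The valence shell is modelled with s/p (and d from n=3) orbitals; bonding
    requires one unpaired electron per bond order unit, obtained by exciting
    paired valence electrons into empty valence orbitals. If the valence
    shell cannot host the required number of unpaired electrons plus the
    remaining lone pairs, basic bonding laws are violated.
    """

    def __init__(self, element: str):
        self.element = element
        self.orbitals: list[Orbital] = []
        self._build()

    def _build(self) -> None:
        z = periodic.atomic_number(self.element)
        remaining = z
        max_n = 0
        for n, sub in periodic.SUBSHELL_ORDER:
            if remaining <= 0:
                break
            n_orb = periodic.SUBSHELL_CAPACITY[sub]
            take = min(remaining, 2 * n_orb)
            orbs = [Orbital(n, sub) for _ in range(n_orb)]
            # Hund filling: singles first, then pair up.
            for i in range(take):
                orbs[i % n_orb].electrons.append("core")
            self.orbitals.extend(orbs)
            remaining -= take
            max_n = max(max_n, n)
        self.valence_n = max_n
        # Ensure empty valence d orbitals exist for expansion (period >= 3).
        if max_n >= 3 and not any(
            o.n == max_n and o.subshell == "d" for o in self.orbitals
        ):
            self.orbitals.extend(Orbital(max_n, "d") for _ in range(5))

    def valence_orbitals(self) -> list[Orbital]:
        return [o for o in self.orbitals if o.n == self.valence_n]

    def allocate_bonding(
        self,
        valency: int,
        valence_electrons: int | None,
        sigma: int,
        pi: int,
        aromatic: int,
        lone_pairs: int,
        aromatic_lone_pairs: int = 0,
        unpaired: int = 0,
    ) -> None:
        """Distribute valence electrons over bonding roles and lone pairs.

        Electrons delegated to an aromatic system ('aromatic' role) stay in
        p-orbital slots but are owned by the system pool. Afterwards any
        unpaired non-bonding electron is dropped back into the lowest
        vacant valence orbital (paired into lone pairs), so no unpaired
        electron sits above a vacancy.
        """
        if valence_electrons is None:
            return  # untabulated element: no electron-level bookkeeping
        valence = self.valence_orbitals()
        n_orbitals = len(valence)
        bonding = sigma + pi + aromatic + 2 * aromatic_lone_pairs
        kept_lone = lone_pairs - aromatic_lone_pairs
        if (
            bonding < 0
            or kept_lone < 0
            or (sigma + pi + aromatic + aromatic_lone_pairs + kept_lone
                + unpaired) > n_orbitals
        ):
            raise StructureError(StructureError.BONDING,
                                 f"{self.element} cannot host {valency} bonds")
        for orb in valence:
            orb.electrons = []
        roles: list[tuple[str, int]] = [
            ("lone", 2)
        ] * kept_lone + [("sigma", 1)] * sigma + [("pi", 1)] * pi + [
            ("aromatic", 1)
        ] * aromatic + [("aromatic", 2)] * aromatic_lone_pairs + [
            ("radical", 1)
        ] * unpaired
        # Lone pairs sit lowest ("dropped back"), bonding electrons above.
        for orb, (role, count) in zip(valence, roles):
            orb.electrons = [role] * count

    def validate(self) -> None:
        for orb in self.orbitals:
            if orb.occupancy > 2:
                raise StructureError(StructureError.BONDING,
                                     "orbital holds more than two electrons")
        # No unpaired electron above a vacant lower orbital of the valence
        # shell, unless it is a bonding electron.
        seen_vacancy = False
        for orb in self.valence_orbitals():
            if orb.occupancy == 0:
                seen_vacancy = True
            elif orb.electrons == ["lone", "lone"] and seen_vacancy:
                raise StructureError(StructureError.BONDING,
                                     "lone pair above a vacant orbital")

    def count_role(self, role: str) -> int:
        return sum(o.electrons.count(role) for o in self.orbitals)


@dataclass
class Atom:
    """A graph node: element, charge, stereo descriptor and bookkeeping."""

    element: str
    index: int
    charge: int = 0
    aromatic: bool = False
    chiral: str | None = None  # 'clockwise' (@@) or 'counterclockwise' (@)
    chiral_order: list[int] = field(default_factory=list)
    explicit_h: int = 0
    annotations: dict[str, Any] = field(default_factory=dict)
    shells: ElectronConfiguration | None = None
    # derived on refresh:
    valency: int = 0
    hybridisation: str = ""
    lone_pairs: int = 0
    pi_count: int = 0          # localised pi bonds (double/triple/quadruple)
    aromatic_pi: int = 0       # 1 if the atom donates one p electron to a ring
    aromatic_lone_pair: int = 0  # 1 if the atom donates a full lone pair
    unpaired: int = 0          # valence electrons without a bonding partner

    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def atomic_number(self) -> int:
        return periodic.atomic_number(self.element)

    def __repr__(self) -> str:
        return f"{self.element}_{self.index}"

    def __hash__(self) -> int:
        return hash(self.index)


@dataclass
class Bond:
    """A graph edge between two atom indices, with order and stereo marks."""

    atom1: int
    atom2: int
    type: str
    index: int
    aromatic: bool = False
    # cis/trans descriptor of a double bond: the two reference neighbour
    # atoms (one per end, in (atom1-side, atom2-side) order) and whether they
    # sit on the same side.
    cis_trans: str | None = None  # 'cis' | 'trans'
    stereo_atoms: tuple[int, int] | None = None
    annotations: dict[str, Any] = field(default_factory=dict)

    def order(self) -> float:
        if self.type == "aromatic":
            return 1.5
        return BOND_ORDER[self.type]

    def other(self, atom_index: int) -> int:
        if atom_index == self.atom1:
            return self.atom2
        if atom_index == self.atom2:
            return self.atom1
        raise KeyError(atom_index)

    def atoms(self) -> tuple[int, int]:
        return (self.atom1, self.atom2)

    def __repr__(self) -> str:
        return f"Bond{self.index}({self.atom1}-{self.atom2},{self.type})"


class AromaticSystem:
    """A maximal bond-sharing union of aromatic cycles with its electron pool."""

    def __init__(self, atoms: set[int], bonds: set[int], pi_electrons: int):
        self.atoms = atoms
        self.bonds = bonds
        self.pi_electrons = pi_electrons

    def __repr__(self) -> str:
        return (f"AromaticSystem({len(self.atoms)} atoms, "
                f"{self.pi_electrons} pi electrons)")


class Structure:
    """A molecular graph with electron-validated atoms and bonds."""

    def __init__(self) -> None:
        self.atoms: dict[int, Atom] = {}
        self.bonds: dict[int, Bond] = {}
        self.adjacency: dict[int, list[int]] = {}
        self._next_atom = 0
        self._next_bond = 0
        self.ring_data = None  # RingSet, filled by the rings module
        self.aromatic_systems: list[AromaticSystem] = []
        self.aromaticity_done = False
        self.annotation_names: dict[str, Any] = {}

    # ------------------------------------------------------------------ build
    def add_atom(self, element: str, charge: int = 0, aromatic: bool = False,
                 chiral: str | None = None, explicit_h: int = 0,
                 index: int | None = None) -> Atom:
        if not periodic.is_known_element(element):
            raise StructureError(StructureError.SYNTAX,
                                 f"unknown element {element!r}")
        if index is None:
            index = self._next_atom
        if index in self.atoms:
            raise StructureError(StructureError.SYNTAX,
                                 f"duplicate atom index {index}")
        atom = Atom(element=element, index=index, charge=charge,
                    aromatic=aromatic, chiral=chiral, explicit_h=explicit_h)
        for name, default in self.annotation_names.items():
            atom.annotations[name] = copy.copy(default)
        self.atoms[index] = atom
        self.adjacency[index] = []
        self._next_atom = max(self._next_atom, index + 1)
        return atom

    def add_bond(self, atom1: int, atom2: int, bond_type: str = "single",
                 index: int | None = None) -> Bond:
        if atom1 == atom2:
            raise StructureError(StructureError.SYNTAX,
                                 "bond endpoints must be distinct")
        for a in (atom1, atom2):
            if a not in self.atoms:
                raise StructureError(StructureError.SYNTAX,
                                     f"bond references missing atom {a}")
        if self.bond_between(atom1, atom2) is not None:
            raise StructureError(StructureError.SYNTAX,
                                 f"duplicate bond {atom1}-{atom2}")
        if index is None:
            index = self._next_bond
        bond = Bond(atom1=atom1, atom2=atom2, type=bond_type, index=index,
                    aromatic=(bond_type == "aromatic"))
        self.bonds[index] = bond
        self.adjacency[atom1].append(index)
        self.adjacency[atom2].append(index)
        self._next_bond = max(self._next_bond, index + 1)
        self._invalidate_caches()
        return bond

    def remove_bond(self, bond: Bond | int) -> None:
        bond = self.bonds[bond] if isinstance(bond, int) else bond
        del self.bonds[bond.index]
        self.adjacency[bond.atom1].remove(bond.index)
        self.adjacency[bond.atom2].remove(bond.index)
        self._invalidate_caches()

    def remove_atom(self, atom: Atom | int) -> None:
        idx = atom.index if isinstance(atom, Atom) else atom
        for bond_idx in list(self.adjacency[idx]):
            self.remove_bond(self.bonds[bond_idx])
        del self.adjacency[idx]
        del self.atoms[idx]
        self._invalidate_caches()

    def _invalidate_caches(self) -> None:
        self.ring_data = None
        self.aromaticity_done = False

    # ------------------------------------------------------------ navigation
    def atom(self, index: int) -> Atom:
        return self.atoms[index]

    def bond(self, index: int) -> Bond:
        return self.bonds[index]

    def bonds_of(self, atom: Atom | int) -> list[Bond]:
        idx = atom.index if isinstance(atom, Atom) else atom
        return [self.bonds[b] for b in self.adjacency[idx]]

    def neighbours(self, atom: Atom | int) -> list[Atom]:
        idx = atom.index if isinstance(atom, Atom) else atom
        return [self.atoms[self.bonds[b].other(idx)] for b in self.adjacency[idx]]

    def heavy_neighbours(self, atom: Atom | int) -> list[Atom]:
        return [a for a in self.neighbours(atom) if a.is_heavy()]

    def hydrogen_count(self, atom: Atom | int) -> int:
        return sum(1 for a in self.neighbours(atom) if a.is_hydrogen())

    def bond_between(self, atom1: int, atom2: int) -> Bond | None:
        for b in self.adjacency.get(atom1, ()):
            if self.bonds[b].other(atom1) == atom2:
                return self.bonds[b]
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms.values() if a.is_heavy()]

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms.values())

    def __len__(self) -> int:
        return len(self.atoms)

    def bond_order_sum(self, atom: Atom | int) -> float:
        """Sum of bond orders at an atom; an aromatic bond counts 1 sigma and
        the atom's own pi/lone-pair donation is tracked separately."""
        idx = atom.index if isinstance(atom, Atom) else atom
        total = 0.0
        for bond in self.bonds_of(idx):
            total += 1 if bond.type == "aromatic" else BOND_ORDER[bond.type]
        return total

    def connected_components(self) -> list[set[int]]:
        seen: set[int] = set()
        components = []
        for start in self.atoms:
            if start in seen:
                continue
            comp = {start}
            queue = deque([start])
            while queue:
                current = queue.popleft()
                for nb in self.neighbours(current):
                    if nb.index not in comp:
                        comp.add(nb.index)
                        queue.append(nb.index)
            seen |= comp
            components.append(comp)
        return components

    def shortest_path(self, source: int, target: int,
                      heavy_only: bool = False) -> list[int] | None:
        """Atom-index path from source to target (BFS), or None."""
        if source == target:
            return [source]
        previous: dict[int, int] = {source: source}
        queue = deque([source])
        while queue:
            current = queue.popleft()
            for nb in self.neighbours(current):
                if heavy_only and nb.is_hydrogen():
                    continue
                if nb.index in previous:
                    continue
                previous[nb.index] = current
                if nb.index == target:
                    path = [target]
                    while path[-1] != source:
                        path.append(previous[path[-1]])
                    return path[::-1]
                queue.append(nb.index)
        return None

    # ------------------------------------------------------------ annotations
    def annotate(self, name: str, default: Any = None) -> None:
        """Register an annotation on every atom at once, with a default."""
        self.annotation_names[name] = default
        for atom in self.atoms.values():
            atom.annotations[name] = copy.copy(default)

    def set_annotation(self, atom: Atom | int, name: str, value: Any) -> None:
        atom = self.atoms[atom] if isinstance(atom, int) else atom
        if name not in self.annotation_names:
            raise KeyError(f"annotation {name!r} is not registered")
        atom.annotations[name] = value

    def get_annotation(self, atom: Atom | int, name: str) -> Any:
        atom = self.atoms[atom] if isinstance(atom, int) else atom
        if name not in self.annotation_names:
            raise KeyError(f"annotation {name!r} is not registered")
        return atom.annotations[name]

    # ---------------------------------------------------------------- refresh
    def refresh(self, perceive_aromaticity: bool = True) -> "Structure":
        """Recompute valencies, electron shells, hybridisation, ring caches
        and aromaticity; raise StructureError if bonding laws are violated."""
        self._assign_valencies()
        self._assign_hybridisation()
        if perceive_aromaticity:
            from . import rings  # local import: rings depends on this module
            rings.detect_aromaticity(self)
            self._assign_hybridisation()  # lone-pair promotion changes labels
        self._allocate_electrons()
        return self

    def _assign_valencies(self) -> None:
        for atom in self.atoms.values():
            if atom.is_hydrogen():
                if len(self.adjacency[atom.index]) > 1:
                    raise StructureError(StructureError.BONDING,
                                         "hydrogen with more than one bond")
                atom.valency = 1
                atom.pi_count = 0
                atom.lone_pairs = 0
                continue
            sigma = len(self.adjacency[atom.index])
            pi_local = 0
            for bond in self.bonds_of(atom):
                if bond.type != "aromatic":
                    pi_local += BOND_ORDER[bond.type] - 1
            needed = sigma + pi_local + atom.aromatic_pi
            allowed = periodic.allowed_valences(atom.element, atom.charge)
            if allowed is None:
                valency = needed
            else:
                options = [v for v in allowed if v >= needed]
                if not options:
                    raise StructureError(
                        StructureError.BONDING,
                        f"{atom.element} with bond order sum {needed}")
                valency = options[0]
            atom.valency = valency
            atom.unpaired = valency - needed
            atom.pi_count = pi_local
            ve = periodic.valence_electrons(atom.element, atom.charge)
            if ve is None:
                atom.lone_pairs = 0
            else:
                nonbonding = ve - valency
                if nonbonding < 0 or nonbonding % 2:
                    raise StructureError(StructureError.BONDING,
                                         f"{atom.element} electron count")
                atom.lone_pairs = nonbonding // 2
            if atom.aromatic_lone_pair > atom.lone_pairs:
                atom.aromatic_lone_pair = 0

    def _assign_hybridisation(self) -> None:
        for atom in self.atoms.values():
            if atom.is_hydrogen():
                atom.hybridisation = "s"
                continue
            sigma = len(self.adjacency[atom.index])
            steric = (sigma + atom.lone_pairs - atom.aromatic_lone_pair
                      + atom.unpaired)
            if atom.aromatic_pi and steric > 3:
                steric = 3
            if steric not in HYBRIDISATION_BY_STERIC:
                raise StructureError(StructureError.BONDING,
                                     f"steric number {steric} out of range")
            atom.hybridisation = HYBRIDISATION_BY_STERIC[steric]

    def _allocate_electrons(self) -> None:
        for atom in self.atoms.values():
            if atom.is_hydrogen():
                atom.shells = None
                continue
            config = ElectronConfiguration(atom.element)
            sigma = len(self.adjacency[atom.index])
            config.allocate_bonding(
                valency=atom.valency,
                valence_electrons=periodic.valence_electrons(atom.element,
                                                             atom.charge),
                sigma=sigma,
                pi=atom.pi_count,
                aromatic=atom.aromatic_pi,
                lone_pairs=atom.lone_pairs,
                aromatic_lone_pairs=atom.aromatic_lone_pair,
                unpaired=atom.unpaired,
            )
            config.validate()
            atom.shells = config

    # ------------------------------------------------------------------ copy
    def deep_copy(self) -> "Structure":
        """A structurally identical, fully independent copy."""
        new = Structure()
        new.annotation_names = dict(self.annotation_names)
        for atom in self.atoms.values():
            clone = Atom(
                element=atom.element, index=atom.index, charge=atom.charge,
                aromatic=atom.aromatic, chiral=atom.chiral,
                chiral_order=list(atom.chiral_order),
                explicit_h=atom.explicit_h,
                annotations=copy.deepcopy(atom.annotations),
                valency=atom.valency, hybridisation=atom.hybridisation,
                lone_pairs=atom.lone_pairs, pi_count=atom.pi_count,
                aromatic_pi=atom.aromatic_pi,
                aromatic_lone_pair=atom.aromatic_lone_pair,
                unpaired=atom.unpaired,
            )
            new.atoms[clone.index] = clone
            new.adjacency[clone.index] = []
        for bond in sorted(self.bonds.values(), key=lambda b: b.index):
            clone = Bond(atom1=bond.atom1, atom2=bond.atom2, type=bond.type,
                         index=bond.index, aromatic=bond.aromatic,
                         cis_trans=bond.cis_trans,
                         stereo_atoms=bond.stereo_atoms,
                         annotations=copy.deepcopy(bond.annotations))
            new.bonds[clone.index] = clone
        for idx, bond_indices in self.adjacency.items():
            new.adjacency[idx] = list(bond_indices)
        new._next_atom = self._next_atom
        new._next_bond = self._next_bond
        if self.ring_data is not None:
            from .rings import RingSet
            new.ring_data = RingSet(
                simple_cycles=list(self.ring_data.simple_cycles),
                sssr=list(self.ring_data.sssr),
                aromatic_cycles=list(self.ring_data.aromatic_cycles),
                atom_rings={k: list(v)
                            for k, v in self.ring_data.atom_rings.items()},
            )
        new.aromatic_systems = [
            AromaticSystem(set(s.atoms), set(s.bonds), s.pi_electrons)
            for s in self.aromatic_systems
        ]
        new.aromaticity_done = self.aromaticity_done
        try:
            new._allocate_electrons()
        except StructureError:
            pass  # copies of intermediate (unvalidated) graphs are allowed
        return new

    def copy(self) -> "Structure":
        return self.deep_copy()


def build_structure(atoms: Iterable[tuple], bonds: Iterable[tuple]) -> Structure:
    """Assemble a Structure from plain atom and bond specs.

    ``atoms``: iterables of (element, index) or (element, index, charge).
    ``bonds``: iterables of (index1, index2) or (index1, index2, type).
    Adjacency is built; no validation is performed (call ``refresh``).
    """
    structure = Structure()
    for spec in atoms:
        element, index = spec[0], spec[1]
        charge = spec[2] if len(spec) > 2 else 0
        structure.add_atom(element, charge=charge, index=index)
    for spec in bonds:
        a1, a2 = spec[0], spec[1]
        bond_type = spec[2] if len(spec) > 2 else "single"
        structure.add_bond(a1, a2, bond_type)
    return structure


def refresh_structure(structure: Structure) -> Structure:
    """Revalidate a structure after edits (valency, shells, rings, aromaticity)."""
    return structure.refresh()
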