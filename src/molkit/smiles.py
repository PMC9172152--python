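"""SMILES reading and writing.

The reader builds a validated :class:`~molkit.chem_graph.Structure`:
valencies are assigned (smallest allowed valence that accommodates the bond
order sum), the pentavalent-nitro correction is applied, implicit hydrogens
are materialised as real graph nodes, hybridisation is set, cycles and
aromaticity are perceived and electrons allocated. The writer emits a
kekulised SMILES via a deterministic depth-first walk from the lowest atom
index; it preserves charges, tetrahedral chirality and double-bond
cis/trans marks, but makes no canonicalisation claim.

Supported grammar: organic subset B C N O P S F Cl Br I (aromatic
b c n o p s), bracket atoms with charge/explicit H/@/@@ (isotope digits are
accepted and ignored), ring closures 0-9 and %nn, branches, '.' for
disconnected components, bonds - = # $ : / \\.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

from . import periodic
from .chem_graph import BOND_ORDER, Atom, Structure
from .errors import StructureError

BOND_SYMBOLS = {"-": "single", "=": "double", "#": "triple",
                "$": "quadruple", ":": "aromatic"}
SYMBOL_FOR_BOND = {"double": "=", "triple": "#", "quadruple": "$"}

_BRACKET_RE = re.compile(
    r"^(?P<isotope>\d+)?"
    r"(?P<symbol>[A-Z][a-z]?|as|se|[bcnops])"
    r"(?P<chiral>@@?)?"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>\+\+|--|[+-]\d*)?"
    r"(?::\d+)?$"
)

_TWO_LETTER_ORGANIC = ("Cl", "Br")
_ONE_LETTER_ORGANIC = set("BCNOPSFI")
_AROMATIC_ORGANIC = set("bcnops")


@dataclass
class SmilesToken:
    """One lexical unit of a SMILES string."""

    kind: str  # 'atom' | 'bond' | 'ring' | 'open' | 'close' | 'dot'
    payload: dict[str, Any] = field(default_factory=dict)
    position: int = 0


def _parse_charge(text: str | None) -> int:
    if not text:
        return 0
    if text == "++":
        return 2
    if text == "--":
        return -2
    sign = 1 if text[0] == "+" else -1
    magnitude = int(text[1:]) if len(text) > 1 else 1
    return sign * magnitude


def tokenise(smiles: str) -> list[SmilesToken]:
    tokens: list[SmilesToken] = []
    i = 0
    n = len(smiles)
    while i < n:
        c = smiles[i]
        if c == "[":
            end = smiles.find("]", i)
            if end < 0:
                raise StructureError(StructureError.SYNTAX,
                                     "unclosed bracket atom")
            body = smiles[i + 1:end]
            match = _BRACKET_RE.match(body)
            if not match:
                raise StructureError(StructureError.SYNTAX,
                                     f"cannot read bracket atom [{body}]")
            symbol = match.group("symbol")
            aromatic = symbol[0].islower()
            element = symbol.capitalize() if aromatic else symbol
            hcount = match.group("hcount")
            explicit_h = 0
            if hcount:
                explicit_h = int(hcount[1:]) if len(hcount) > 1 else 1
            chiral = None
            if match.group("chiral") == "@":
                chiral = "counterclockwise"
            elif match.group("chiral") == "@@":
                chiral = "clockwise"
            tokens.append(SmilesToken("atom", {
                "element": element, "aromatic": aromatic,
                "charge": _parse_charge(match.group("charge")),
                "explicit_h": explicit_h, "chiral": chiral, "bracket": True,
            }, i))
            i = end + 1
        elif smiles[i:i + 2] in _TWO_LETTER_ORGANIC:
            tokens.append(SmilesToken("atom", {
                "element": smiles[i:i + 2], "aromatic": False, "charge": 0,
                "explicit_h": 0, "chiral": None, "bracket": False}, i))
            i += 2
        elif c in _ONE_LETTER_ORGANIC:
            tokens.append(SmilesToken("atom", {
                "element": c, "aromatic": False, "charge": 0,
                "explicit_h": 0, "chiral": None, "bracket": False}, i))
            i += 1
        elif c in _AROMATIC_ORGANIC:
            tokens.append(SmilesToken("atom", {
                "element": c.upper(), "aromatic": True, "charge": 0,
                "explicit_h": 0, "chiral": None, "bracket": False}, i))
            i += 1
        elif c in BOND_SYMBOLS or c in "/\\":
            tokens.append(SmilesToken("bond", {"symbol": c}, i))
            i += 1
        elif c == "%":
            if i + 2 >= n or not smiles[i + 1:i + 3].isdigit():
                raise StructureError(StructureError.SYNTAX,
                                     "'%' needs two digits")
            tokens.append(SmilesToken("ring", {"label": int(smiles[i + 1:i + 3])}, i))
            i += 3
        elif c.isdigit():
            tokens.append(SmilesToken("ring", {"label": int(c)}, i))
            i += 1
        elif c == "(":
            tokens.append(SmilesToken("open", {}, i))
            i += 1
        elif c == ")":
            tokens.append(SmilesToken("close", {}, i))
            i += 1
        elif c == ".":
            tokens.append(SmilesToken("dot", {}, i))
            i += 1
        else:
            raise StructureError(StructureError.SYNTAX,
                                 f"unexpected character {c!r}")
    return tokens


class _RingSlot:
    __slots__ = ("atom", "symbol", "order_slot")

    def __init__(self, atom: int, symbol: str | None, order_slot: int):
        self.atom = atom
        self.symbol = symbol
        self.order_slot = order_slot


def _flip(symbol: str) -> str:
    return "\\" if symbol == "/" else "/"


class _Parser:
    """Builds the raw graph from tokens, then runs the validation pipeline."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        self.structure = Structure()
        # atom index -> written neighbour order; entries are atom indices,
        # ('ring', label, serial) placeholders or 'H' for the bracket hydrogen
        self.order: dict[int, list] = {}
        self.directional: list[tuple[int, str]] = []  # (bond index, symbol)

    def run(self) -> Structure:
        tokens = tokenise(self.smiles)
        self._build_graph(tokens)
        correct_pentavalent_nitrogen(self.structure)
        self._classify_aromatic_atoms()
        add_implicit_hydrogens(self.structure)
        self._materialise_chiral_order()
        self.structure.refresh()
        self._resolve_cis_trans()
        return self.structure

    # ------------------------------------------------------------- graph
    def _build_graph(self, tokens: list[SmilesToken]) -> None:
        structure = self.structure
        prev: int | None = None
        pending_bond: str | None = None
        stack: list[int | None] = []
        open_rings: dict[int, _RingSlot] = {}
        ring_serial = 0
        for token in tokens:
            if token.kind == "atom":
                atom = structure.add_atom(
                    token.payload["element"], charge=token.payload["charge"],
                    aromatic=token.payload["aromatic"],
                    chiral=token.payload["chiral"],
                    explicit_h=token.payload["explicit_h"])
                atom.bracket = token.payload["bracket"]
                self.order[atom.index] = []
                if prev is not None:
                    bond_type, symbol = self._bond_type(pending_bond, prev,
                                                        atom.index)
                    bond = structure.add_bond(prev, atom.index, bond_type)
                    if symbol:
                        self.directional.append((bond.index, symbol))
                    self.order[prev].append(atom.index)
                    self.order[atom.index].append(prev)
                if token.payload["bracket"] and token.payload["explicit_h"]:
                    self.order[atom.index].append("H")
                prev = atom.index
                pending_bond = None
            elif token.kind == "bond":
                if pending_bond is not None:
                    raise StructureError(StructureError.SYNTAX,
                                         "two consecutive bond symbols")
                pending_bond = token.payload["symbol"]
            elif token.kind == "ring":
                if prev is None:
                    raise StructureError(StructureError.SYNTAX,
                                         "ring closure before any atom")
                label = token.payload["label"]
                if label in open_rings:
                    slot = open_rings.pop(label)
                    self._close_ring(slot, prev, pending_bond)
                else:
                    ring_serial += 1
                    placeholder = ("ring", label, ring_serial)
                    open_rings[label] = _RingSlot(prev, pending_bond,
                                                  ring_serial)
                    self.order[prev].append(placeholder)
                pending_bond = None
            elif token.kind == "open":
                if prev is None:
                    raise StructureError(StructureError.SYNTAX,
                                         "branch before any atom")
                stack.append(prev)
            elif token.kind == "close":
                if not stack:
                    raise StructureError(StructureError.SYNTAX,
                                         "unbalanced parenthesis")
                prev = stack.pop()
            elif token.kind == "dot":
                if pending_bond is not None:
                    raise StructureError(StructureError.SYNTAX,
                                         "bond before '.'")
                prev = None
        if stack:
            raise StructureError(StructureError.SYNTAX,
                                 "unbalanced parenthesis")
        if open_rings:
            raise StructureError(StructureError.SYNTAX,
                                 "unmatched ring closure")
        if pending_bond is not None:
            raise StructureError(StructureError.SYNTAX,
                                 "dangling bond symbol")
        if not structure.atoms:
            raise StructureError(StructureError.SYNTAX, "no atoms")

    def _bond_type(self, symbol: str | None, atom1: int,
                   atom2: int) -> tuple[str, str | None]:
        if symbol in ("/", "\\"):
            return "single", symbol
        if symbol is None:
            a1 = self.structure.atom(atom1)
            a2 = self.structure.atom(atom2)
            if a1.aromatic and a2.aromatic:
                return "aromatic", None
            return "single", None
        return BOND_SYMBOLS[symbol], None

    def _close_ring(self, slot: _RingSlot, closing_atom: int,
                    close_symbol: str | None) -> None:
        open_symbol = slot.symbol
        directional = None
        symbols = []
        for raw, reverse in ((open_symbol, False), (close_symbol, True)):
            if raw in ("/", "\\"):
                symbols.append(_flip(raw) if reverse else raw)
            elif raw is not None:
                symbols.append(raw)
        if len(symbols) == 2 and symbols[0] != symbols[1]:
            raise StructureError(StructureError.STEREO_CONFLICT,
                                 "ring bond symbols disagree")
        symbol = symbols[0] if symbols else None
        if symbol in ("/", "\\"):
            directional = symbol
            bond_type = "single"
        else:
            bond_type, _ = self._bond_type(symbol, slot.atom, closing_atom)
        bond = self.structure.add_bond(slot.atom, closing_atom, bond_type)
        if directional:
            self.directional.append((bond.index, directional))
        # resolve the placeholder in the opening atom's written order and
        # append the partner to the closing atom's order
        placeholder = ("ring", None, slot.order_slot)
        order = self.order[slot.atom]
        for i, entry in enumerate(order):
            if (isinstance(entry, tuple) and entry[0] == "ring"
                    and entry[2] == slot.order_slot):
                order[i] = closing_atom
                break
        self.order[closing_atom].append(slot.atom)

    # ----------------------------------------------------------- aromatics
    def _classify_aromatic_atoms(self) -> None:
        structure = self.structure
        for atom in structure.atoms.values():
            if not atom.aromatic:
                continue
            heavy = len(structure.adjacency[atom.index])
            allowed = periodic.allowed_valences(atom.element, atom.charge)
            if allowed is None:
                raise StructureError(StructureError.BONDING,
                                     f"aromatic {atom.element} unsupported")
            if getattr(atom, "bracket", False):
                hydrogens = atom.explicit_h
            elif atom.element in ("C", "B"):
                hydrogens = max(0, allowed[0] - heavy - 1)
                atom.explicit_h = 0
            else:
                hydrogens = 0
            sigma = heavy + hydrogens
            atom._aromatic_h = hydrogens
            if any(v == sigma + 1 for v in allowed):
                atom.aromatic_pi = 1
            elif any(v == sigma for v in allowed):
                atom.aromatic_lone_pair = 1
            else:
                raise StructureError(
                    StructureError.BONDING,
                    f"aromatic {atom.element} with {sigma} sigma bonds")

    # ----------------------------------------------------------- hydrogens
    def _materialise_chiral_order(self) -> None:
        structure = self.structure
        for atom in list(structure.atoms.values()):
            if atom.chiral is None:
                continue
            order = self.order[atom.index]
            resolved: list[int] = []
            h_neighbours = [a.index for a in structure.neighbours(atom)
                            if a.is_hydrogen()]
            for entry in order:
                if entry == "H":
                    if not h_neighbours:
                        raise StructureError(StructureError.CHIRALITY,
                                             "chiral centre lost its hydrogen",
                                             )
                    resolved.append(h_neighbours.pop(0))
                else:
                    resolved.append(entry)
            if len(resolved) != 4 or len(set(resolved)) != 4:
                raise StructureError(
                    StructureError.CHIRALITY,
                    "a tetrahedral centre needs exactly 4 distinct "
                    "neighbours (counting hydrogens)")
            atom.chiral_order = resolved

    # ------------------------------------------------------------ cis/trans
    def _resolve_cis_trans(self) -> None:
        structure = self.structure
        sides: dict[int, dict[int, list[tuple[int, int]]]] = {}
        # sides[double_bond_index][end_atom] = [(substituent, side), ...]
        directional_bonds = [(structure.bond(b), sym)
                             for b, sym in self.directional]
        for double in structure.bonds.values():
            if double.type != "double":
                continue
            per_end: dict[int, list[tuple[int, int]]] = {}
            for end in (double.atom1, double.atom2):
                for bond, symbol in directional_bonds:
                    if end not in (bond.atom1, bond.atom2):
                        continue
                    substituent = bond.other(end)
                    if substituent in (double.atom1, double.atom2):
                        continue
                    base = 1 if symbol == "/" else -1
                    # '/' written a/b places b above a; the far atom's side
                    # relative to the stereo end flips when the bond is
                    # written toward the end.
                    side = base if bond.atom1 == end else -base
                    per_end.setdefault(end, []).append((substituent, side))
            for end, subs in per_end.items():
                if len(subs) == 2 and subs[0][1] == subs[1][1]:
                    raise StructureError(StructureError.STEREO_CONFLICT)
            if len(per_end) < 2:
                continue
            r1 = self._pick_reference(per_end[double.atom1])
            r2 = self._pick_reference(per_end[double.atom2])
            double.stereo_atoms = (r1[0], r2[0])
            double.cis_trans = "cis" if r1[1] == r2[1] else "trans"

    def _pick_reference(self, subs: list[tuple[int, int]]) -> tuple[int, int]:
        heavy = [s for s in subs
                 if self.structure.atom(s[0]).is_heavy()]
        pool = heavy or subs
        return min(pool, key=lambda s: s[0])


def correct_pentavalent_nitrogen(structure: Structure) -> Structure:
    """Rewrite nitro-style N(=O)=O nitrogens: one N=O becomes N(+)-O(-).

    A neutral nitrogen whose bond order sum reaches 5 has no fifth bonding
    orbital; if it carries at least one doubly bonded oxygen the group is
    reinterpreted as the charge-separated nitro form (N valency 4).
    Pentavalent nitrogens without such an oxygen are left for validation to
    reject.
    """
    for atom in structure.atoms.values():
        if atom.element != "N" or atom.charge != 0 or atom.aromatic:
            continue
        order_sum = sum(
            BOND_ORDER.get(b.type, 1) for b in structure.bonds_of(atom)
        ) + atom.explicit_h
        if order_sum != 5:
            continue
        for bond in structure.bonds_of(atom):
            other = structure.atom(bond.other(atom.index))
            if bond.type == "double" and other.element == "O" \
                    and other.charge == 0:
                bond.type = "single"
                other.charge = -1
                atom.charge = 1
                break
    return structure


def assign_valency(element: str, charge: int, bond_order_sum: float,
                   explicit_h: int = 0) -> int:
    """Smallest allowed valency >= the bond order sum (plus explicit H)."""
    import math

    needed = math.ceil(bond_order_sum + explicit_h)
    allowed = periodic.allowed_valences(element, charge)
    if allowed is None:
        return needed
    for valency in allowed:
        if valency >= needed:
            return valency
    raise StructureError(StructureError.BONDING,
                         f"{element} with bond order sum {needed}")


def add_implicit_hydrogens(structure: Structure) -> Structure:
    """Materialise implicit hydrogens as graph nodes so that assigned
    valencies are obeyed; bracket atoms only receive their written count."""
    for atom in list(structure.atoms.values()):
        if atom.is_hydrogen():
            continue
        if atom.aromatic:
            hydrogens = getattr(atom, "_aromatic_h", atom.explicit_h)
        elif getattr(atom, "bracket", False):
            hydrogens = atom.explicit_h
        else:
            order_sum = sum(b.order() for b in structure.bonds_of(atom))
            valency = assign_valency(atom.element, atom.charge, order_sum)
            hydrogens = valency - int(order_sum)
        if hydrogens < 0:
            raise StructureError(StructureError.BONDING,
                                 f"negative hydrogen count on {atom.element}")
        for _ in range(hydrogens):
            h = structure.add_atom("H")
            structure.add_bond(atom.index, h.index, "single")
    return structure


def determine_hybridisation(atom: Atom) -> str:
    """Hybridisation label from the steric number (set during refresh)."""
    return atom.hybridisation


def parse_smiles(smiles: str) -> Structure:
    """Parse a SMILES string into a validated Structure."""
    if not smiles or not smiles.strip():
        raise StructureError(StructureError.SYNTAX, "empty SMILES", smiles)
    try:
        return _Parser(smiles.strip()).run()
    except StructureError as err:
        if err.smiles is None:
            raise err.with_smiles(smiles.strip()) from None
        raise


# =====================================================================
# Writing
# =====================================================================

def _default_h_count(element: str, charge: int, order_sum: float) -> int | None:
    if element not in periodic.ORGANIC_SUBSET or charge != 0:
        return None
    try:
        valency = assign_valency(element, 0, order_sum)
    except StructureError:
        return None
    return int(valency - order_sum)


def _permutation_parity(reference: list[int], observed: list[int]) -> int:
    """0 if observed is an even permutation of reference, else 1."""
    positions = [reference.index(x) for x in observed]
    swaps = 0
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if positions[i] > positions[j]:
                swaps += 1
    return swaps % 2


class _Writer:
    def __init__(self, structure: Structure):
        from . import rings as rings_module

        if structure.aromatic_systems:
            structure = rings_module.kekulise(structure)
        self.structure = structure
        self.emitted_order: dict[int, list[int]] = {}

    # -------------------------------------------------------------- stereo
    def _plan_cis_trans(self) -> None:
        """Assign '/' and '\\' marks by 2-colouring the constraint graph of
        single bonds adjacent to stereo double bonds."""
        structure = self.structure
        stereo_bonds = []
        for bond in structure.bonds.values():
            if bond.type != "double" or bond.cis_trans is None:
                continue
            if bond.stereo_atoms is None:
                continue
            refs = self._normalised_refs(bond)
            if refs is not None:
                stereo_bonds.append((bond, refs))
        # candidate directional bonds: value +1 means "the higher-index
        # endpoint sits above the lower-index endpoint"
        value: dict[int, int] = {}
        constraints: dict[int, list[tuple[int, int]]] = {}

        def side_key(bond, end):
            """Map (bond,end) pair to (+1 factor) relating bond value to the
            substituent's side at this end."""
            low, high = sorted((bond.atom1, bond.atom2))
            return 1 if end == low else -1

        def add_constraint(b1, f1, b2, f2, relation):
            # relation: side1 * side2 == relation
            constraints.setdefault(b1.index, []).append(
                (b2.index, relation * f1 * f2))
            constraints.setdefault(b2.index, []).append(
                (b1.index, relation * f1 * f2))

        registered: dict[int, "object"] = {}
        for bond, (r1, r2) in stereo_bonds:
            b1 = structure.bond_between(bond.atom1, r1)
            b2 = structure.bond_between(bond.atom2, r2)
            if b1 is None or b2 is None:
                continue
            registered[b1.index] = b1
            registered[b2.index] = b2
            relation = 1 if bond.cis_trans == "cis" else -1
            add_constraint(b1, side_key(b1, bond.atom1),
                           b2, side_key(b2, bond.atom2), relation)
            # opposite-side constraints for second substituents at each end
            for end, ref in ((bond.atom1, r1), (bond.atom2, r2)):
                for nb_bond in structure.bonds_of(end):
                    other = nb_bond.other(end)
                    if other in (bond.atom1, bond.atom2) or other == ref:
                        continue
                    if nb_bond.type != "single":
                        continue
                    if not structure.atom(other).is_heavy():
                        continue
                    ref_bond = structure.bond_between(end, ref)
                    registered[nb_bond.index] = nb_bond
                    add_constraint(ref_bond, side_key(ref_bond, end),
                                   nb_bond, side_key(nb_bond, end), -1)
        for index in registered:
            if index in value:
                continue
            value[index] = 1
            queue = [index]
            while queue:
                current = queue.pop()
                for other, relation in constraints.get(current, ()):
                    expected = value[current] * relation
                    if other in value:
                        if value[other] != expected:
                            from .errors import ChiralityError
                            raise ChiralityError(
                                "inconsistent cis/trans constraints")
                    else:
                        value[other] = expected
                        queue.append(other)
        self._directional_values = value

    def _normalised_refs(self, bond) -> tuple[int, int] | None:
        """References as heavy atoms (flipping cis/trans when switching to
        the opposite substituent); None when inexpressible."""
        structure = self.structure
        r1, r2 = bond.stereo_atoms
        flips = 0
        refs = []
        for end, ref in ((bond.atom1, r1), (bond.atom2, r2)):
            if structure.bond_between(end, ref) is None:
                return None
            if structure.atom(ref).is_heavy():
                refs.append(ref)
                continue
            alternatives = [
                a.index for a in structure.heavy_neighbours(end)
                if a.index not in (bond.atom1, bond.atom2)
            ]
            if not alternatives:
                return None
            refs.append(alternatives[0])
            flips += 1
        if flips % 2:
            bond.cis_trans = ("trans" if bond.cis_trans == "cis" else "cis")
        bond.stereo_atoms = (refs[0], refs[1])
        return refs[0], refs[1]

    def _bond_token(self, bond, from_atom: int) -> str:
        if bond.index in getattr(self, "_directional_values", {}):
            v = self._directional_values[bond.index]
            low, _high = sorted((bond.atom1, bond.atom2))
            to_atom = bond.other(from_atom)
            # side of to_atom relative to from_atom
            side = v if from_atom == low else -v
            return "/" if side == 1 else "\\"
        if bond.type == "single" or bond.type == "aromatic":
            return ""
        return SYMBOL_FOR_BOND[bond.type]

    # ---------------------------------------------------------------- walk
    def write(self) -> str:
        self._plan_cis_trans()
        components = self.structure.connected_components()
        pieces = []
        for component in sorted(components, key=min):
            heavy = sorted(i for i in component
                           if self.structure.atom(i).is_heavy())
            start = heavy[0] if heavy else min(component)
            pieces.append(self._component(start))
        return ".".join(pieces)

    def _suppressed(self, atom: Atom) -> bool:
        if atom.is_heavy():
            return False
        neighbours = self.structure.neighbours(atom)
        return len(neighbours) == 1 and neighbours[0].is_heavy()

    def _component(self, start: int) -> str:
        order: list[int] = []
        tree: dict[int, list[int]] = {}
        closures: dict[int, list[int]] = {}
        visited: set[int] = set()

        def dfs(current: int, parent: int | None) -> None:
            visited.add(current)
            order.append(current)
            tree[current] = []
            for nb in sorted(self.structure.neighbours(current),
                             key=lambda a: a.index):
                if self._suppressed(nb):
                    continue
                if nb.index == parent:
                    continue
                if nb.index in visited:
                    pair = (nb.index, current)
                    if current not in closures or nb.index not in closures[current]:
                        closures.setdefault(current, []).append(nb.index)
                        closures.setdefault(nb.index, []).append(current)
                        self._closure_pairs.add(frozenset(pair))
                else:
                    tree[current].append(nb.index)
                    dfs(nb.index, current)

        self._closure_pairs: set[frozenset[int]] = set()
        dfs(start, None)
        # digits are assigned in first-visit order
        digit_of: dict[frozenset[int], int] = {}
        free = list(range(1, 100))
        open_digits: dict[frozenset[int], int] = {}

        def emit(current: int, parent: int | None) -> str:
            atom = self.structure.atom(current)
            emitted_neighbours: list[int] = []
            if parent is not None:
                emitted_neighbours.append(parent)
            h_nodes = [a.index for a in self.structure.neighbours(atom)
                       if a.is_hydrogen() and self._suppressed(a)]
            text = self._atom_token(atom, parent, h_nodes,
                                    emitted_neighbours)
            for partner in closures.get(current, ()):
                key = frozenset((current, partner))
                bond = self.structure.bond_between(current, partner)
                if key not in open_digits:
                    digit = free.pop(0)
                    open_digits[key] = digit
                    symbol = self._bond_token(bond, current)
                else:
                    digit = open_digits.pop(key)
                    free.insert(0, digit)
                    free.sort()
                    symbol = self._bond_token(bond, current)
                    if bond.index not in getattr(self, "_directional_values", {}):
                        symbol = ""  # order symbol printed at opening only
                text += symbol + (str(digit) if digit < 10 else f"%{digit:02d}")
                emitted_neighbours.append(partner)
            children = tree.get(current, [])
            parts = [text]
            for i, child in enumerate(children):
                bond = self.structure.bond_between(current, child)
                symbol = self._bond_token(bond, current)
                sub = symbol + emit(child, current)
                if i < len(children) - 1:
                    parts.append(f"({sub})")
                else:
                    parts.append(sub)
                emitted_neighbours.append(child)
            self.emitted_order[current] = emitted_neighbours
            return "".join(parts)

        text = emit(start, None)
        # chirality marks depend on the emission order, so patch them in a
        # second pass
        return self._patch_chirality(text, order, closures, tree, start)

    def _atom_token(self, atom: Atom, parent: int | None,
                    h_nodes: list[int], emitted_neighbours: list[int]) -> str:
        structure = self.structure
        h_count = len(h_nodes)
        order_sum = sum(
            b.order() for b in structure.bonds_of(atom)
            if not self._suppressed(structure.atom(b.other(atom.index)))
        )
        chiral_mark = self._chiral_mark_placeholder(atom)
        needs_bracket = (
            atom.charge != 0
            or chiral_mark
            or atom.element not in periodic.ORGANIC_SUBSET
            or _default_h_count(atom.element, atom.charge,
                                order_sum) != h_count
        )
        if chiral_mark and h_count:
            # the bracket hydrogen sits right after the incoming atom in the
            # written neighbour order
            emitted_neighbours.extend(h_nodes)
        if not needs_bracket:
            return atom.element
        token = atom.element
        if chiral_mark:
            token += chiral_mark
        if h_count == 1:
            token += "H"
        elif h_count > 1:
            token += f"H{h_count}"
        if atom.charge == 1:
            token += "+"
        elif atom.charge == -1:
            token += "-"
        elif atom.charge > 1:
            token += f"+{atom.charge}"
        elif atom.charge < -1:
            token += str(atom.charge)
        return f"[{token}]"

    def _chiral_mark_placeholder(self, atom: Atom) -> str:
        if atom.chiral is None or len(atom.chiral_order) != 4:
            return ""
        if any(n not in self.structure.atoms for n in atom.chiral_order):
            return ""
        if any(self.structure.bond_between(atom.index, n) is None
               for n in atom.chiral_order):
            return ""
        return f"\x00{atom.index}\x00"

    def _patch_chirality(self, text: str, order, closures, tree,
                         start: int) -> str:
        for atom_index in list(self.emitted_order):
            atom = self.structure.atom(atom_index)
            placeholder = f"\x00{atom.index}\x00"
            if placeholder not in text:
                continue
            emitted = self.emitted_order[atom_index]
            parity = _permutation_parity(atom.chiral_order, emitted)
            mark = atom.chiral
            if parity:
                mark = ("clockwise" if mark == "counterclockwise"
                        else "counterclockwise")
            text = text.replace(placeholder,
                                "@" if mark == "counterclockwise" else "@@")
        return text


def write_smiles(structure: Structure) -> str:
    """Write a kekulised SMILES for a validated structure."""
    return _Writer(structure.deep_copy()).write()
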