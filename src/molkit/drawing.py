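"""2D structure diagrams: coordinates, clash resolution, wedges, output.

The layout engine places ring systems first (regular polygons for simple and
overlapping rings, a Kamada-Kawai force-spring relaxation started on a
circle for bridged systems) and then walks the remaining graph depth-first,
placing chain atoms one bond length from their parent with angles chosen
from the neighbour count and branch depths. Stereo double bonds are forced
into their declared cis/trans arrangement by mirroring, reading the marks
from bond objects rather than the SMILES text. An optional finetuning pass
resolves steric clashes by rotating subtrees around rotatable bonds in 30
degree steps, keeping the angle with the fewest clashes.

Output: SVG (primary, bit-stable), PNG (rasterised from the same
primitives) and MDL MOL V2000 with wedge stereo flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageColor, ImageDraw, ImageFont

from . import rings as rings_module
from .chem_graph import Structure
from .errors import ChiralityError, StructureError


# --------------------------------------------------------------------- types

@dataclass
class DrawOptions:
    """Rendering and layout options (lengths in bond-length units)."""

    finetune: bool = True
    rotation_step: float = 30.0          # degrees; must divide 360
    clash_threshold: float = 0.5         # fraction of the mean bond length
    show_hydrogens: bool = False
    bond_length: float = 1.0
    scale: float = 50.0                  # pixels per bond length
    font_size: float = 0.5               # fraction of a bond length
    line_width: float = 0.05             # fraction of a bond length
    padding: float = 1.0                 # canvas margin, bond lengths
    background: str = "white"

    def __post_init__(self):
        if 360 % int(self.rotation_step) != 0:
            raise ValueError("rotation step must divide 360 degrees")


@dataclass
class RingClass:
    """Per-ring layout classes and merged bridged systems."""

    labels: dict[int, str]                 # sssr ring id -> class
    bridged_systems: list[set[int]]        # merged atom sets

    def label(self, ring_id: int) -> str:
        return self.labels[ring_id]


@dataclass
class Drawing:
    """2D coordinates plus render styling for one structure."""

    structure: Structure
    positions: dict[int, np.ndarray]
    options: DrawOptions
    wedges: dict[int, tuple[str, int]] = field(default_factory=dict)
    atom_colours: dict[int, str] = field(default_factory=dict)
    bond_colours: dict[int, str] = field(default_factory=dict)
    kamada_kawai_atoms: set[int] = field(default_factory=set)

    def drawn_atoms(self) -> list[int]:
        return sorted(self.positions)

    def drawn_bonds(self):
        return [b for b in self.structure.bonds.values()
                if b.atom1 in self.positions and b.atom2 in self.positions]

    def mean_bond_length(self) -> float:
        lengths = [np.linalg.norm(self.positions[b.atom1]
                                  - self.positions[b.atom2])
                   for b in self.drawn_bonds()]
        return float(np.mean(lengths)) if lengths else 1.0


def parse_colour(colour: str) -> tuple[int, int, int]:
    """Validate and normalise a colour (hex code or descriptive name)."""
    try:
        rgb = ImageColor.getrgb(colour)
    except ValueError as err:
        raise ValueError(f"unknown colour {colour!r}") from err
    return rgb[:3]


# ------------------------------------------------------------ ring classes

def classify_rings(structure: Structure) -> RingClass:
    """Label each SSSR ring simple / overlapping / bridged.

    A ring is bridged when it shares more than two atoms with another ring,
    contains an atom that is part of three or more rings, or shares atoms
    with another bridged ring (applied to a fixed point); rings sharing at
    most two atoms are overlapping; isolated rings are simple.
    """
    ring_data = rings_module.ensure_ring_data(structure)
    sssr = ring_data.sssr
    sets = [set(r) for r in sssr]
    atom_count: dict[int, int] = {}
    for ring in sets:
        for atom in ring:
            atom_count[atom] = atom_count.get(atom, 0) + 1
    bridged = [False] * len(sssr)
    for i, ring in enumerate(sets):
        if any(atom_count[a] >= 3 for a in ring):
            bridged[i] = True
            continue
        for j, other in enumerate(sets):
            if i != j and len(ring & other) > 2:
                bridged[i] = True
                break
    changed = True
    while changed:
        changed = False
        for i, ring in enumerate(sets):
            if bridged[i]:
                continue
            for j, other in enumerate(sets):
                if bridged[j] and ring & other:
                    bridged[i] = True
                    changed = True
                    break
    labels = {}
    for i, ring in enumerate(sets):
        if bridged[i]:
            labels[i] = "bridged"
        elif any(i != j and ring & other for j, other in enumerate(sets)):
            labels[i] = "overlapping"
        else:
            labels[i] = "simple"
    systems: list[set[int]] = []
    for i, ring in enumerate(sets):
        if not bridged[i]:
            continue
        merged = set(ring)
        keep = []
        for system in systems:
            if system & merged:
                merged |= system
            else:
                keep.append(system)
        keep.append(merged)
        systems = keep
    return RingClass(labels=labels, bridged_systems=systems)


# ------------------------------------------------------------------ geometry

def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _rotate(vector: np.ndarray, degrees: float) -> np.ndarray:
    angle = math.radians(degrees)
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vector[0] - s * vector[1],
                     s * vector[0] + c * vector[1]])


def _unit(vector: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(vector)
    if norm < 1e-12:
        return np.array([1.0, 0.0])
    return vector / norm


def _reflect(point: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = _unit(b - a)
    ap = point - a
    return a + 2 * d * np.dot(ap, d) - ap


def kamada_kawai(count: int, distances: np.ndarray,
                 tolerance: float = 1e-4, max_iterations: int = 2000
                 ) -> np.ndarray:
    """Force-spring layout: nodes start on a circle and relax toward their
    graph-distance-proportional separations (stress gradient descent)."""
    radius = max(1.0, count / (2 * math.pi))
    angles = np.linspace(0, 2 * math.pi, count, endpoint=False)
    pos = np.stack([radius * np.cos(angles), radius * np.sin(angles)], axis=1)
    weight = 1.0 / np.maximum(distances, 1e-9) ** 2
    np.fill_diagonal(weight, 0.0)
    step = 0.1
    for _ in range(max_iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=2)
        np.fill_diagonal(dist, 1.0)
        coeff = weight * (dist - distances) / dist
        gradient = (coeff[:, :, None] * delta).sum(axis=1)
        move = -step * gradient
        pos = pos + move
        if np.abs(move).max() < tolerance:
            break
    return pos


# -------------------------------------------------------------------- layout

class _LayoutEngine:
    def __init__(self, structure: Structure, options: DrawOptions):
        self.structure = structure
        self.options = options
        self.ring_data = rings_module.ensure_ring_data(structure)
        self.ring_class = classify_rings(structure)
        self.positions: dict[int, np.ndarray] = {}
        self.kk_atoms: set[int] = set()
        self.drawn = self._drawn_atoms()
        self._ring_systems = self._group_ring_systems()
        self._system_of = {}
        for sid, system in enumerate(self._ring_systems):
            for ring_id in system:
                for atom in self.ring_data.sssr[ring_id]:
                    self._system_of.setdefault(atom, sid)
        self._turn: dict[int, int] = {}

    # ------------------------------------------------------------- helpers
    def _drawn_atoms(self) -> set[int]:
        if self.options.show_hydrogens:
            return set(self.structure.atoms)
        return {a.index for a in self.structure.heavy_atoms()}

    def _drawn_neighbours(self, idx: int) -> list[int]:
        return [a.index for a in self.structure.neighbours(idx)
                if a.index in self.drawn]

    def _group_ring_systems(self) -> list[set[int]]:
        sssr = self.ring_data.sssr
        systems: list[set[int]] = []
        assigned = [False] * len(sssr)
        for i in range(len(sssr)):
            if assigned[i]:
                continue
            group = {i}
            frontier = [i]
            assigned[i] = True
            while frontier:
                current = frontier.pop()
                for j in range(len(sssr)):
                    if not assigned[j] and set(sssr[current]) & set(sssr[j]):
                        assigned[j] = True
                        group.add(j)
                        frontier.append(j)
            systems.append(group)
        return systems

    def _subtree_atoms(self, start: int, blocked: int) -> set[int]:
        """Atoms reachable from ``start`` without stepping onto ``blocked``."""
        seen = {start}
        stack = [start]
        while stack:
            current = stack.pop()
            for nb in self._drawn_neighbours(current):
                if nb != blocked and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    def _branch_depth(self, child: int, parent: int) -> int:
        """Longest-path depth of the branch rooted at child, seen from parent."""
        best = 1
        stack = [(child, parent, 1)]
        while stack:
            current, prev, depth = stack.pop()
            best = max(best, depth)
            for nb in self._drawn_neighbours(current):
                if nb != prev and nb != parent:
                    if depth < 40:  # depth cap guards pathological graphs
                        stack.append((nb, current, depth + 1))
        return best

    def ring_centroid(self, atom: int) -> np.ndarray | None:
        for ring_id in self.ring_data.atom_rings.get(atom, ()):
            ring = self.ring_data.sssr[ring_id]
            if all(a in self.positions for a in ring):
                return np.mean([self.positions[a] for a in ring], axis=0)
        return None

    # ------------------------------------------------------------- driving
    def run(self) -> dict[int, np.ndarray]:
        offset_x = 0.0
        for component in sorted(self.structure.connected_components(),
                                key=min):
            drawn = sorted(component & self.drawn)
            if not drawn:
                continue
            placed_before = set(self.positions)
            self._place_component(drawn)
            placed = [idx for idx in self.positions
                      if idx not in placed_before]
            xs = [self.positions[idx][0] for idx in placed]
            shift = offset_x - min(xs)
            for idx in placed:
                self.positions[idx] = self.positions[idx] \
                    + np.array([shift, 0.0])
            offset_x = max(self.positions[idx][0] for idx in placed) \
                + 2.0 * self.options.bond_length
        self._enforce_cis_trans()
        return self.positions

    def _place_component(self, drawn: list[int]) -> None:
        start = self._choose_start(drawn)
        if start in self._system_of:
            self._place_ring_system(self._system_of[start], entry=start,
                                    anchor=None, direction=np.array([1.0, 0]))
        else:
            self.positions[start] = np.array([0.0, 0.0])
            self._turn[start] = 1
        # breadth-first expansion over placed atoms
        frontier = [idx for idx in sorted(self.positions) if idx in set(drawn)]
        seen_frontier = set(frontier)
        while frontier:
            current = frontier.pop(0)
            children = [nb for nb in self._drawn_neighbours(current)
                        if nb not in self.positions]
            if children:
                self._place_children(current, children)
            for nb in self._drawn_neighbours(current):
                if nb in self.positions and nb not in seen_frontier:
                    seen_frontier.add(nb)
                    frontier.append(nb)

    def _choose_start(self, drawn: list[int]) -> int:
        pool = set(drawn)
        bridged_atoms = {a for system in self.ring_class.bridged_systems
                         for a in system} & pool
        if bridged_atoms:
            return min(bridged_atoms)
        ring_atoms = sorted(a for a in self._system_of if a in pool)
        if ring_atoms:
            return ring_atoms[0]
        return min(pool)

    # -------------------------------------------------------- ring systems
    def _place_ring_system(self, system_id: int, entry: int,
                           anchor: int | None,
                           direction: np.ndarray) -> None:
        system = self._ring_systems[system_id]
        ring_ids = sorted(system)
        atoms = sorted({a for rid in ring_ids
                        for a in self.ring_data.sssr[rid]})
        is_bridged = any(self.ring_class.labels[rid] == "bridged"
                         for rid in ring_ids)
        if is_bridged:
            local = self._bridged_local(atoms)
            self.kk_atoms.update(atoms)
        else:
            local = self._polygon_local(ring_ids, entry)
        self._install_system(local, entry, anchor, direction)

    def _bridged_local(self, atoms: list[int]) -> dict[int, np.ndarray]:
        index_of = {a: i for i, a in enumerate(atoms)}
        n = len(atoms)
        distances = np.zeros((n, n))
        for a in atoms:
            # BFS inside the system
            level = {a: 0}
            queue = [a]
            while queue:
                current = queue.pop(0)
                for nb in self._drawn_neighbours(current):
                    if nb in index_of and nb not in level:
                        level[nb] = level[current] + 1
                        queue.append(nb)
            for b, d in level.items():
                distances[index_of[a], index_of[b]] = d * self.options.bond_length
        missing = distances == 0
        np.fill_diagonal(missing, False)
        distances[missing] = n * self.options.bond_length
        coords = kamada_kawai(n, distances)
        return {a: coords[index_of[a]] for a in atoms}

    def _polygon_local(self, ring_ids: list[int],
                       entry: int) -> dict[int, np.ndarray]:
        sssr = self.ring_data.sssr
        local: dict[int, np.ndarray] = {}
        start_ring = next((rid for rid in ring_ids if entry in sssr[rid]),
                          ring_ids[0])
        self._place_polygon(sssr[start_ring], local, shared=None)
        placed_rings = {start_ring}
        progress = True
        while progress:
            progress = False
            for rid in ring_ids:
                if rid in placed_rings:
                    continue
                ring = sssr[rid]
                shared = [a for a in ring if a in local]
                if not shared:
                    continue
                self._place_polygon(ring, local, shared=shared)
                placed_rings.add(rid)
                progress = True
        return local

    def _place_polygon(self, ring: tuple[int, ...],
                       local: dict[int, np.ndarray],
                       shared: list[int] | None) -> None:
        k = len(ring)
        length = self.options.bond_length
        circumradius = length / (2 * math.sin(math.pi / k))
        if not shared:
            for i, atom in enumerate(ring):
                angle = math.pi / 2 + 2 * math.pi * i / k
                local[atom] = np.array([circumradius * math.cos(angle),
                                        circumradius * math.sin(angle)])
            return
        # order ring so traversal starts at a shared atom
        ring_list = list(ring)
        anchor_atoms = [a for a in shared][:2]
        start_pos = ring_list.index(anchor_atoms[0])
        ring_list = ring_list[start_pos:] + ring_list[:start_pos]
        occupied = [p for a, p in local.items()]
        centroid_existing = (np.mean(occupied, axis=0) if occupied
                             else np.array([0.0, 0.0]))
        if len(anchor_atoms) >= 2 and (
                ring_list[1] == anchor_atoms[1]
                or ring_list[-1] == anchor_atoms[1]):
            # fused edge: build the polygon on the shared edge, away from
            # the existing centroid
            if ring_list[-1] == anchor_atoms[1]:
                ring_list = [ring_list[0]] + ring_list[:0:-1]
            a, b = ring_list[0], ring_list[1]
            pa, pb = local[a], local[b]
            edge = pb - pa
            edge_len = np.linalg.norm(edge)
            apothem = edge_len / (2 * math.tan(math.pi / k))
            midpoint = (pa + pb) / 2
            normal = _unit(np.array([-edge[1], edge[0]]))
            if np.dot(midpoint + normal - centroid_existing,
                      midpoint - centroid_existing) < np.dot(
                          midpoint - normal - centroid_existing,
                          midpoint - centroid_existing):
                normal = -normal
            centre = midpoint + normal * apothem
            base_angle = math.atan2(pa[1] - centre[1], pa[0] - centre[0])
            step_angle = math.atan2(pb[1] - centre[1], pb[0] - centre[0]) \
                - base_angle
            step_angle = math.remainder(step_angle, 2 * math.pi)
            direction = 1.0 if step_angle > 0 else -1.0
            radius = np.linalg.norm(pa - centre)
            for i, atom in enumerate(ring_list):
                if atom in local:
                    continue
                angle = base_angle + direction * 2 * math.pi * i / k
                local[atom] = centre + radius * np.array([math.cos(angle),
                                                          math.sin(angle)])
        else:
            # spiro: single shared atom; centre placed away from what exists
            a = ring_list[0]
            pa = local[a]
            direction = _unit(pa - centroid_existing)
            centre = pa + direction * circumradius
            base_angle = math.atan2(pa[1] - centre[1], pa[0] - centre[0])
            for i, atom in enumerate(ring_list):
                if atom in local:
                    continue
                angle = base_angle + 2 * math.pi * i / k
                local[atom] = centre + circumradius * np.array(
                    [math.cos(angle), math.sin(angle)])

    def _install_system(self, local: dict[int, np.ndarray], entry: int,
                        anchor: int | None, direction: np.ndarray) -> None:
        entry_local = local[entry]
        centroid_local = np.mean(list(local.values()), axis=0)
        out_local = centroid_local - entry_local
        if np.linalg.norm(out_local) < 1e-9:
            out_local = np.array([1.0, 0.0])
        if anchor is None:
            target = np.array([0.0, 0.0])
            rotation = 0.0
        else:
            target = self.positions[anchor] + direction \
                * self.options.bond_length
            rotation = math.degrees(
                math.atan2(direction[1], direction[0])
                - math.atan2(out_local[1], out_local[0]))
        for atom, pos in local.items():
            if atom in self.positions:
                continue
            vec = _rotate(pos - entry_local, rotation)
            self.positions[atom] = target + vec
            self._turn[atom] = 1

    # ------------------------------------------------------------- chains
    def _place_children(self, parent: int, children: list[int]) -> None:
        directions = self._child_directions(parent, children)
        ordered = self._order_children(parent, children)
        for child, direction in zip(ordered, directions):
            if child in self.positions:
                continue
            if child in self._system_of:
                self._place_ring_system(self._system_of[child], entry=child,
                                        anchor=parent, direction=direction)
            else:
                self.positions[child] = self.positions[parent] \
                    + direction * self.options.bond_length

    def _order_children(self, parent: int, children: list[int]) -> list[int]:
        return sorted(children,
                      key=lambda c: -self._branch_depth(c, parent))

    def _child_directions(self, parent: int,
                          children: list[int]) -> list[np.ndarray]:
        placed_nb = [nb for nb in self._drawn_neighbours(parent)
                     if nb in self.positions]
        centroid = self.ring_centroid(parent)
        if centroid is not None:
            outward = _unit(self.positions[parent] - centroid)
            k = len(children)
            if k == 1:
                return [outward]
            spread = 60.0
            offsets = np.linspace(-spread / 2, spread / 2, k)
            return [_rotate(outward, off) for off in offsets]
        if not placed_nb:
            base = np.array([1.0, 0.0])
            k = len(children)
            if k == 1:
                return [base]
            return [_rotate(base, i * 360.0 / k) for i in range(k)]
        grandparent = placed_nb[0]
        incoming = _unit(self.positions[parent] - self.positions[grandparent])
        k = len(children)
        linear = any(
            self.structure.bond_between(parent, x) is not None
            and self.structure.bond_between(parent, x).type == "triple"
            for x in children + [grandparent]
        )
        if linear and k == 1:
            return [incoming]
        if k == 1:
            turn = self._turn.get(grandparent, 1) * -1
            self._turn[parent] = turn
            return [_rotate(incoming, 60.0 * turn)]
        if k == 2:
            self._turn[parent] = 1
            return [_rotate(incoming, 60.0), _rotate(incoming, -60.0)]
        if k == 3:
            depths = sorted(
                (self._branch_depth(c, parent) for c in children))
            parent_bond = -incoming  # direction parent -> grandparent
            if depths[0] == 1 and depths[1] == 1 and depths[2] > 1:
                # two short branches: 120 between the two longest, 90
                # short-long, 60 short-short
                return [_rotate(parent_bond, 120.0),
                        _rotate(parent_bond, 210.0),
                        _rotate(parent_bond, 270.0)]
            return [_rotate(parent_bond, 180.0),
                    _rotate(parent_bond, 90.0),
                    _rotate(parent_bond, 270.0)]
        # 5+ neighbours: spread evenly over the free half-plane
        k = len(children)
        return [_rotate(incoming, -150.0 + i * 300.0 / max(k - 1, 1))
                for i in range(k)]

    # -------------------------------------------------------- stereo bonds
    def _stereo_sides(self, bond) -> tuple[int, int] | None:
        r1, r2 = bond.stereo_atoms
        if any(idx not in self.positions
               for idx in (bond.atom1, bond.atom2, r1, r2)):
            return None
        axis = self.positions[bond.atom2] - self.positions[bond.atom1]
        v1 = self.positions[r1] - self.positions[bond.atom1]
        v2 = self.positions[r2] - self.positions[bond.atom2]
        s1 = np.sign(_cross2(axis, v1))
        s2 = np.sign(_cross2(axis, v2))
        if s1 == 0 or s2 == 0:
            return None
        return int(s1), int(s2)

    def _enforce_cis_trans(self) -> None:
        adjusted: set[int] = set()
        for bond in sorted(self.structure.bonds.values(),
                           key=lambda b: b.index):
            if bond.type != "double" or bond.cis_trans is None \
                    or bond.stereo_atoms is None:
                continue
            sides = self._stereo_sides(bond)
            if sides is None:
                continue
            want_same = bond.cis_trans == "cis"
            if (sides[0] == sides[1]) == want_same:
                continue
            a1, a2 = bond.atom1, bond.atom2
            subtree = self._subtree_atoms(a2, blocked=a1) - {a2}
            if a1 not in subtree and bond.atom1 not in subtree:
                for atom in subtree:
                    self.positions[atom] = _reflect(
                        self.positions[atom], self.positions[a1],
                        self.positions[a2])
            else:
                # the double bond sits in a ring: mirror the reference
                # neighbour with the smallest protruding side chain
                fixed = self._mirror_ring_substituent(bond, adjusted)
                if not fixed:
                    raise ChiralityError(
                        "cannot depict the declared cis/trans arrangement")
            sides = self._stereo_sides(bond)
            if sides is None or (sides[0] == sides[1]) != want_same:
                raise ChiralityError(
                    "cannot depict the declared cis/trans arrangement")

    def _mirror_ring_substituent(self, bond, adjusted: set[int]) -> bool:
        candidates = []
        for end, ref in ((bond.atom1, bond.stereo_atoms[0]),
                         (bond.atom2, bond.stereo_atoms[1])):
            if ref in adjusted:
                continue
            subtree = self._subtree_atoms(ref, blocked=end)
            if bond.atom1 in subtree or bond.atom2 in subtree:
                continue  # the reference folds back into the ring
            candidates.append((len(subtree), end, ref, subtree))
        if not candidates:
            return False
        candidates.sort()
        _, end, ref, subtree = candidates[0]
        a1, a2 = bond.atom1, bond.atom2
        for atom in subtree:
            self.positions[atom] = _reflect(self.positions[atom],
                                            self.positions[a1],
                                            self.positions[a2])
        adjusted.add(ref)
        return True


def layout(structure: Structure, options: DrawOptions | None = None
           ) -> Drawing:
    """Compute 2D coordinates for a kekulised structure."""
    options = options or DrawOptions()
    engine = _LayoutEngine(structure, options)
    positions = engine.run()
    drawing = Drawing(structure=structure, positions=positions,
                      options=options)
    drawing.kamada_kawai_atoms = engine.kk_atoms
    return drawing


# ----------------------------------------------------------- clashes/finetune

def detect_clashes(drawing: Drawing) -> list[tuple[int, int]]:
    """Non-neighbouring drawn atom pairs closer than half the mean bond
    length (strictly), in deterministic sorted order."""
    atoms = drawing.drawn_atoms()
    threshold = drawing.options.clash_threshold * drawing.mean_bond_length()
    clashes = []
    structure = drawing.structure
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            if structure.bond_between(a, b) is not None:
                continue
            distance = float(np.linalg.norm(drawing.positions[a]
                                            - drawing.positions[b]))
            if distance < threshold:
                clashes.append((a, b))
    return clashes


def _rotatable(drawing: Drawing, atom1: int, atom2: int) -> bool:
    structure = drawing.structure
    bond = structure.bond_between(atom1, atom2)
    if bond is None:
        return False
    if bond.cis_trans is not None:
        return False
    for end in (atom1, atom2):
        for nb_bond in structure.bonds_of(end):
            if nb_bond.cis_trans is not None:
                return False
    ring_data = rings_module.ensure_ring_data(structure)
    if ring_data.bond_in_ring(structure, bond):
        return False
    return True


def finetune(drawing: Drawing) -> Drawing:
    """Resolve clashes by rotating subtrees around rotatable bonds.

    For every clashing pair the rotatable bond nearest the centre of their
    shortest path is selected; each selected bond is tried at every multiple
    of the rotation step and the angle minimising the total clash count is
    kept (ties break toward the smallest rotation). The clash count never
    increases because zero rotation is always a candidate.
    """
    clashes = detect_clashes(drawing)
    if not clashes:
        return drawing
    structure = drawing.structure
    selected: list[tuple[int, int]] = []
    for a, b in clashes:
        path = structure.shortest_path(a, b)
        if path is None or len(path) < 2:
            continue
        centre = (len(path) - 1) / 2
        best = None
        for i in range(len(path) - 1):
            if not _rotatable(drawing, path[i], path[i + 1]):
                continue
            distance = abs((i + 0.5) - centre)
            if best is None or distance < best[0]:
                best = (distance, (path[i], path[i + 1]))
        if best and best[1] not in selected:
            selected.append(best[1])
    step = drawing.options.rotation_step
    angles = sorted(
        (k * step for k in range(int(360 // step))),
        key=lambda angle: (min(angle, 360 - angle), angle))
    for pivot_atom, moving_atom in selected:
        subtree = _subtree(drawing, moving_atom, pivot_atom)
        pivot = drawing.positions[moving_atom]
        original = {idx: drawing.positions[idx].copy() for idx in subtree}
        best_angle = 0.0
        best_count = len(detect_clashes(drawing))
        for angle in angles:
            if angle == 0.0:
                continue
            for idx in subtree:
                drawing.positions[idx] = pivot + _rotate(
                    original[idx] - pivot, angle)
            count = len(detect_clashes(drawing))
            if count < best_count:
                best_count = count
                best_angle = angle
        for idx in subtree:
            if best_angle == 0.0:
                drawing.positions[idx] = original[idx]
            else:
                drawing.positions[idx] = pivot + _rotate(
                    original[idx] - pivot, best_angle)
    return drawing


def _subtree(drawing: Drawing, start: int, blocked: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        current = stack.pop()
        for nb in drawing.structure.neighbours(current):
            if nb.index == blocked or nb.index not in drawing.positions:
                continue
            if nb.index not in seen:
                seen.add(nb.index)
                stack.append(nb.index)
    return seen - {start}


# --------------------------------------------------------------------- wedges

def _subtree_size(structure: Structure, start: int, blocked: int) -> int:
    seen = {start}
    stack = [start]
    while stack:
        current = stack.pop()
        for nb in structure.heavy_neighbours(current):
            if nb.index != blocked and nb.index not in seen:
                seen.add(nb.index)
                stack.append(nb.index)
    return len(seen)


def assign_wedges(drawing: Drawing) -> Drawing:
    """One wedge per tetrahedral centre, chosen by priority: prefer bonds
    whose far atom neighbours at most one chiral centre, bonds outside
    rings, and the shortest branch; direction matches the declared parity."""
    structure = drawing.structure
    ring_data = rings_module.ensure_ring_data(structure)
    for atom in structure.atoms.values():
        if atom.chiral is None or len(atom.chiral_order) != 4:
            continue
        if atom.index not in drawing.positions:
            continue
        candidates = []
        for bond in structure.bonds_of(atom):
            other = structure.atom(bond.other(atom.index))
            if other.index not in drawing.positions:
                continue
            if bond.type != "single":
                continue
            chiral_neighbours = sum(
                1 for nb in structure.neighbours(other)
                if nb.chiral is not None
            )
            in_ring = ring_data.bond_in_ring(structure, bond)
            size = _subtree_size(structure, other.index, atom.index)
            candidates.append(((chiral_neighbours > 1, in_ring, size,
                                other.index), bond))
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[0])
        bond = candidates[0][1]
        wedge_to = bond.other(atom.index)
        direction = _wedge_direction(drawing, atom, wedge_to)
        drawing.wedges[bond.index] = (direction, atom.index)
    return drawing


def _wedge_direction(drawing: Drawing, atom, wedge_to: int) -> str:
    """'up' or 'down' so that the 2D depiction plus wedge reproduces the
    declared tetrahedral parity."""
    centre = drawing.positions[atom.index]
    vectors = {}
    missing = []
    for nb in atom.chiral_order:
        if nb in drawing.positions:
            v = drawing.positions[nb] - centre
            vectors[nb] = np.array([v[0], v[1], 0.0])
        else:
            missing.append(nb)
    z = 0.5 * drawing.mean_bond_length()
    if wedge_to in vectors:
        vectors[wedge_to][2] = z
    for nb in missing:  # suppressed hydrogens sit opposite the visible bonds
        opposite = -sum(vectors.values())
        vectors[nb] = opposite if np.linalg.norm(opposite) > 1e-9 \
            else np.array([0.0, 0.0, -z])
    ordered = [vectors[nb] for nb in atom.chiral_order]
    v = np.dot(ordered[1] - ordered[0],
               np.cross(ordered[2] - ordered[0], ordered[3] - ordered[0]))
    observed = "clockwise" if v > 0 else "counterclockwise"
    return "up" if observed == atom.chiral else "down"


# ------------------------------------------------------------------- pipeline

def draw_molecule(structure: Structure, options: DrawOptions | None = None
                  ) -> Drawing:
    """Full pipeline: kekulise, place atoms, resolve clashes, add wedges."""
    options = options or DrawOptions()
    working = rings_module.kekulise(structure) if structure.aromatic_systems \
        else structure.deep_copy()
    drawing = layout(working, options)
    if options.finetune:
        finetune(drawing)
    assign_wedges(drawing)
    return drawing


# -------------------------------------------------------------------- render

def _label_text(structure: Structure, atom, drawn: set[int]) -> str | None:
    degree = sum(1 for nb in structure.neighbours(atom)
                 if nb.index in drawn)
    if atom.element == "C" and atom.charge == 0 and degree > 0:
        return None
    hydrogens = sum(1 for nb in structure.neighbours(atom)
                    if nb.is_hydrogen() and nb.index not in drawn)
    text = atom.element
    if hydrogens == 1:
        text += "H"
    elif hydrogens > 1:
        text += f"H{hydrogens}"
    if atom.charge == 1:
        text += "+"
    elif atom.charge == -1:
        text += "-"
    elif atom.charge:
        text += f"{atom.charge:+d}"
    return text


class _Canvas:
    """Geometry shared by the SVG and PNG back ends."""

    def __init__(self, drawing: Drawing):
        self.drawing = drawing
        options = drawing.options
        positions = drawing.positions
        xs = [p[0] for p in positions.values()]
        ys = [p[1] for p in positions.values()]
        pad = options.padding
        self.min_x = min(xs) - pad
        self.max_y = max(ys) + pad
        self.width = (max(xs) - min(xs) + 2 * pad) * options.scale
        self.height = (max(ys) - min(ys) + 2 * pad) * options.scale

    def to_screen(self, point: np.ndarray) -> tuple[float, float]:
        options = self.drawing.options
        return ((point[0] - self.min_x) * options.scale,
                (self.max_y - point[1]) * options.scale)


def _render_primitives(drawing: Drawing):
    """Resolution-independent primitives: lines, polygons, hashes, labels."""
    structure = drawing.structure
    drawn = set(drawing.positions)
    scale = drawing.options.scale
    mean_len = drawing.mean_bond_length()
    labels = {}
    for idx in drawing.drawn_atoms():
        text = _label_text(structure, structure.atom(idx), drawn)
        if text:
            labels[idx] = text
    primitives = []  # (kind, payload, colour)

    def shorten(p, q, at_p: bool, at_q: bool):
        gap = 0.25 * mean_len
        d = _unit(q - p)
        p2 = p + d * gap if at_p else p
        q2 = q - d * gap if at_q else q
        return p2, q2

    for bond in drawing.drawn_bonds():
        p = drawing.positions[bond.atom1]
        q = drawing.positions[bond.atom2]
        colour = drawing.bond_colours.get(bond.index, "black")
        p2, q2 = shorten(p, q, bond.atom1 in labels, bond.atom2 in labels)
        wedge = drawing.wedges.get(bond.index)
        if wedge is not None:
            direction, from_atom = wedge
            tail = drawing.positions[from_atom]
            head = drawing.positions[bond.other(from_atom)]
            tail, head = shorten(tail, head, from_atom in labels,
                                 bond.other(from_atom) in labels)
            axis = _unit(head - tail)
            normal = np.array([-axis[1], axis[0]]) * 0.09 * mean_len
            if direction == "up":
                primitives.append(("polygon",
                                   [tuple(tail), tuple(head + normal),
                                    tuple(head - normal)], colour))
            else:
                hashes = 6
                for i in range(1, hashes + 1):
                    t = i / hashes
                    centre_point = tail + (head - tail) * t
                    half = normal * t
                    primitives.append(("line",
                                       (tuple(centre_point - half),
                                        tuple(centre_point + half)), colour))
            continue
        if bond.type in ("double", "quadruple"):
            offset_dir = np.array([-(q2 - p2)[1], (q2 - p2)[0]])
            offset = _unit(offset_dir) * 0.06 * mean_len
            primitives.append(("line", (tuple(p2 + offset),
                                        tuple(q2 + offset)), colour))
            primitives.append(("line", (tuple(p2 - offset),
                                        tuple(q2 - offset)), colour))
            if bond.type == "quadruple":
                off3 = _unit(offset_dir) * 0.18 * mean_len
                primitives.append(("line", (tuple(p2 + off3),
                                            tuple(q2 + off3)), colour))
                primitives.append(("line", (tuple(p2 - off3),
                                            tuple(q2 - off3)), colour))
        elif bond.type == "triple":
            offset = _unit(np.array([-(q2 - p2)[1], (q2 - p2)[0]])) \
                * 0.11 * mean_len
            primitives.append(("line", (tuple(p2), tuple(q2)), colour))
            primitives.append(("line", (tuple(p2 + offset),
                                        tuple(q2 + offset)), colour))
            primitives.append(("line", (tuple(p2 - offset),
                                        tuple(q2 - offset)), colour))
        else:
            primitives.append(("line", (tuple(p2), tuple(q2)), colour))
    for idx, text in labels.items():
        colour = drawing.atom_colours.get(idx, "black")
        primitives.append(("text", (tuple(drawing.positions[idx]), text),
                           colour))
    return primitives


def render_svg(drawing: Drawing) -> str:
    """Serialise the drawing to an SVG 1.1 document (y axis flipped here)."""
    canvas = _Canvas(drawing)
    options = drawing.options
    stroke = options.line_width * options.scale
    font = options.font_size * options.scale
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{canvas.width:.1f}" height="{canvas.height:.1f}" '
        f'viewBox="0 0 {canvas.width:.1f} {canvas.height:.1f}">',
        f'<rect width="100%" height="100%" fill="{options.background}"/>',
    ]
    for kind, payload, colour in _render_primitives(drawing):
        if kind == "line":
            (x1, y1), (x2, y2) = (canvas.to_screen(np.array(p))
                                  for p in payload)
            parts.append(
                f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" '
                f'y2="{y2:.2f}" stroke="{colour}" '
                f'stroke-width="{stroke:.2f}" stroke-linecap="round"/>')
        elif kind == "polygon":
            points = " ".join(
                "{:.2f},{:.2f}".format(*canvas.to_screen(np.array(p)))
                for p in payload)
            parts.append(f'<polygon points="{points}" fill="{colour}"/>')
        elif kind == "text":
            (x, y) = canvas.to_screen(np.array(payload[0]))
            parts.append(
                f'<text x="{x:.2f}" y="{y:.2f}" font-size="{font:.1f}" '
                f'font-family="Helvetica, Arial, sans-serif" '
                f'text-anchor="middle" dominant-baseline="central" '
                f'fill="{colour}" stroke="{options.background}" '
                f'stroke-width="{stroke * 4:.2f}" '
                f'paint-order="stroke">{payload[1]}</text>')
    parts.append("</svg>")
    return "\n".join(parts)


def render_png(drawing: Drawing, path: str) -> None:
    """Rasterise the same primitives with Pillow."""
    canvas = _Canvas(drawing)
    options = drawing.options
    image = Image.new("RGB", (max(1, int(canvas.width)),
                              max(1, int(canvas.height))),
                      parse_colour(options.background))
    painter = ImageDraw.Draw(image)
    stroke = max(1, int(options.line_width * options.scale))
    font = ImageFont.load_default(size=options.font_size * options.scale)
    for kind, payload, colour in _render_primitives(drawing):
        rgb = parse_colour(colour)
        if kind == "line":
            p1 = canvas.to_screen(np.array(payload[0]))
            p2 = canvas.to_screen(np.array(payload[1]))
            painter.line([p1, p2], fill=rgb, width=stroke)
        elif kind == "polygon":
            points = [canvas.to_screen(np.array(p)) for p in payload]
            painter.polygon(points, fill=rgb)
        elif kind == "text":
            point = canvas.to_screen(np.array(payload[0]))
            painter.text(point, payload[1], fill=rgb, font=font,
                         anchor="mm")
    image.save(path, format="PNG")


def render(drawing: Drawing, path: str, fmt: str | None = None) -> None:
    """Write the drawing to an SVG or PNG file."""
    if fmt is None:
        fmt = "png" if str(path).lower().endswith(".png") else "svg"
    if fmt == "svg":
        with open(path, "w", encoding="utf8") as handle:
            handle.write(render_svg(drawing))
    elif fmt == "png":
        render_png(drawing, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ----------------------------------------------------------------- MOL files

def write_molfile(drawing: Drawing, path: str | None = None) -> str:
    """Serialise coordinates and connectivity as MDL MOL V2000.

    Wedge stereo flags: 1 = up, 6 = down, written on the bond whose first
    atom is the chiral centre. Charges go into M CHG lines. Returns the text
    (and writes it when a path is given).
    """
    atoms = drawing.drawn_atoms()
    if len(atoms) > 999:
        raise StructureError(StructureError.BONDING,
                             "MOL V2000 supports at most 999 atoms")
    number = {idx: i + 1 for i, idx in enumerate(atoms)}
    structure = drawing.structure
    bonds = drawing.drawn_bonds()
    lines = ["", "  molkit", ""]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for idx in atoms:
        x, y = drawing.positions[idx]
        element = structure.atom(idx).element
        lines.append(f"{x:10.4f}{y:10.4f}{0.0:10.4f} {element:<3}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    order_code = {"single": 1, "double": 2, "triple": 3, "quadruple": 4,
                  "aromatic": 4}
    for bond in sorted(bonds, key=lambda b: b.index):
        a1, a2 = bond.atom1, bond.atom2
        stereo = 0
        wedge = drawing.wedges.get(bond.index)
        if wedge is not None:
            direction, from_atom = wedge
            if from_atom != a1:
                a1, a2 = a2, a1
            stereo = 1 if direction == "up" else 6
        lines.append(f"{number[a1]:3d}{number[a2]:3d}"
                     f"{order_code[bond.type]:3d}{stereo:3d}  0  0  0")
    charged = [(number[idx], structure.atom(idx).charge)
               for idx in atoms if structure.atom(idx).charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        line = f"M  CHG{len(chunk):3d}"
        for num, charge in chunk:
            line += f"{num:4d}{charge:4d}"
        lines.append(line)
    lines.append("M  END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf8") as handle:
            handle.write(text)
    return text
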