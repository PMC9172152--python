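"""Element reference data: atomic numbers, standard atomic weights, allowed
valences and electron-shell layout.

Weights are the standard (isotope-averaged) values rounded to two decimals;
isotopic differentiation is unsupported, so a single constant per element is
all the kit ever needs.
"""

from __future__ import annotations

# symbol -> (atomic number, standard atomic weight)
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.01), "He": (2, 4.00),
    "Li": (3, 6.94), "Be": (4, 9.01), "B": (5, 10.81), "C": (6, 12.01),
    "N": (7, 14.01), "O": (8, 16.00), "F": (9, 19.00), "Ne": (10, 20.18),
    "Na": (11, 22.99), "Mg": (12, 24.31), "Al": (13, 26.98),
    "Si": (14, 28.09), "P": (15, 30.97), "S": (16, 32.07),
    "Cl": (17, 35.45), "Ar": (18, 39.95),
    "K": (19, 39.10), "Ca": (20, 40.08), "Sc": (21, 44.96),
    "Ti": (22, 47.87), "V": (23, 50.94), "Cr": (24, 52.00),
    "Mn": (25, 54.94), "Fe": (26, 55.85), "Co": (27, 58.93),
    "Ni": (28, 58.69), "Cu": (29, 63.55), "Zn": (30, 65.38),
    "Ga": (31, 69.72), "Ge": (32, 72.63), "As": (33, 74.92),
    "Se": (34, 78.97), "Br": (35, 79.90), "Kr": (36, 83.80),
    "Rb": (37, 85.47), "Sr": (38, 87.62), "Y": (39, 88.91),
    "Zr": (40, 91.22), "Nb": (41, 92.91), "Mo": (42, 95.95),
    "Tc": (43, 98.00), "Ru": (44, 101.07), "Rh": (45, 102.91),
    "Pd": (46, 106.42), "Ag": (47, 107.87), "Cd": (48, 112.41),
    "In": (49, 114.82), "Sn": (50, 118.71), "Sb": (51, 121.76),
    "Te": (52, 127.60), "I": (53, 126.90), "Xe": (54, 131.29),
    "Cs": (55, 132.91), "Ba": (56, 137.33), "La": (57, 138.91),
    "W": (74, 183.84), "Pt": (78, 195.08), "Au": (79, 196.97),
    "Hg": (80, 200.59), "Pb": (82, 207.20), "Bi": (83, 208.98),
}

# Organic ("bare symbol") subset of SMILES.
ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

AROMATIC_SYMBOLS = {"b", "c", "n", "o", "p", "s", "se", "as"}

# Neutral-atom valence options, smallest first.
_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "Br": (1,),
    "I": (1, 3, 5, 7),
    "Si": (4,),
    "Se": (2, 4, 6),
    "As": (3, 5),
    "Te": (2, 4, 6),
}

# (element, charge) -> valence options where the neutral table does not apply.
_CHARGED_VALENCES: dict[tuple[str, int], tuple[int, ...]] = {
    ("C", -1): (3,), ("C", 1): (3,),
    ("N", 1): (4,), ("N", -1): (2,),
    ("O", 1): (3,), ("O", -1): (1,),
    ("S", 1): (3, 5), ("S", -1): (1,),
    ("P", 1): (4,), ("P", -1): (2,),
    ("B", -1): (4,),
    ("F", -1): (0,), ("Cl", -1): (0,), ("Br", -1): (0,), ("I", -1): (0,),
    ("H", 1): (0,), ("H", -1): (0,),
}

# Main-group counts of valence electrons for the supported chemistry.
_GROUP_ELECTRONS: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "Si": 4, "N": 5, "P": 5, "As": 5,
    "O": 6, "S": 6, "Se": 6, "Te": 6,
    "F": 7, "Cl": 7, "Br": 7, "I": 7,
}


def atomic_number(element: str) -> int:
    return ELEMENTS[element][0]


def atomic_weight(element: str) -> float:
    return ELEMENTS[element][1]


def is_known_element(element: str) -> bool:
    return element in ELEMENTS


def allowed_valences(element: str, charge: int = 0) -> tuple[int, ...] | None:
    """Valence options for an element/charge pair, smallest first.

    Returns None for elements outside the table (e.g. metals); callers then
    accept whatever bond-order sum the input provides.
    """
    if charge != 0 and (element, charge) in _CHARGED_VALENCES:
        return _CHARGED_VALENCES[(element, charge)]
    if charge == 0 and element in _VALENCES:
        return _VALENCES[element]
    if element in _VALENCES:
        # Uncommon charge on a tabulated element: fall back to the neutral
        # options; validation still catches impossible bond counts.
        return _VALENCES[element]
    return None


def valence_electrons(element: str, charge: int = 0) -> int | None:
    ve = _GROUP_ELECTRONS.get(element)
    if ve is None:
        return None
    return ve - charge


# Aufbau filling order restricted to shells n<=4 with s/p/d subshells, which
# covers the supported element set (f orbitals are never populated here).
SUBSHELL_ORDER: tuple[tuple[int, str], ...] = (
    (1, "s"), (2, "s"), (2, "p"), (3, "s"), (3, "p"), (4, "s"),
    (3, "d"), (4, "p"), (5, "s"), (4, "d"), (5, "p"), (6, "s"), (5, "d"),
)

SUBSHELL_CAPACITY = {"s": 1, "p": 3, "d": 5}  # orbitals per subshell
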