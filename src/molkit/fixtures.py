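"""Seeded generation of valid test SMILES.

Molecules are assembled from a library of valence-safe fragment templates
(chains, rings, aromatics, charged groups, stereocentres, stereo double
bonds), so every emitted string parses by construction. The same seed and
spec always produce the same list, and each enabled feature is guaranteed to
occur at least once per batch.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field


@dataclass(frozen=True)
class FixtureSpec:
    """What a batch of generated SMILES should contain."""

    seed: int = 0
    count: int = 10
    min_size: int = 3          # heavy atoms, approximate lower bound
    max_size: int = 20         # heavy atoms, approximate upper bound
    rings: bool = True
    aromatics: bool = True
    charges: bool = True
    stereocentres: bool = True
    cis_trans: bool = True
    heteroatoms: bool = True


# (template, heavy-atom count, feature tag); each template is attachable as
# a branch behind one bond
_CHAIN = [("C", 1, None), ("CC", 2, None), ("CCC", 3, None),
          ("C(C)C", 3, None), ("CC(C)C", 4, None), ("CCCC", 4, None)]
_HETERO = [("O", 1, "heteroatoms"), ("N", 1, "heteroatoms"),
           ("OC", 2, "heteroatoms"), ("C#N", 2, "heteroatoms"),
           ("Cl", 1, "heteroatoms"), ("F", 1, "heteroatoms"),
           ("Br", 1, "heteroatoms"), ("C(=O)O", 3, "heteroatoms"),
           ("C(=O)N", 3, "heteroatoms"), ("S", 1, "heteroatoms"),
           ("C=O", 2, "heteroatoms")]
_RINGS = [("C1CCCCC1", 6, "rings"), ("C1CCCC1", 5, "rings"),
          ("C1CCOC1", 5, "rings"), ("C1CCNCC1", 6, "rings"),
          ("C1CC1", 3, "rings"), ("C2CCC(C)CC2", 7, "rings")]
_AROMATICS = [("c1ccccc1", 6, "aromatics"), ("c1ccncc1", 6, "aromatics"),
              ("c1cc[nH]c1", 5, "aromatics"), ("c1ccoc1", 5, "aromatics"),
              ("c1ccc2ccccc2c1", 10, "aromatics"),
              ("c1ccsc1", 5, "aromatics")]
_CHARGES = [("[NH3+]", 1, "charges"), ("C(=O)[O-]", 3, "charges"),
            ("[O-]", 1, "charges"), ("[N+](C)(C)C", 4, "charges")]
_STEREO = [("[C@@H](C)O", 3, "stereocentres"), ("[C@H](N)C", 3, "stereocentres"),
           ("[C@@H](F)CC", 4, "stereocentres"),
           ("[C@H](O)C(=O)O", 5, "stereocentres")]
_CIS_TRANS = [("/C=C/C", 3, "cis_trans"), ("/C=C\\C", 3, "cis_trans"),
              ("/C=C/CC", 4, "cis_trans"), ("/C=C(C)\\C", 4, "cis_trans")]

_FEATURES = ("rings", "aromatics", "charges", "stereocentres", "cis_trans",
             "heteroatoms")


def _template_pool(spec: FixtureSpec) -> list[tuple[str, int, str | None]]:
    pool = list(_CHAIN)
    if spec.heteroatoms:
        pool += _HETERO
    if spec.rings:
        pool += _RINGS
    if spec.aromatics:
        pool += _AROMATICS
    if spec.charges:
        pool += _CHARGES
    if spec.stereocentres:
        pool += _STEREO
    if spec.cis_trans:
        pool += _CIS_TRANS
    return pool


def _build_molecule(rng: random.Random, spec: FixtureSpec,
                    forced: list[tuple[str, int, str | None]]) -> str:
    target = rng.randint(spec.min_size, spec.max_size)
    pool = _template_pool(spec)
    heavy = 1
    branches: list[str] = []
    for template, size, _tag in forced:
        branches.append(template)
        heavy += size
    while heavy < target:
        template, size, _tag = rng.choice(pool)
        if heavy + size > target + 2:
            template, size = "C", 1
        branches.append(template)
        heavy += size
    # attach at most 3 branches directly; chain the rest linearly
    text = "C"
    direct = branches[:3]
    rest = branches[3:]
    for branch in direct:
        text += f"({branch})" if not branch.startswith("/") else f"({branch})"
    for branch in rest:
        text += f"C({branch})"
    return text


def generate_test_smiles(spec: FixtureSpec) -> list[str]:
    """A deterministic batch of valid SMILES matching the spec."""
    if spec.count <= 0:
        raise ValueError("count must be positive")
    if spec.min_size < 1 or spec.max_size < spec.min_size:
        raise ValueError("invalid size range")
    if spec.aromatics and spec.max_size < 5:
        raise ValueError("aromatic rings need at least 5 heavy atoms")
    if spec.rings and spec.max_size < 3:
        raise ValueError("rings need at least 3 heavy atoms")
    rng = random.Random(spec.seed)
    forced_templates = []
    if spec.rings:
        forced_templates.append(_RINGS[0])
    if spec.aromatics:
        forced_templates.append(_AROMATICS[0])
    if spec.charges:
        forced_templates.append(_CHARGES[0])
    if spec.stereocentres:
        forced_templates.append(_STEREO[0])
    if spec.cis_trans:
        forced_templates.append(_CIS_TRANS[0])
    if spec.heteroatoms:
        forced_templates.append(_HETERO[0])
    per_molecule: list[list] = [[] for _ in range(spec.count)]
    for i, template in enumerate(forced_templates):
        per_molecule[i % spec.count].append(template)
    return [_build_molecule(rng, spec, per_molecule[i])
            for i in range(spec.count)]
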