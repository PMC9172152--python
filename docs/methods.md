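# Methods

## The molecular graph and its electron model

A molecule is an undirected labelled graph: nodes are atoms (hydrogens
included as real nodes once parsing completes), edges are bonds typed
single/double/triple/quadruple/aromatic. Validation is electron-based
rather than rule-table-based: each heavy atom gets an electron
configuration (Aufbau filling over shells n ≤ 4 with s/p/d subshells, at
most two electrons per orbital), and forming `v` bonds requires `v`
unpaired electrons in the valence shell, obtained by exciting paired
electrons into vacant valence orbitals. This single mechanism yields the
familiar valence rules as consequences: sulphur and phosphorus expand into
3d orbitals (valences 2/4/6 and 3/5), while a neutral nitrogen cannot reach
valency 5 because its valence shell has only four orbitals — the error such
an input raises is "Basic bonding laws have been violated".

Valency assignment picks the smallest allowed valence (charge-adjusted)
that is ≥ the atom's bond-order sum; the difference between assigned
valency and realised bonds is kept as unpaired electrons, which makes
sub-valent bracket atoms such as `[CH3]` representable without a separate
radical model. After bonding, non-bonding electrons are paired into the
lowest valence orbitals ("dropped back"), and lone pairs are counted as
`(valence electrons − valency) / 2`. Hybridisation is the steric number
(σ neighbours + lone pairs, minus any lone pair promoted into an aromatic
system) mapped 1→s … 6→sp3d2.

### The nitro correction

SMILES databases frequently write nitro groups as `N(=O)=O`, a formally
pentavalent nitrogen. When such a nitrogen has at least one doubly bonded
neutral oxygen, that double bond is reinterpreted as single with O⁻ and N⁺,
giving valency 4. Without such an oxygen the structure is rejected as a
bonding-law violation.

## SMILES reading and writing

The reader supports the organic subset (B C N O P S F Cl Br I, aromatic
b c n o p s), bracket atoms with charges, explicit hydrogen counts and
@/@@ tetrahedral marks, ring closures 0–9 and `%nn`, branches, `.`
components and the bond symbols `- = # $ : / \`. Isotope digits inside
brackets are accepted and discarded (isotopic differentiation is
unsupported; atomic weight is a per-element constant throughout the kit).

For lowercase aromatic atoms the per-atom π assignment follows a
Daylight-style rule: an atom whose charge-adjusted valence exceeds its
σ-bond count by exactly 1 contributes one π electron; an atom whose valence
equals its σ count donates a lone pair (pyrrole N, furan O); anything else
is an error. For aromatic carbons this is numerically identical to counting
aromatic bonds as 1.5 and rounding up; for donor heteroatoms the 1.5 rule
would overshoot the element's valence, which is why the π-slot formulation
is used.

Tetrahedral chirality is stored as the written mark plus the neighbour
order in which the SMILES listed the four substituents (the bracket
hydrogen occupies its written position). Double-bond stereochemistry is
resolved from directional bonds into a per-bond cis/trans flag plus a pair
of reference substituents, one per end; two directional marks implying the
same side on one end raise "Conflicting double bond stereochemistry" at
parse time.

The writer emits kekulised SMILES by a deterministic depth-first walk from
the lowest atom index, bracketing atoms only when charge, stereo or a
non-default hydrogen count requires it. Chirality marks are re-derived by
comparing the permutation parity of the stored neighbour order against the
emitted order. Directional bonds are assigned by 2-colouring a constraint
graph: each stereo bond constrains its two reference bonds (equal sides for
cis, opposite for trans) and second substituents on one end must take the
opposite side; a breadth-first assignment propagates values through
conjugated chains. No canonicalisation is claimed — round-trip fidelity is
the contract, checked structurally and, in the tests, against an external
canonicaliser.

## Rings, aromaticity, kekulisation

All elementary cycles are enumerated by a depth-first search rooted at each
cycle's smallest atom (cycles below length 3 are discarded); a configurable
ceiling (10⁶ cycles / 10⁷ search steps) rejects fullerene-like cage inputs
with a clear error instead of appearing to hang. The SSSR is a minimum
cycle basis chosen greedily smallest-first over GF(2) bond-incidence
vectors, ties broken by the lexicographically smallest sorted atom tuple so
results are deterministic.

Aromaticity is perceived per SSSR cycle, recursively. A candidate cycle
must consist of sp2 atoms or sp3 atoms with a delocalisable lone pair (the
hybridisation screen doubles as the planarity criterion; no geometric test
is used). The Hückel count is the number of in-cycle double bonds plus
contributed lone pairs — odd means aromatic (equivalent to 4n + 2 π
electrons). Aromatic stretches inherited from lowercase input or from
previously aromatised neighbouring cycles are "locally kekulised" by a
maximum matching over the cycle's unused π-capable atoms, which makes the
count independent of where the traversal starts. Marking a cycle aromatic
retypes its bonds, promotes donor lone pairs to p orbitals (new
hybridisation sp2) and can enable a neighbouring cycle in the next round;
iteration stops when the aromatic cycle count is stable, which takes at
most |SSSR| rounds. Aromatic cycles sharing a bond merge into aromatic
systems whose electron pool is the sum of surrendered π electrons (1 per π
contributor, 2 per donor). At most one lone pair per atom counts; exocyclic
double bonds contribute nothing.

Unspecified bonds between aromatic atoms that end up outside any aromatic
cycle are demoted to single bonds when they are acyclic (the biphenyl
linker); a ring written aromatic that fails the Hückel test is rejected.
One consequence of strictly per-cycle counting: azulene-type 5–7 fused
aromatics are not perceived (the 5-ring counts two doubles, the 7-ring
three), so lowercase azulene input is rejected; its kekulé spelling parses
with localised double bonds. This mirrors the per-cycle design choice
rather than a bug in it.

Kekulisation runs per aromatic system: a maximum-cardinality matching
(Edmonds blossom, verified against an independent implementation in the
tests) over π-contributing atoms restricted to the system's bonds; matched
bonds become double, the rest single, and lone-pair donors are never
matched. A system without a perfect matching over its π contributors is a
malformed input and raises a `StructureError`.

## 2D layout

Bond length is 1.0 internal unit (scaled at render time; 50 px per bond by
default, with font size 0.5 and line width 0.05 bond lengths so the ratios
are constant across drawings). The y axis points up internally; the flip
happens at SVG/PNG serialisation.

Rings are classified simple / overlapping / bridged: bridged when a ring
shares more than two atoms with another ring, contains an atom in three or
more rings, or shares atoms with another bridged ring (applied to a fixed
point); rings sharing one or two atoms are overlapping; isolated rings are
simple. Placement starts inside a ring when one exists, preferring bridged
systems. Simple and overlapping ring systems are laid out with regular
polygons — fused rings built on the shared edge away from the existing
centroid, spiro rings tangent at the shared atom. Bridged systems are
relaxed with a Kamada–Kawai force-spring model: desired distance = graph
distance × bond length, nodes initialised on a circle, stress gradient
descent until the largest displacement is below 10⁻⁴ or 2000 iterations
(tolerances chosen for visual stability, not physical meaning). Chain atoms
are placed one bond from their parent: 120° zigzag for up to three heavy
neighbours; four neighbours default to 90° except when exactly two branches
have depth exactly 1, where the two longest branches sit 120° apart, short
against long at 90° and short against short at 60°; the deepest subtree
continues opposite the parent; branch depth is longest-path depth (subtree
size was the noted alternative). Ring substituents point outward from the
ring centroid. Disconnected components are laid out separately and placed
side by side.

Declared cis/trans geometry is enforced after placement by reading the bond
objects (never the input text): a wrongly drawn stereo bond has the subtree
behind its second atom mirrored across the bond axis; when the bond lies in
a ring, the reference neighbour with the smallest protruding side chain
(heavy-atom subtree count) is mirrored instead, consecutive ring
stereobonds are adjusted in order and no neighbour of the same bond is
rotated twice. If the declared arrangement still cannot be drawn, a
`ChiralityError` is raised.

A clash is two non-neighbouring drawn atoms strictly closer than half the
mean bond length. The optional finetuning pass takes each clashing pair,
finds the shortest path between them, selects the rotatable bond nearest
the path centre (bonds are unrotatable when they carry cis/trans marks, sit
next to such a bond, or lie in a cycle) and evaluates all twelve 30°
rotations of the smaller subtree, keeping the angle with the fewest clashes
(ties to the smallest rotation; zero rotation is always a candidate, so the
clash count never increases).

Each tetrahedral centre receives one wedge, preferring bonds whose far atom
neighbours at most one chiral centre, then bonds outside rings, then the
shortest branch. The wedge direction (solid = up, hashed = down) is chosen
so that the signed volume of the four substituent vectors — in-plane
positions, the wedge neighbour lifted out of plane, suppressed hydrogens
placed opposite the visible bonds — reproduces the declared parity; the
tests verify the convention independently by writing MOL files and reading
them back with an external toolkit.

Macrocycles are drawn as regular polygons (the honeycomb style is out of
scope). Output formats: SVG 1.1 (primary, bit-stable), PNG rasterised from
the same primitives with Pillow, and MOL V2000 with wedge flags 1/6 and
`M CHG` charge lines; hydrogens are suppressed in output and shown as part
of heteroatom labels. Atom and bond colours accept hex codes and
descriptive names.

## Substructure matching

Hydrogens are ignored in all stages. 1) element counts; 2) a local screen
requiring, for every query atom, a parent atom with the same element,
charge and aromaticity whose (bond type, neighbour element) multiset
contains the query atom's; 3) a depth-first embedding seeded at the query
atom whose (element, degree, neighbour-element multiset) signature is
rarest in the parent — "most diverse connectivity" made concrete — with
ties to the lowest index; 4) chiral centres compared by mapping the query's
neighbour order through the embedding and testing permutation parity, with
hydrogens as lowest-priority phantom neighbours; 5) cis/trans compared via
the reference substituents with a flip per reference that maps to the
opposite substituent. Undefined query stereo matches defined parent stereo,
never the reverse. Symmetry-equivalent embeddings onto the same parent atom
set collapse to one match by default (`all_mappings=True` keeps them); this
keeps highlighting counts sensible.

## Fingerprints

The initial per-atom identifier is a 32-bit truncation of a SHA-256 digest
of the 7-tuple (heavy-neighbour count, valency, atomic number, standard
atomic weight quantised to two decimals, charge, hydrogen-neighbour count,
ring membership); a cryptographic digest of a canonical byte serialisation
is used because the host language's hash is randomised per process. Each
iteration (default radius 2, ECFP-4) rehashes every atom with its sorted
(bond-order tag, neighbour identifier) pairs — neighbours are always at
graph distance one from the centre, and the bond-order tag is the
distance-related discriminator retained from the two candidate readings —
plus a canonical chirality tag once the centre's neighbours carry distinct
identifiers (parity is evaluated against the neighbour order sorted by
identifier, so the tag is independent of input atom order; enantiomers
therefore differ). Deduplication removes equal identifiers and identifiers
whose environments span the same atom set, keeping the smaller radius and
then the smaller identifier. Tanimoto similarity is |A∩B|/|A∪B| with two
empty sets defined as 1. Bit vectors fold identifiers modulo the configured
length (default 1024) and carry a legend mapping each set bit to a loose
serialisation of a representative substructure.

## Reactions

Targets are defined by a substructure SMILES and one or two heavy-atom
indices in its SMILES order; occurrences are located by substructure search
and returned oriented as written, which fixes regiochemistry: hydrolysis
attaches OH to the side named first in the definition and H to the leaving
side, then splits the products. The hydrolysable-bond check demands a
single bond from an acyl-like atom (one with a doubly bonded O or S) to an
N/O/S leaving atom. Condensation removes a hydroxyl from one partner and a
hydrogen from the other and joins them with a single bond — the exact
inverse of hydrolysis up to graph isomorphism. Ketoreduction removes the π
electrons of a C=O bond, sets it single, rehybridises both atoms to sp3,
adds one hydrogen to each and annotates the new hydroxyl group (annotation
name `reduced`) for highlighting; the configuration of the new alcohol
carbon is deliberately left undefined (a parameter-free choice; setting
product stereochemistry is left to the caller). Primitive edits cap freed
valences with hydrogen by default; `cap=None` defers validation so several
edits can be chained before one refresh, which then re-runs the full
valence/ring/aromaticity pipeline and accepts only chemically legal
results (an under-bonded atom is represented as carrying unpaired
electrons; an over-bonded one is rejected).

## The SMILES generator

`generate_test_smiles` assembles molecules from valence-safe fragment
templates — saturated chains, heteroatom groups, alicyclic rings, aromatic
rings, charged groups, tetrahedral centres, stereo double bonds — attached
as branches to a backbone, so every emitted string parses by construction.
The same seed and spec give byte-identical batches, and each enabled
feature class appears at least once per batch. Sizes default to 3–20 heavy
atoms, the range the rest of the suite exercises. The generator emulates
the *syntactic and chemical feature mix* of curated natural-product SMILES
(rings, fused aromatics, charges, stereochemistry) but not their scale or
statistics: it does not produce macrocycles beyond the template rings,
polycyclic cages, unusual elements, or the size distribution of a real
database — so passing tests demonstrate correctness of the algorithms on
representative chemistry, not database-scale coverage or timing.

## Problem sizes used in the tests

The suite runs on a curated 50-molecule corpus plus seeded generator
batches: 1000 molecules for the SMILES round-trip check, 500 for the
finetuning monotonicity property, 200 random graphs (≤ 14 nodes) for the
SSSR oracle, and query/parent pairs of ≤ 12 heavy atoms for exhaustive
substructure enumeration — sizes at which the independent oracles
(exhaustive enumeration, an external canonicaliser and MOL reader, and a
second matching implementation) are exact.

## Known limitations

* No isotopes (accepted, ignored), no radicals beyond unpaired-electron
  bookkeeping, no 3D, no SMARTS, no reaction SMILES / atom mapping.
* Per-cycle Hückel perception misses system-level aromaticity (azulene).
* Quadruple bonds are parsed and drawn plainly but excluded from
  aromaticity.
* The drawing engine optimises readability heuristically; heavily bridged
  or macrocyclic systems can render distorted even when chemically correct.
* Canonical SMILES are not produced; equality checks should go through
  graph isomorphism or an external canonicaliser.
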