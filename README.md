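# molkit

A dependency-light cheminformatics kit for Python, aimed at bio- and
cheminformatics pipelines that need basic chemical processing — reading
SMILES, validating chemistry, drawing structures, finding substructures,
fingerprinting and building simple reactions — without pulling in a heavy
toolkit. Its only runtime dependencies are numpy, Pillow and click.

## What it does

* **SMILES → validated molecular graph.** A `Structure` is a graph of
  `Atom` and `Bond` objects with hydrogens as real nodes. Valencies are
  assigned as the smallest allowed valence ≥ the bond-order sum (S: 2/4/6,
  P: 3/5, …), electron shells are built per atom and electrons excited into
  valence orbitals to supply one unpaired electron per bond — so a carbon
  with five bonds is *physically* impossible and raises a `StructureError`
  ("Basic bonding laws have been violated"). Pentavalent nitro nitrogens
  written `N(=O)=O` are tolerated and rewritten to the charge-separated
  form `[N+](=O)[O-]` (N valency 4).
* **Ring perception and aromaticity.** All simple cycles are enumerated,
  the smallest set of smallest rings (SSSR) is chosen as a minimum cycle
  basis, and aromaticity is perceived per cycle with Hückel's 4n + 2 rule,
  applied recursively: a cycle of sp2 atoms (or sp3 atoms with a
  delocalisable lone pair) is aromatic when its in-cycle double bonds plus
  contributed lone pairs sum to an odd number. Aromatic electrons are
  pooled in `AromaticSystem` objects; kekulisation assigns alternating
  double bonds through an Edmonds blossom maximum matching.
* **2D drawing.** Polygon geometry for simple/fused rings, Kamada–Kawai
  force-spring refinement for bridged systems, depth-first chain placement
  with neighbour-count-dependent angles, declared cis/trans geometry
  enforced from bond objects, clash detection (non-neighbours closer than
  half a bond length) with a 30°-step "finetuning" rotation pass, and wedge
  assignment for tetrahedral centres. Output: SVG, PNG, MOL V2000.
* **Substructure search** with element/connectivity pre-filters, a seeded
  depth-first embedding, and independent chirality and cis/trans checks;
  match highlighting in one call.
* **ECFP fingerprints** (default radius 2 = ECFP-4) built from seven atom
  invariants and iterative neighbour hashing, Tanimoto similarity/distance,
  and bit-vector featurisation with substructure legends.
* **Reactions as validated graph edits**: target definitions (substructure
  SMILES + one or two atom indices, e.g. `("C(=O)NC", 0, 2)` for a peptide
  bond), primitives for breaking/making bonds and adding/removing atoms,
  plus built-in hydrolysis, condensation and ketoreduction. Every product
  passes the same valence validation as parsed input.

## Worked example

Reduce the β-keto group of acetoacetic acid and compare substrate and
product:

```python
from molkit import parse_smiles, write_smiles, ecfp, tanimoto
from molkit.reactions import TargetDefinition, find_targets, ketoreduce
from molkit.drawing import draw_molecule, detect_clashes, render

substrate = parse_smiles("CC(=O)CC(=O)O")
beta_keto = TargetDefinition("CC(=O)C", (1, 2), "beta-keto bond")
targets = find_targets(beta_keto, substrate)
print("targets:", len(targets))
product = ketoreduce(substrate, targets[0])
print("product:", write_smiles(product))
print(f"tanimoto(substrate, product) = {tanimoto(ecfp(substrate), ecfp(product)):.3f}")
drawing = draw_molecule(product)
print("clashes:", len(detect_clashes(drawing)))
render(drawing, "product.svg")
```

prints

```
targets: 1
product: CC(O)CC(=O)O
tanimoto(substrate, product) = 0.364
clashes: 0
```

One β-keto bond was found; reduction turned the ketone into a hydroxyl
(`CC(O)CC(=O)O`), the fingerprints of substrate and product now share only
about a third of their substructure identifiers, and the drawing of the
product is clash-free. The new hydroxyl group carries a `reduced`
annotation so it can be highlighted in the rendered image.

The same functionality is available from the shell:

```bash
molkit react ketoreduction 'CC(=O)CC(=O)O'
molkit draw 'CC(=O)Oc1ccccc1C(=O)O' -o aspirin.svg
molkit similarity 'CCO' 'CCN'
molkit search 'C(=O)NC' 'CC(=O)NC' --highlight match.svg
```

## Documentation

`docs/methods.md` describes the underlying models and algorithms, the
numerical choices, what the synthetic SMILES generator does and does not
emulate, and known limitations.
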