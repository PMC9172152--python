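import pytest

from molkit.fixtures import FixtureSpec, generate_test_smiles

# A curated corpus covering rings, fused aromatics, charges, tetrahedral
# stereocentres and double-bond stereochemistry across SMILES syntaxes.
CURATED_SMILES = [
    "C", "CC", "CCO", "CC(C)C", "CC(C)(C)C", "C=C", "C#N", "CC#CC",
    "c1ccccc1", "C1=CC=CC=C1", "c1ccncc1", "c1cc[nH]c1", "c1ccoc1",
    "c1ccsc1", "c1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",
    "C1CCCCC1", "C1CCC1", "C1CC1", "C1CCOC1", "C1CC2CCC1CC2",
    "CC(=O)O", "CC(=O)NC", "CC(=O)OC", "CC(=O)Oc1ccccc1C(=O)O",
    "C[N+](=O)[O-]", "CN(=O)=O", "[NH4+].[Cl-]", "CC(=O)[O-]",
    "C[N+](C)(C)C", "OS(=O)(=O)O", "CP(=O)(O)O",
    "N[C@@H](C)C(=O)O", "N[C@H](C)C(=O)O", "C[C@@H](O)[C@H](N)C(=O)O",
    "C[C@H]1CC[C@@H](N)CC1", "CN1CC[C@H](c2ccccc2)C1",
    "F/C=C/F", "F/C=C\\F", "C/C=C(\\N)/C", "C/C=C/C=C/C",
    "CC1=CC(=O)CC(C)(C)C1", "O=C(O)c1ccccc1O", "O=C1CCCCC1",
    "ClC(Cl)(Cl)Cl", "FC(F)(F)c1ccccc1", "CSC", "CCS", "OCC(O)CO",
    "c1ccc2[nH]ccc2c1",
]


@pytest.fixture(scope="session")
def curated_smiles():
    return CURATED_SMILES


@pytest.fixture(scope="session")
def fixture_smiles():
    """A seeded batch exercising every generator feature."""
    return generate_test_smiles(FixtureSpec(seed=11, count=100, min_size=3,
                                            max_size=18))


@pytest.fixture(scope="session")
def parsed_corpus(curated_smiles, fixture_smiles):
    from molkit import parse_smiles

    return {smi: parse_smiles(smi) for smi in curated_smiles + fixture_smiles}
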