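import random

import networkx as nx
import pytest

from molkit import (StructureError, build_structure, detect_aromaticity,
                    enumerate_simple_cycles, find_sssr, kekulise,
                    parse_smiles)
from molkit.rings import (CycleOverflowError, cyclomatic_number,
                          ensure_ring_data, maximum_matching)


def _graph_structure(edges, n=None):
    n = n or (max(max(e) for e in edges) + 1 if edges else 1)
    return build_structure([("C", i) for i in range(n)], edges)


class TestSimpleCycles:
    def test_acyclic_chain_has_no_cycles(self):
        s = _graph_structure([(0, 1), (1, 2), (2, 3)])
        assert enumerate_simple_cycles(s) == []

    def test_benzene_has_one_cycle(self):
        assert len(enumerate_simple_cycles(parse_smiles("c1ccccc1"))) == 1

    def test_two_fused_triangles_give_three_cycles(self):
        s = _graph_structure([(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)])
        cycles = enumerate_simple_cycles(s)
        assert sorted(len(c) for c in cycles) == [3, 3, 4]

    def test_matches_networkx_on_random_graphs(self):
        rng = random.Random(4)
        for _ in range(40):
            n = rng.randint(4, 12)
            m = rng.randint(n - 1, min(n + 4, n * (n - 1) // 2))
            graph = nx.gnm_random_graph(n, m, seed=rng.randint(0, 10 ** 6))
            edges = list(graph.edges)
            s = _graph_structure(edges, n=n)
            ours = {frozenset(c) for c in enumerate_simple_cycles(s)
                    if len(c) >= 3}
            theirs = {frozenset(c) for c in nx.simple_cycles(graph)
                      if len(c) >= 3}
            assert ours == theirs

    def test_cycle_ceiling_guard(self):
        # complete graph K9 has > 100 simple cycles
        edges = [(i, j) for i in range(9) for j in range(i + 1, 9)]
        s = _graph_structure(edges, n=9)
        with pytest.raises(CycleOverflowError):
            enumerate_simple_cycles(s, ceiling=100)


class TestSSSR:
    def test_benzene(self):
        s = parse_smiles("c1ccccc1")
        assert [len(r) for r in find_sssr(s)] == [6]

    def test_naphthalene_prefers_the_two_hexagons(self):
        s = parse_smiles("c1ccc2ccccc2c1")
        assert sorted(len(r) for r in find_sssr(s)) == [6, 6]

    def test_cubane_has_five_four_rings(self):
        s = parse_smiles("C12C3C4C1C5C4C3C25")
        rings = find_sssr(s)
        assert sorted(len(r) for r in rings) == [4] * 5

    def test_size_equals_cyclomatic_number_on_random_graphs(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(4, 14)
            m = rng.randint(n - 1, min(n + 5, n * (n - 1) // 2))
            graph = nx.gnm_random_graph(n, m, seed=rng.randint(0, 10 ** 6))
            edges = list(graph.edges)
            s = _graph_structure(edges, n=n)
            sssr = find_sssr(s)
            assert len(sssr) == cyclomatic_number(s)
            # minimum basis: total ring size matches networkx's minimum
            # cycle basis (computed per component)
            ours = sorted(len(r) for r in sssr)
            theirs = sorted(len(c) for c in nx.minimum_cycle_basis(graph))
            assert ours == theirs


class TestAromaticity:
    def test_benzene_aromatic(self):
        s = parse_smiles("C1=CC=CC=C1")
        assert all(a.aromatic for a in s.heavy_atoms())

    def test_cyclobutadiene_not_aromatic(self):
        s = parse_smiles("C1=CC=C1")
        assert not any(a.aromatic for a in s.heavy_atoms())

    def test_cyclohexane_not_aromatic(self):
        s = parse_smiles("C1CCCCC1")
        assert not any(a.aromatic for a in s.heavy_atoms())

    def test_pyrrole_aromatic_through_lone_pair_promotion(self):
        s = parse_smiles("N1C=CC=C1")
        nitrogen = next(a for a in s.atoms.values() if a.element == "N")
        assert nitrogen.aromatic
        assert nitrogen.aromatic_lone_pair == 1
        assert nitrogen.hybridisation == "sp2"
        assert s.aromatic_systems[0].pi_electrons == 6

    def test_exocyclic_double_bond_contributes_nothing(self):
        s = parse_smiles("O=C1C=CC=C1")  # cyclopentadienone: 4n electrons
        ring_atoms = [a for a in s.heavy_atoms() if a.element == "C"]
        assert not any(a.aromatic for a in ring_atoms)

    def test_detection_is_idempotent(self):
        s = parse_smiles("c1ccc2ccccc2c1")
        flags = [(a.index, a.aromatic, a.aromatic_pi)
                 for a in s.heavy_atoms()]
        detect_aromaticity(s)
        assert flags == [(a.index, a.aromatic, a.aromatic_pi)
                         for a in s.heavy_atoms()]

    def test_fused_system_needs_recursion(self):
        # kekule naphthalene where one ring only reaches an odd count after
        # the shared bond has turned aromatic in a previous round
        s = parse_smiles("C1=CC2=CC=CC=C2C=C1")
        assert all(a.aromatic for a in s.heavy_atoms())
        assert len(s.aromatic_systems) == 1
        assert s.aromatic_systems[0].pi_electrons == 10

    def test_aromatic_input_failing_hueckel_is_rejected(self):
        with pytest.raises(StructureError):
            parse_smiles("c1ccc1")

    def test_biphenyl_link_bond_is_single(self):
        s = parse_smiles("c1ccc(cc1)c1ccccc1")
        link = [b for b in s.bonds.values()
                if b.type == "single"
                and s.atom(b.atom1).aromatic and s.atom(b.atom2).aromatic
                and s.atom(b.atom1).is_heavy() and s.atom(b.atom2).is_heavy()]
        assert len(link) == 1
        assert len(s.aromatic_systems) == 2


class TestMaximumMatching:
    def test_matches_networkx_cardinality_on_random_graphs(self):
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randint(2, 14)
            m = rng.randint(0, n * (n - 1) // 2)
            graph = nx.gnm_random_graph(n, m, seed=rng.randint(0, 10 ** 6))
            adjacency = [list(graph.neighbors(v)) for v in range(n)]
            match = maximum_matching(n, adjacency)
            ours = sum(1 for v in range(n) if match[v] != -1) // 2
            theirs = len(nx.max_weight_matching(graph,
                                                maxcardinality=True))
            assert ours == theirs
            for v in range(n):  # it is a matching
                if match[v] != -1:
                    assert match[match[v]] == v


class TestKekulise:
    def _doubles(self, structure):
        return [b for b in structure.bonds.values() if b.type == "double"]

    def test_benzene_three_alternating_doubles(self):
        k = kekulise(parse_smiles("c1ccccc1"))
        doubles = self._doubles(k)
        assert len(doubles) == 3
        covered = [a for b in doubles for a in b.atoms()]
        assert len(covered) == len(set(covered)) == 6

    def test_naphthalene_five_doubles(self):
        k = kekulise(parse_smiles("c1ccc2ccccc2c1"))
        doubles = self._doubles(k)
        assert len(doubles) == 5
        covered = {a for b in doubles for a in b.atoms()}
        assert len(covered) == 10

    def test_pyrrole_nitrogen_stays_unmatched(self):
        k = kekulise(parse_smiles("c1cc[nH]c1"))
        doubles = self._doubles(k)
        assert len(doubles) == 2
        nitrogen = next(a for a in k.atoms.values() if a.element == "N")
        assert all(nitrogen.index not in b.atoms() for b in doubles)

    def test_matching_is_valid_on_all_aromatic_fixtures(self, parsed_corpus):
        for smiles, structure in parsed_corpus.items():
            if not structure.aromatic_systems:
                continue
            pi_atoms = {
                a.index for a in structure.heavy_atoms() if a.aromatic_pi}
            k = kekulise(structure)
            covered = set()
            for bond in self._doubles(k):
                if bond.aromatic:  # belonged to an aromatic system
                    for idx in bond.atoms():
                        assert idx not in covered, smiles
                        covered.add(idx)
            assert pi_atoms <= covered, smiles

    def test_kekulised_structure_passes_validation(self, parsed_corpus):
        for structure in parsed_corpus.values():
            if structure.aromatic_systems:
                kekulise(structure).refresh(perceive_aromaticity=False)


class TestRingData:
    def test_fixed_point_within_sssr_rounds(self, parsed_corpus):
        # perception must stabilise; rerunning changes nothing
        for structure in parsed_corpus.values():
            before = [(b.index, b.type) for b in structure.bonds.values()]
            detect_aromaticity(structure)
            after = [(b.index, b.type) for b in structure.bonds.values()]
            assert before == after

    def test_no_short_cycles_are_retained(self, parsed_corpus):
        for structure in parsed_corpus.values():
            data = ensure_ring_data(structure)
            assert all(len(c) >= 3 for c in data.simple_cycles)
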