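"""Interior/exterior decomposition, fringe trees, k-leanness."""

import math

import numpy as np
import pytest

from invqsar.chemgraph import make_chem_graph
from invqsar.twolayer import (
    EmptyInteriorError,
    decompose,
    fringe_trees,
    height_map,
    is_k_lean,
)


def brute_force_strip(G):
    """Independent re-implementation of iterated leaf removal."""
    alive = set(range(G.n))
    ht = {}
    k = 0
    while True:
        leaves = {
            v for v in alive
            if sum(1 for u in G.neighbors(v) if u in alive) == 1
        }
        if not leaves:
            break
        for v in leaves:
            ht[v] = k
        alive -= leaves
        k += 1
    for v in alive:
        ht[v] = math.inf
    return ht


def path_graph(n):
    return make_chem_graph(n, [(i, i + 1) for i in range(n - 1)], ["C"] * n, [1] * (n - 1))


class TestHeightMap:
    def test_five_path(self):
        ht = height_map(path_graph(5))
        assert [ht[v] for v in range(5)] == [0, 1, math.inf, 1, 0]

    def test_cycle_all_sentinel(self):
        C = make_chem_graph(6, [(i, (i + 1) % 6) for i in range(6)], ["C"] * 6, [1] * 6)
        assert all(h == math.inf for h in height_map(C).values())

    def test_reference_molecule_stripping_rounds(self, ref_molecule):
        """14 degree-1 atoms stripped in round 0, then 5 in round 1."""
        G, _, _ = ref_molecule
        ht = height_map(G)
        assert sum(1 for h in ht.values() if h == 0) == 14
        assert sum(1 for h in ht.values() if h == 1) == 5

    def test_matches_brute_force(self, random_graphs):
        for G in random_graphs[:40]:
            assert height_map(G) == brute_force_strip(G)


class TestDecompose:
    def test_reference_molecule_counts(self, ref_molecule):
        G, _, _ = ref_molecule
        dec = decompose(G, 2)
        assert len(dec.exterior_vertices) == 19
        assert len(dec.interior_vertices) == 28
        assert sum(1 for t in dec.fringe_trees if not t.is_trivial) == 8

    def test_rho_zero_everything_interior(self, random_graphs):
        for G in random_graphs[:10]:
            dec = decompose(G, 0)
            assert not dec.exterior_vertices
            assert all(t.is_trivial for t in dec.fringe_trees)

    def test_empty_interior_is_an_error(self):
        # an even path strips away entirely, leaving no interior vertex
        with pytest.raises(EmptyInteriorError) as exc:
            decompose(path_graph(4), 5)
        assert exc.value.graph.n == 4

    @pytest.mark.parametrize("rho", [1, 2, 3])
    def test_partition_against_oracle(self, random_graphs, rho):
        for G in random_graphs[:40]:
            ht = brute_force_strip(G)
            expected_ext = {v for v in range(G.n) if ht[v] < rho}
            if len(expected_ext) == G.n:
                with pytest.raises(EmptyInteriorError):
                    decompose(G, rho)
                continue
            dec = decompose(G, rho)
            assert set(dec.exterior_vertices) == expected_ext
            assert set(dec.interior_vertices) == set(range(G.n)) - expected_ext
            exp_ee = {e for e in G.edges if e[0] in expected_ext or e[1] in expected_ext}
            assert set(dec.exterior_edges) == exp_ee
            assert set(dec.interior_edges) == set(G.edges) - exp_ee

    def test_core_is_always_interior(self, random_graphs):
        from invqsar.chemgraph import core_edges, core_vertices

        for G in random_graphs[:20]:
            try:
                dec = decompose(G, 2)
            except EmptyInteriorError:
                continue
            assert core_vertices(G) <= set(dec.interior_vertices)
            assert core_edges(G) <= set(dec.interior_edges)

    def test_partition_sizes_and_monotonicity(self, random_graphs):
        for G in random_graphs[:20]:
            prev = None
            for rho in (0, 1, 2, 3):
                try:
                    dec = decompose(G, rho)
                except EmptyInteriorError:
                    break
                assert len(dec.interior_vertices) + len(dec.exterior_vertices) == G.n
                assert len(dec.interior_edges) + len(dec.exterior_edges) == len(G.edges)
                if prev is not None:
                    assert set(dec.interior_vertices) <= prev
                prev = set(dec.interior_vertices)


class TestFringeTrees:
    def test_cycle_only_trivial_trees(self):
        C = make_chem_graph(5, [(i, (i + 1) % 5) for i in range(5)], ["C"] * 5, [1] * 5)
        trees = fringe_trees(decompose(C, 2))
        assert len(trees) == 5 and all(t.is_trivial for t in trees)

    def test_one_tree_per_interior_vertex_and_coverage(self, random_graphs):
        for G in random_graphs[:30]:
            try:
                dec = decompose(G, 2)
            except EmptyInteriorError:
                continue
            trees = dec.fringe_trees
            assert sorted(t.root for t in trees) == sorted(dec.interior_vertices)
            non_roots = {v for t in trees for v in t.vertices if v != t.root}
            assert non_roots == set(dec.exterior_vertices)
            assert all(t.height <= 2 for t in trees)

    def test_reconstruction(self, random_graphs):
        """Interior edges plus all fringe-tree edges reproduce the graph."""
        for G in random_graphs[:30]:
            try:
                dec = decompose(G, 2)
            except EmptyInteriorError:
                continue
            rebuilt = set(dec.interior_edges)
            for t in dec.fringe_trees:
                rebuilt |= set(t.edges)
            assert rebuilt == set(G.edges)


class TestKLean:
    def test_paths_always_lean(self):
        for n in (2, 5, 9):
            for k in range(4):
                assert is_k_lean(path_graph(n), k)

    def test_three_legged_spider_not_2_lean(self):
        # center with three legs of length 3: three vertices of height 2
        edges = []
        n = 1
        for _ in range(3):
            prev = 0
            for _ in range(3):
                edges.append((prev, n))
                prev = n
                n += 1
        G = make_chem_graph(n, edges, ["C"] * n, [1] * len(edges))
        assert not is_k_lean(G, 2, root=0)
        assert is_k_lean(G, 3, root=0)
        assert not is_k_lean(G, 2)  # default end-rooting: two height-2 mids

    def test_cyclic_pendant_trees(self):
        # triangle with one pendant path: single leaf branch at every height
        edges = [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5)]
        G = make_chem_graph(6, edges, ["C"] * 6, [1] * 6)
        for k in range(4):
            assert is_k_lean(G, k)
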