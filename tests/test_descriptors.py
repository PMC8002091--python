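"""Canonical rooted-tree codes, configurations, descriptor spaces, and the
feature vector with its conservation identities."""

import itertools

import numpy as np
import pytest

from invqsar.chemgraph import DEFAULT_TABLE, Dataset, make_chem_graph
from invqsar.descriptors import (
    DescriptorSpace,
    FeatureError,
    RootedTree,
    adjacency_config,
    build_descriptor_space,
    canonical_code,
    chemical_symbol,
    edge_config,
    feature_vector,
    feature_vector_length,
)
from invqsar.twolayer import EmptyInteriorError, decompose


# ---------------------------------------------------------------------------
# independent oracle: root-preserving isomorphism by backtracking
# ---------------------------------------------------------------------------


def r_isomorphic(t1: RootedTree, t2: RootedTree) -> bool:
    if (t1.element, t1.bond, len(t1.children)) != (t2.element, t2.bond, len(t2.children)):
        return False
    if not t1.children:
        return True
    for perm in itertools.permutations(range(len(t2.children))):
        if all(
            r_isomorphic(c1, t2.children[p])
            for c1, p in zip(t1.children, perm)
        ):
            return True
    return False


def random_tree(rng, n, elements=("C", "O", "N"), bonds=(1, 2)) -> RootedTree:
    nodes = [RootedTree(elements[rng.integers(len(elements))], None)]
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        nodes.append(
            RootedTree(
                elements[rng.integers(len(elements))],
                int(bonds[rng.integers(len(bonds))]),
            )
        )
        nodes[parent] = nodes[parent]  # placeholder; assembled below
    # assemble via parent array
    parents = [None] + [int(rng.integers(0, i)) for i in range(1, n)]
    children = {i: [] for i in range(n)}
    for i in range(1, n):
        children[parents[i]].append(i)

    def build(i):
        return RootedTree(nodes[i].element, nodes[i].bond, tuple(build(j) for j in children[i]))

    return build(0)


def shuffled(t: RootedTree, rng) -> RootedTree:
    kids = list(t.children)
    rng.shuffle(kids)
    return RootedTree(t.element, t.bond, tuple(shuffled(k, rng) for k in kids))


class TestCanonicalCode:
    def test_single_root(self):
        assert RootedTree("C", None).code() == "(C)"

    def test_child_order_irrelevant(self):
        a = RootedTree("C", None, (RootedTree("O", 1), RootedTree("O", 1)))
        b = RootedTree("C", None, tuple(reversed(a.children)))
        assert canonical_code(a) == canonical_code(b)

    def test_code_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t = random_tree(rng, int(rng.integers(1, 9)))
            code = canonical_code(t)
            assert RootedTree.from_code(code).canonical().code() == code

    def test_shuffle_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = random_tree(rng, int(rng.integers(1, 11)))
            assert canonical_code(t) == canonical_code(shuffled(t, rng))

    def test_agrees_with_exhaustive_isomorphism_oracle(self):
        rng = np.random.default_rng(2)
        same = diff = 0
        for _ in range(300):
            n = int(rng.integers(1, 7))
            t1, t2 = random_tree(rng, n), random_tree(rng, n)
            iso = r_isomorphic(t1, t2)
            codes_equal = canonical_code(t1) == canonical_code(t2)
            assert iso == codes_equal
            same += iso
            diff += not iso
        assert same > 10 and diff > 10  # both outcomes exercised


from hypothesis import given, settings
from hypothesis import strategies as st

tree_strategy = st.recursive(
    st.builds(RootedTree, st.sampled_from(["C", "O", "N"]), st.none()),
    lambda kids: st.builds(
        lambda e, ks: RootedTree(
            e, None, tuple(RootedTree(k.element, m, k.children) for k, m in ks)
        ),
        st.sampled_from(["C", "O", "N"]),
        st.lists(st.tuples(kids, st.sampled_from([1, 2])), min_size=1, max_size=3),
    ),
    max_leaves=8,
)


class TestCanonicalCodeProperties:
    """Derandomised property tests over generated chemical rooted trees."""

    @given(tree_strategy)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_code_is_reordering_invariant_and_parseable(self, t):
        rng = np.random.default_rng(0)
        code = canonical_code(t)
        assert canonical_code(shuffled(t, rng)) == code
        assert RootedTree.from_code(code).canonical().code() == code

    @given(tree_strategy, tree_strategy)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_code_equality_iff_isomorphic(self, t1, t2):
        if t1.size <= 6 and t2.size <= 6:
            assert (canonical_code(t1) == canonical_code(t2)) == r_isomorphic(t1, t2)


class TestConfigs:
    def test_chemical_symbol(self):
        G = make_chem_graph(4, [(0, 1), (0, 2), (0, 3)], ["C", "C", "O", "N"], [1, 1, 1])
        assert chemical_symbol(G, 0) == ("C", 3)
        assert chemical_symbol(G, 2) == ("O", 1)

    def test_adjacency_config_orientation(self):
        G = make_chem_graph(2, [(0, 1)], ["O", "C"], [1])
        assert adjacency_config(G, (0, 1)) == ("C", "O", 1)
        H = make_chem_graph(2, [(0, 1)], ["C", "C"], [2])
        assert adjacency_config(H, (0, 1)) == ("C", "C", 2)

    def test_adjacency_orientation_stable_under_relabel(self, random_graphs):
        rng = np.random.default_rng(3)
        for G in random_graphs[:10]:
            perm = list(rng.permutation(G.n))
            G2 = G.relabel(perm)
            acs = sorted(adjacency_config(G, e) for e in G.edges)
            acs2 = sorted(adjacency_config(G2, e) for e in G2.edges)
            assert acs == acs2

    def test_edge_config_orientation_and_domain(self):
        # path C-C-C-C-C with rho=1: middle edge interior
        G = make_chem_graph(5, [(i, i + 1) for i in range(4)], ["C"] * 5, [1, 2, 1, 1])
        dec = decompose(G, 1)
        assert (1, 2) in dec.interior_edges
        assert edge_config(G, (1, 2), dec) == (("C", 2), ("C", 2), 2)
        with pytest.raises(Exception):
            edge_config(G, (0, 1), dec)  # exterior edge

    def test_edge_config_frequencies_sum_to_interior_edges(self, random_graphs):
        for G in random_graphs[:20]:
            try:
                dec = decompose(G, 2)
            except EmptyInteriorError:
                continue
            freqs = {}
            for e in dec.interior_edges:
                g = edge_config(G, e, dec)
                freqs[g] = freqs.get(g, 0) + 1
            assert sum(freqs.values()) == len(dec.interior_edges)


class TestDescriptorSpace:
    def test_k_formula(self):
        assert feature_vector_length(3, 3, 24, 109) == 156
        space = DescriptorSpace(("C",), (), ((("C", 2), ("C", 2), 1),), ("(C)",), 1, DEFAULT_TABLE)
        assert space.K == 17 + 1 + 0 + 1 + 1

    def test_triangle_dataset(self):
        tri = make_chem_graph(3, [(0, 1), (1, 2), (0, 2)], ["C"] * 3, [1] * 3)
        space = build_descriptor_space(Dataset([tri], [0.0]), 2)
        assert space.lambda_int == ("C",)
        assert space.lambda_ex == ()  # no exterior vertex anywhere
        assert space.gamma_int == ((("C", 2), ("C", 2), 1),)
        assert space.fringe_codes == ("(C)",)
        assert space.K == 17 + 1 + 0 + 1 + 1

    def test_k_recomputed_from_cardinalities(self, random_graphs):
        ds = Dataset(random_graphs[:30], [0.0] * 30)
        space = build_descriptor_space(ds, 2)
        assert space.K == feature_vector_length(
            len(space.lambda_int),
            len(space.lambda_ex),
            len(space.gamma_int),
            len(space.fringe_codes),
        )

    def test_serialization_roundtrip(self, toy_space):
        d = toy_space.to_dict()
        back = DescriptorSpace.from_dict(d)
        assert back.to_dict() == d
        assert back.K == toy_space.K


class TestFeatureVector:
    def test_basic_slots(self, ref_molecule):
        G, _, _ = ref_molecule
        space = build_descriptor_space(Dataset([G], [0.0]), 2)
        x = feature_vector(G, space)
        assert x[0] == G.n
        assert x[1] == 28

    def test_all_carbon_mass(self):
        G = make_chem_graph(4, [(0, 1), (1, 2), (2, 3)], ["C"] * 4, [1] * 3)
        space = build_descriptor_space(Dataset([G], [0.0]), 1)
        x = feature_vector(G, space)
        assert x[2] == pytest.approx(120.0)  # floor(10 * 12.011)

    def test_conservation_identities(self, random_graphs):
        for G in random_graphs[:60]:
            space = build_descriptor_space(Dataset([G], [0.0]), 2)
            x = feature_vector(G, space)
            dec = decompose(G, 2)
            n_int = len(dec.interior_vertices)
            o = space
            assert x[1] == n_int
            assert x[3:7].sum() == n_int  # degree histogram
            # interior-degree histogram covers 1..4; a single-vertex
            # interior has interior-degree 0 and contributes nothing
            assert x[7:11].sum() == (n_int if n_int > 1 else 0)
            assert x[11:15].sum() == G.n  # hydrogen-degree histogram
            assert x[o.na_int_offset:o.na_ex_offset].sum() == n_int
            assert x[o.na_ex_offset:o.ec_offset].sum() == G.n - n_int
            assert x[o.ec_offset:o.fc_offset].sum() == len(dec.interior_edges)
            assert x[o.fc_offset:].sum() == n_int

    def test_ms_avg_bounds(self, random_graphs):
        for G in random_graphs[:30]:
            space = build_descriptor_space(Dataset([G], [0.0]), 2)
            x = feature_vector(G, space)
            masses = [G.table.mass10(a) for a in set(G.alpha)]
            assert min(masses) <= x[2] <= max(masses)

    def test_isomorphism_invariance(self, random_graphs):
        rng = np.random.default_rng(7)
        for G in random_graphs[:15]:
            space = build_descriptor_space(Dataset([G], [0.0]), 2)
            x = feature_vector(G, space)
            G2 = G.relabel(list(rng.permutation(G.n)))
            assert np.allclose(feature_vector(G2, space), x)

    def test_out_of_space_symbol_error(self, toy_space):
        G = make_chem_graph(5, [(i, i + 1) for i in range(4)], ["C", "C", "S", "C", "C"], [1] * 4)
        with pytest.raises(FeatureError) as exc:
            feature_vector(G, toy_space)
        assert any("S" in m for m in exc.value.missing)
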