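"""Target specifications: schema, serialization, subdivision matching,
extension validation and random/exhaustive generation."""

import json

import networkx as nx
import numpy as np
import pytest

from invqsar.chemgraph import ChemGraph
from invqsar.specification import (
    ChemSpec,
    EdgeBounds,
    InteriorSpec,
    SeedEdge,
    SeedGraph,
    SideConstraint,
    SpecError,
    TargetSpec,
    VertexBounds,
    is_subdivision,
    iter_extensions,
    load_spec,
    random_extension,
    save_spec,
    validate_extension,
)


def simple_spec(**over):
    seed = SeedGraph(2, [SeedEdge("a1", 0, 1, "ge2"), SeedEdge("a2", 0, 1, "ge1")])
    si = InteriorSpec(3, 5, {"a1": EdgeBounds(l_ub=3), "a2": EdgeBounds(l_ub=2)})
    codes = ("(C)", "(N)", "(C(O~1))")
    sce = ChemSpec(
        over.pop("n_lb", 3), over.pop("n_star", 8),
        {0: codes, 1: codes}, codes, ("C", "N", "O"),
    )
    return TargetSpec(seed, si, sce, rho=1)


class TestSchemaAndSerialization:
    def test_bad_length_bounds(self):
        seed = SeedGraph(2, [SeedEdge("a1", 0, 1, "ge1")])
        si = InteriorSpec(2, 4, {"a1": EdgeBounds(l_lb=3, l_ub=2)})
        sce = ChemSpec(2, 6, {}, ("(C)",), ("C",))
        with pytest.raises(SpecError, match="a1"):
            TargetSpec(seed, si, sce, rho=1)

    def test_unknown_edge_class(self):
        with pytest.raises(SpecError):
            SeedEdge("a1", 0, 1, "maybe")

    def test_fringe_taller_than_rho(self):
        seed = SeedGraph(1, [])
        si = InteriorSpec(1, 1)
        sce = ChemSpec(1, 4, {}, ("(C(C~1(C~1)))",), ("C",))
        with pytest.raises(SpecError, match="taller"):
            TargetSpec(seed, si, sce, rho=1)

    def test_low_valence_element_in_lambda_star(self):
        seed = SeedGraph(1, [])
        si = InteriorSpec(1, 1)
        sce = ChemSpec(1, 4, {}, ("(C)",), ("C", "Cl"), lambda_star={0: ("Cl",)})
        with pytest.raises(SpecError, match="valence"):
            TargetSpec(seed, si, sce, rho=1)

    def test_roundtrip_byte_identical(self, tmp_path, toy_spec):
        p1, p2 = tmp_path / "s1.json", tmp_path / "s2.json"
        save_spec(toy_spec, p1)
        save_spec(load_spec(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_roundtrip_many_random_specs(self, tmp_path):
        rng = np.random.default_rng(4)
        classes = ["ge2", "ge1", "zero_one", "eq1"]
        for i in range(25):
            nv = int(rng.integers(2, 5))
            edges = []
            for j in range(int(rng.integers(1, 5))):
                u, v = sorted(rng.choice(nv, 2, replace=False))
                edges.append(SeedEdge(f"a{j}", int(u), int(v), classes[rng.integers(4)]))
            si = InteriorSpec(
                1, int(rng.integers(4, 10)),
                {e.id: EdgeBounds(l_ub=int(rng.integers(1, 4) + 1)) for e in edges if e.cls in ("ge1", "ge2")},
                vertex_bounds={0: VertexBounds(bl_ub=1, ch_ub=int(rng.integers(1, 3)))},
                side_constraints=[SideConstraint({edges[0].id: 1}, "<=", 5)],
            )
            sce = ChemSpec(
                2, 12, {0: ("(C)",)}, ("(C)", "(N)"), ("C", "N"),
                na_ub={"N": int(rng.integers(1, 5))},
            )
            try:
                spec = TargetSpec(SeedGraph(nv, edges), si, sce, rho=1)
            except SpecError:
                continue
            p1, p2 = tmp_path / f"r{i}.json", tmp_path / f"r{i}b.json"
            save_spec(spec, p1)
            save_spec(load_spec(p1), p2)
            assert p1.read_bytes() == p2.read_bytes()

    def test_default_bounds_are_free(self, toy_spec, tmp_path):
        """Unspecified bounds round-trip as the documented defaults:
        lower bounds 0, count upper bounds n*."""
        p = tmp_path / "s.json"
        save_spec(toy_spec, p)
        d = json.loads(p.read_text())
        assert d["chemical_spec"]["na_lb"] == {}  # absent = all-zero lower bounds
        eb = toy_spec.interior.eb("unconstrained-edge")
        assert eb.l_lb == 0 and eb.bl_ub == 0 and eb.bd2_ub is None


class TestSubdivision:
    def test_degenerate_paths_accepted(self):
        seed = SeedGraph(
            3,
            [
                SeedEdge("a1", 0, 1, "ge1"),
                SeedEdge("a2", 1, 2, "zero_one"),
                SeedEdge("a3", 0, 2, "eq1"),
            ],
        )
        S = nx.Graph([(10, 11), (11, 12), (10, 12)])
        m = is_subdivision(S, seed, {0: 10, 1: 11, 2: 12})
        assert m is not None
        assert m["a1"] == [10, 11] and m["a3"] == [10, 12]

    def test_ge2_edge_left_unreplaced_fails(self):
        seed = SeedGraph(2, [SeedEdge("a1", 0, 1, "ge2")])
        S = nx.Graph([(5, 6)])
        assert is_subdivision(S, seed, {0: 5, 1: 6}) is None

    def test_expanded_paths_found(self):
        seed = SeedGraph(2, [SeedEdge("a1", 0, 1, "ge2"), SeedEdge("a2", 0, 1, "ge1")])
        # cycle 0-7-8-1-9-0: a1 as length-3 path, a2 as length-2 path
        S = nx.Graph([(0, 7), (7, 8), (8, 1), (1, 9), (9, 0)])
        m = is_subdivision(S, seed, {0: 0, 1: 1})
        assert m is not None
        lens = sorted(len(m[e]) - 1 for e in ("a1", "a2"))
        assert lens == [2, 3]


class TestValidateExtension:
    def test_reference_molecule_is_extension(self, ref_molecule):
        G, spec, _ = ref_molecule
        assert validate_extension(G, spec).is_extension

    def test_size_cap_violation_flagged(self, ref_molecule):
        G, spec, _ = ref_molecule
        import dataclasses

        small = dataclasses.replace(spec.chemical, n_star=G.n - 1)
        spec2 = TargetSpec(spec.seed, spec.interior, small, spec.rho, spec.table)
        rep = validate_extension(G, spec2)
        assert not rep.is_extension
        assert any(r[0] == "n" for r in rep.violations)

    def test_every_enumerated_graph_validates(self, toy_spec, toy_extensions):
        for G, _ in toy_extensions[::61]:
            assert validate_extension(G, toy_spec).is_extension

    def test_foreign_graph_rejected(self, toy_spec):
        # a tree cannot subdivide the two-path cyclic seed
        G = ChemGraph(4, [(0, 1), (1, 2), (1, 3)], ["C"] * 4, [1] * 3)
        rep = validate_extension(G, toy_spec)
        assert not rep.is_extension
        assert rep.violations[0][0] == "subdivision"

    def test_invariant_under_relabeling(self, toy_spec, toy_extensions):
        rng = np.random.default_rng(9)
        for G, _ in toy_extensions[::997]:
            perm = list(rng.permutation(G.n))
            assert validate_extension(G.relabel(perm), toy_spec).is_extension


class TestRandomExtension:
    def test_samples_validate(self, toy_spec):
        ok = 0
        for s in range(8):
            G = random_extension(toy_spec, rng_seed=s)
            if G is not None:
                assert validate_extension(G, toy_spec).is_extension
                ok += 1
        assert ok >= 6

    def test_unique_extension_found(self):
        # spec pinning everything: triangle of carbons, single bonds
        seed = SeedGraph(
            3,
            [SeedEdge("a1", 0, 1, "eq1"), SeedEdge("a2", 1, 2, "eq1"), SeedEdge("a3", 0, 2, "eq1")],
        )
        si = InteriorSpec(3, 3, edge_bounds={e: EdgeBounds(bd2_ub=0, bd3_ub=0) for e in ("a1", "a2", "a3")})
        code = "(C(C~1(C~1)))"
        sce = ChemSpec(9, 9, {i: (code,) for i in range(3)}, (code,), ("C",))
        spec = TargetSpec(seed, si, sce, rho=2)
        exts = list(iter_extensions(spec))
        assert len(exts) == 1
        G = random_extension(spec, rng_seed=0)
        assert G is not None and G.n == 9

    def test_infeasible_spec_returns_none(self):
        seed = SeedGraph(2, [SeedEdge("a1", 0, 1, "eq1")])
        si = InteriorSpec(2, 2)
        sce = ChemSpec(
            2, 4, {0: ("(C)",), 1: ("(C)",)}, ("(C)",), ("C",),
            ec_int_lb={((("C", 1)), (("C", 1)), 3): 2},  # 2 interior edges impossible
        )
        sce.ec_int_lb = {(("C", 1), ("C", 1), 3): 2}
        spec = TargetSpec(seed, si, sce, rho=0)
        assert random_extension(spec, rng_seed=0, attempts=200) is None
        assert list(iter_extensions(spec)) == []


class TestEnumerationSoundness:
    def test_mutation_breaks_exactly_one_rule(self, toy_spec, toy_extensions):
        """Raising a bond multiplicity past a bound is caught as ec/valence."""
        G, _ = toy_extensions[40]
        # flip one edge's multiplicity; either invalid chemistry or a
        # different (still valid or invalid) extension -- never silently both
        edges = list(G.edges)
        beta = [G.beta[e] for e in edges]
        beta[0] = 3
        try:
            G2 = ChemGraph(G.n, edges, list(G.alpha), beta, G.table)
        except Exception:
            return  # valence violation caught upstream
        rep = validate_extension(G2, toy_spec)
        # if it still validates it must genuinely be another extension
        if rep.is_extension:
            from invqsar._canon import is_isomorphic

            assert any(is_isomorphic(G2, h) for h, _ in toy_extensions)

    def test_enumeration_matches_validator(self, toy_spec, toy_extensions):
        """Brute-force construction and the validator agree on membership."""
        from invqsar._canon import dedup_graphs, graph_invariant, is_isomorphic

        reps = dedup_graphs([g for g, _ in toy_extensions[::17]])
        for G in reps[:25]:
            assert validate_extension(G, toy_spec).is_extension
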