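"""Shared fixtures: toy specifications, spaces, and a hand-built reference
reconstruction of a 47-atom multi-ring molecule used for count checks."""

from __future__ import annotations

import numpy as np
import pytest

from invqsar.chemgraph import ChemGraph, Dataset
from invqsar.descriptors import RootedTree, build_descriptor_space
from invqsar.specification import (
    ChemSpec,
    EdgeBounds,
    InteriorSpec,
    Plan,
    SeedEdge,
    SeedGraph,
    SideConstraint,
    TargetSpec,
    VertexBounds,
    build_graph,
    iter_extensions,
)
from invqsar.synthetic import SyntheticConfig, generate_synthetic_dataset


def canon(code: str) -> str:
    return RootedTree.from_code(code).canonical().code()


TOY_CODES = ("(C)", "(N)", "(C(O~1))", "(C(C~2))")


@pytest.fixture(scope="session")
def toy_spec() -> TargetSpec:
    """Monocyclic seed (two vertices, two parallel path edges), rho=1."""
    seed = SeedGraph(2, [SeedEdge("a1", 0, 1, "ge2"), SeedEdge("a2", 0, 1, "ge1")])
    si = InteriorSpec(
        3, 5,
        {"a1": EdgeBounds(l_ub=3), "a2": EdgeBounds(l_ub=2)},
        side_constraints=[SideConstraint({"a1": 1, "a2": -1}, ">=", 0)],
    )
    sce = ChemSpec(
        n_lb=3, n_star=8,
        fringe_v={0: TOY_CODES, 1: TOY_CODES},
        fringe_e=TOY_CODES,
        lambda_int_allowed=("C", "N", "O"),
    )
    return TargetSpec(seed, si, sce, rho=1)


@pytest.fixture(scope="session")
def toy_extensions(toy_spec):
    return list(iter_extensions(toy_spec))


@pytest.fixture(scope="session")
def toy_space(toy_spec, toy_extensions):
    graphs = [g for g, _ in toy_extensions[::29]]
    return build_descriptor_space(Dataset(graphs, [0.0] * len(graphs)), toy_spec.rho)


@pytest.fixture(scope="session")
def random_graphs():
    """A reproducible batch of valence-valid random chemical graphs."""
    cfg = SyntheticConfig(n_samples=120, extra_cycle_edges=(0, 2))
    return generate_synthetic_dataset(cfg, seed=11).graphs


# ---------------------------------------------------------------------------
# The reference molecule: a 12-vertex multi-ring seed expanded by five paths
# and three leaf paths into a 28-vertex interior carrying 8 fringe trees
# with 19 exterior atoms (14 stripped in round 0, 5 in round 1) at rho=2.
# ---------------------------------------------------------------------------

REF_CODES = {
    "Ta": canon("(C(C~1(C~1)))"),
    "Tb": canon("(C(N~1(C~1)))"),
    "Tc": canon("(C(O~1(C~1)))"),
    "Td": canon("(C(C~1(C~1)(C~1))(C~1))"),
    "Te": canon("(C(C~1(O~1))(O~1))"),
    "Tf": canon("(C(O~1)(O~1))"),
    "Th": canon("(C(N~1)(O~1))"),
}


def _ref_seed() -> SeedGraph:
    edges = [
        SeedEdge("a1", 0, 1, "ge2"),
        SeedEdge("a2", 0, 2, "ge2"),
        SeedEdge("a3", 3, 6, "ge2"),
        SeedEdge("a4", 9, 10, "ge2"),
        SeedEdge("a5", 10, 11, "ge2"),
        SeedEdge("a6", 4, 7, "ge1"),
        SeedEdge("a7", 5, 8, "zero_one"),
        SeedEdge("a8", 1, 2, "eq1"),
        SeedEdge("a9", 3, 4, "eq1"),
        SeedEdge("a10", 4, 5, "eq1"),
        SeedEdge("a11", 5, 6, "eq1"),
        SeedEdge("a12", 9, 11, "eq1"),
        SeedEdge("a13", 2, 3, "eq1"),
        SeedEdge("a14", 6, 7, "eq1"),
        SeedEdge("a15", 7, 8, "eq1"),
        SeedEdge("a16", 8, 9, "eq1"),
        SeedEdge("a17", 8, 11, "eq1"),
    ]
    return SeedGraph(12, edges)


def ref_spec() -> TargetSpec:
    c = REF_CODES
    plain = canon("(C)")
    seed = _ref_seed()
    si = InteriorSpec(
        20, 30,
        edge_bounds={
            "a1": EdgeBounds(l_ub=2),
            "a2": EdgeBounds(l_ub=2),
            "a3": EdgeBounds(l_ub=3),
            "a4": EdgeBounds(l_ub=4, bl_ub=1, ch_ub=3),
            "a5": EdgeBounds(l_ub=4, bl_ub=1, ch_ub=1),
            "a6": EdgeBounds(l_ub=1),
        },
        vertex_bounds={4: VertexBounds(bl_ub=1, ch_ub=2)},
    )
    fv = {i: (plain,) for i in range(12)}
    fv[1] = (c["Tf"],)
    fe = tuple(sorted({plain, *c.values()}))
    sce = ChemSpec(
        n_lb=30, n_star=60,
        fringe_v=fv,
        fringe_e=fe,
        lambda_int_allowed=("C", "N", "O"),
    )
    return TargetSpec(seed, si, sce, rho=2)


def ref_plan() -> Plan:
    c = REF_CODES
    plain = canon("(C)")
    lengths = {"a1": 2, "a2": 2, "a3": 3, "a4": 4, "a5": 4, "a6": 1, "a7": 1}
    lengths.update({f"a{i}": 1 for i in range(8, 18)})
    leaf_vertex = {4: 2}
    leaf_path = {("a4", 2): 3, ("a5", 3): 1}
    fringe = {f"s{i}": plain for i in range(12)}
    fringe["s1"] = c["Tf"]
    fringe.update(
        {
            "p:a1:1": c["Td"],
            "p:a2:1": c["Te"],
            "p:a3:1": c["Tf"],
            "p:a3:2": plain,
            "p:a4:1": plain,
            "p:a4:2": plain,
            "p:a4:3": plain,
            "p:a5:1": c["Th"],
            "p:a5:2": plain,
            "p:a5:3": plain,
            "q:v4:1": plain,
            "q:v4:2": c["Ta"],
            "q:p:a4:2:1": plain,
            "q:p:a4:2:2": plain,
            "q:p:a4:2:3": c["Tb"],
            "q:p:a5:3:1": c["Tc"],
        }
    )
    bonds = {}
    for eid, l in lengths.items():
        for k in range(l):
            bonds[f"e:{eid}:{k}"] = 1
    for (eid, slot), q in leaf_path.items():
        for j in range(q):
            bonds[f"qe:p:{eid}:{slot}:{j}"] = 1
    for j in range(leaf_vertex[4]):
        bonds[f"qe:v4:{j}"] = 1
    return Plan(lengths, leaf_vertex, leaf_path, fringe, bonds)


@pytest.fixture(scope="session")
def ref_molecule():
    """(graph, spec, plan) of the reference reconstruction."""
    spec = ref_spec()
    plan = ref_plan()
    G, meta = build_graph(plan, spec)
    return G, spec, plan
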