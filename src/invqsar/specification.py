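"""Target specifications: seed graphs, interior and chemical constraints.

A target graph is built from a *seed graph* whose edges carry expansion
classes: ``ge2`` edges become paths of length >= 2, ``ge1`` edges paths of
length >= 1, ``zero_one`` edges are kept or dropped, ``eq1`` edges are kept
as-is.  *Leaf paths* may hang off seed vertices or path-internal vertices.
The resulting graph is the interior of the target; every interior vertex is
then assigned a fringe tree from per-vertex candidate sets, which fixes its
element label, and every interior edge a bond multiplicity.

The *interior specification* bounds path lengths, leaf-path counts and
lengths, interior size and per-path double/triple-bond counts; the
*chemical specification* bounds total size, fringe candidates, allowed
elements and the frequencies of elements, chemical symbols,
adjacency-configurations and edge-configurations in the interior.

All construction routes (random sampling, exhaustive enumeration, MILP
decoding) share one *plan* representation, so they agree exactly on which
graphs are extensions of a specification.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .chemgraph import ChemGraph, ChemGraphError, DEFAULT_TABLE, ElementTable
from .descriptors import (
    AdjConfig,
    DescriptorSpace,
    EdgeConfig,
    RootedTree,
    adjacency_config,
    canonical_code,
    chemical_symbol,
    edge_config,
    gamma_text,
)
from .twolayer import decompose

EDGE_CLASSES = ("ge2", "ge1", "zero_one", "eq1")


class SpecError(ChemGraphError):
    """Schema or consistency error in a target specification."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedEdge:
    id: str
    u: int
    v: int
    cls: str

    def __post_init__(self):
        if self.cls not in EDGE_CLASSES:
            raise SpecError(f"unknown edge class {self.cls!r}")
        if self.u == self.v:
            raise SpecError(f"seed edge {self.id} is a loop")


@dataclass
class SeedGraph:
    """Abstract multigraph with edge expansion classes (parallel edges OK)."""

    n_vertices: int
    edges: List[SeedEdge]

    def __post_init__(self):
        ids = [e.id for e in self.edges]
        if len(set(ids)) != len(ids):
            raise SpecError("duplicate seed edge ids")
        for e in self.edges:
            if not (0 <= e.u < self.n_vertices and 0 <= e.v < self.n_vertices):
                raise SpecError(f"seed edge {e.id} out of range")

    def edge(self, eid: str) -> SeedEdge:
        for e in self.edges:
            if e.id == eid:
                return e
        raise SpecError(f"unknown seed edge {eid!r}")

    def by_class(self, cls: str) -> List[SeedEdge]:
        return [e for e in self.edges if e.cls == cls]

    def required_nx(self) -> nx.MultiGraph:
        """Seed graph without the optional zero_one edges."""
        g = nx.MultiGraph()
        g.add_nodes_from(range(self.n_vertices))
        for e in self.edges:
            if e.cls != "zero_one":
                g.add_edge(e.u, e.v, key=e.id)
        return g


@dataclass
class EdgeBounds:
    l_lb: int = 0
    l_ub: Optional[int] = None
    bl_lb: int = 0
    bl_ub: int = 0
    ch_lb: int = 0
    ch_ub: int = 0
    bd2_lb: int = 0
    bd2_ub: Optional[int] = None
    bd3_lb: int = 0
    bd3_ub: Optional[int] = None


@dataclass
class VertexBounds:
    bl_lb: int = 0  # leaf-path count indicator at a seed vertex, in {0,1}
    bl_ub: int = 0
    ch_lb: int = 0  # leaf-path length bounds at a seed vertex
    ch_ub: int = 0


@dataclass
class SideConstraint:
    """Integer linear inequality over per-edge path lengths."""

    coeffs: Dict[str, int]
    sense: str  # "<=", ">=", "=="
    rhs: int

    def holds(self, lengths: Dict[str, int]) -> bool:
        lhs = sum(c * lengths[eid] for eid, c in self.coeffs.items())
        if self.sense == "<=":
            return lhs <= self.rhs
        if self.sense == ">=":
            return lhs >= self.rhs
        return lhs == self.rhs


@dataclass
class InteriorSpec:
    n_int_lb: int
    n_int_ub: int
    edge_bounds: Dict[str, EdgeBounds] = field(default_factory=dict)
    vertex_bounds: Dict[int, VertexBounds] = field(default_factory=dict)
    side_constraints: List[SideConstraint] = field(default_factory=list)

    def eb(self, eid: str) -> EdgeBounds:
        return self.edge_bounds.get(eid, EdgeBounds())

    def vb(self, v: int) -> VertexBounds:
        return self.vertex_bounds.get(v, VertexBounds())


@dataclass
class ChemSpec:
    n_lb: int
    n_star: int
    fringe_v: Dict[int, Tuple[str, ...]]  # per seed vertex F(v), canonical codes
    fringe_e: Tuple[str, ...]  # FE for non-seed interior vertices
    lambda_int_allowed: Tuple[str, ...]
    lambda_star: Dict[int, Tuple[str, ...]] = field(default_factory=dict)
    gamma_int_allowed: Optional[Tuple[EdgeConfig, ...]] = None
    na_lb: Dict[str, int] = field(default_factory=dict)
    na_ub: Dict[str, int] = field(default_factory=dict)
    na_int_lb: Dict[str, int] = field(default_factory=dict)
    na_int_ub: Dict[str, int] = field(default_factory=dict)
    ns_int_lb: Dict[Tuple[str, int], int] = field(default_factory=dict)
    ns_int_ub: Dict[Tuple[str, int], int] = field(default_factory=dict)
    ac_int_lb: Dict[AdjConfig, int] = field(default_factory=dict)
    ac_int_ub: Dict[AdjConfig, int] = field(default_factory=dict)
    ec_int_lb: Dict[EdgeConfig, int] = field(default_factory=dict)
    ec_int_ub: Dict[EdgeConfig, int] = field(default_factory=dict)

    def f_star(self) -> Tuple[str, ...]:
        codes = set(self.fringe_e)
        for cs in self.fringe_v.values():
            codes |= set(cs)
        return tuple(sorted(codes))

    def candidates(self, seed_vertex: Optional[int]) -> Tuple[str, ...]:
        if seed_vertex is None:
            return self.fringe_e
        return self.fringe_v.get(seed_vertex, self.fringe_e)


@dataclass
class TargetSpec:
    seed: SeedGraph
    interior: InteriorSpec
    chemical: ChemSpec
    rho: int
    table: ElementTable = DEFAULT_TABLE

    def __post_init__(self):
        validate_schema(self)


@dataclass
class ValidationReport:
    violations: List[Tuple[str, str, object, object]] = field(default_factory=list)

    @property
    def is_extension(self) -> bool:
        return not self.violations

    def add(self, rule: str, location: str, observed, bound):
        self.violations.append((rule, location, observed, bound))


# ---------------------------------------------------------------------------
# Schema validation, load and save
# ---------------------------------------------------------------------------


def _forced_length_range(e: SeedEdge, eb: EdgeBounds, n_star: int) -> Tuple[int, int]:
    if e.cls == "eq1":
        return (1, 1)
    if e.cls == "zero_one":
        return (max(0, eb.l_lb), 1 if eb.l_ub is None else min(1, eb.l_ub))
    lo = max(eb.l_lb, 2 if e.cls == "ge2" else 1)
    hi = eb.l_ub if eb.l_ub is not None else n_star
    return (lo, hi)


def validate_schema(spec: TargetSpec):
    si, sce, seed = spec.interior, spec.chemical, spec.seed
    errors = []
    if not (si.n_int_lb <= si.n_int_ub):
        errors.append("n_int_lb > n_int_ub")
    if not (si.n_int_lb <= sce.n_lb <= sce.n_star):
        errors.append("need n_int_lb <= n_lb <= n_star")
    for e in seed.edges:
        eb = si.eb(e.id)
        lo, hi = _forced_length_range(e, eb, sce.n_star)
        if lo > hi:
            errors.append(f"edge {e.id}: length lower bound {lo} > upper bound {hi}")
        if eb.ch_lb > eb.ch_ub:
            errors.append(f"edge {e.id}: ch_lb > ch_ub")
        if eb.bl_lb > eb.bl_ub:
            errors.append(f"edge {e.id}: bl_lb > bl_ub")
    for v, vb in si.vertex_bounds.items():
        if not (0 <= vb.bl_lb <= vb.bl_ub <= 1):
            errors.append(f"vertex {v}: leaf-path indicator bounds must be in {{0,1}}")
        if vb.ch_lb > vb.ch_ub:
            errors.append(f"vertex {v}: ch_lb > ch_ub")
    for a in sce.lambda_int_allowed:
        if a not in spec.table:
            errors.append(f"unknown element {a}")
    for v, elems in sce.lambda_star.items():
        for a in elems:
            if spec.table.valence(a) < 2:
                errors.append(f"Lambda*({v}) element {a} has valence < 2")
    for code in sce.f_star():
        t = RootedTree.from_code(code)
        if t.height > spec.rho:
            errors.append(f"fringe tree {code} taller than rho={spec.rho}")
    if errors:
        raise SpecError("; ".join(errors))


def _bounds_to_dict(spec: TargetSpec) -> dict:
    si, sce, seed = spec.interior, spec.chemical, spec.seed
    return {
        "rho": spec.rho,
        "element_table": spec.table.to_dict(),
        "seed_graph": {
            "n_vertices": seed.n_vertices,
            "edges": [
                {"id": e.id, "u": e.u, "v": e.v, "class": e.cls} for e in seed.edges
            ],
        },
        "interior_spec": {
            "n_int_lb": si.n_int_lb,
            "n_int_ub": si.n_int_ub,
            "edges": {
                eid: {k: v for k, v in vars(eb).items() if v is not None}
                for eid, eb in sorted(si.edge_bounds.items())
            },
            "vertices": {
                str(v): vars(vb) for v, vb in sorted(si.vertex_bounds.items())
            },
        },
        "chemical_spec": {
            "n_lb": sce.n_lb,
            "n_star": sce.n_star,
            "fringe_v": {str(v): list(c) for v, c in sorted(sce.fringe_v.items())},
            "fringe_e": list(sce.fringe_e),
            "lambda_int": list(sce.lambda_int_allowed),
            "lambda_star": {
                str(v): list(a) for v, a in sorted(sce.lambda_star.items())
            },
            "gamma_int": None
            if sce.gamma_int_allowed is None
            else [[g[0][0], g[0][1], g[1][0], g[1][1], g[2]] for g in sce.gamma_int_allowed],
            "na_lb": dict(sce.na_lb),
            "na_ub": dict(sce.na_ub),
            "na_int_lb": dict(sce.na_int_lb),
            "na_int_ub": dict(sce.na_int_ub),
            "ns_int_lb": {f"{a}{d}": x for (a, d), x in sorted(sce.ns_int_lb.items())},
            "ns_int_ub": {f"{a}{d}": x for (a, d), x in sorted(sce.ns_int_ub.items())},
            "ac_int_lb": {f"{a},{b},{m}": x for (a, b, m), x in sorted(sce.ac_int_lb.items())},
            "ac_int_ub": {f"{a},{b},{m}": x for (a, b, m), x in sorted(sce.ac_int_ub.items())},
            "ec_int_lb": {gamma_text(g): x for g, x in sorted(sce.ec_int_lb.items(), key=lambda kv: gamma_text(kv[0]))},
            "ec_int_ub": {gamma_text(g): x for g, x in sorted(sce.ec_int_ub.items(), key=lambda kv: gamma_text(kv[0]))},
        },
        "side_constraints": [
            {"coeffs": dict(c.coeffs), "sense": c.sense, "rhs": c.rhs}
            for c in si.side_constraints
        ],
    }


def _parse_symbol(s: str) -> Tuple[str, int]:
    return (s[:-1], int(s[-1]))


def _parse_gamma(s: str) -> EdgeConfig:
    body = s.strip("()")
    mu, xi, m = body.split(",")
    return (_parse_symbol(mu), _parse_symbol(xi), int(m))


def save_spec(spec: TargetSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(_bounds_to_dict(spec), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_spec(source) -> TargetSpec:
    """Load a specification from a JSON file path or an equivalent dict."""
    if isinstance(source, dict):
        d = source
    else:
        with open(source) as fh:
            d = json.load(fh)
    table = (
        ElementTable.from_dict(d["element_table"])
        if "element_table" in d
        else DEFAULT_TABLE
    )
    sg = d["seed_graph"]
    seed = SeedGraph(
        n_vertices=int(sg["n_vertices"]),
        edges=[
            SeedEdge(e["id"], int(e["u"]), int(e["v"]), e["class"])
            for e in sg["edges"]
        ],
    )
    sid = d["interior_spec"]
    interior = InteriorSpec(
        n_int_lb=int(sid["n_int_lb"]),
        n_int_ub=int(sid["n_int_ub"]),
        edge_bounds={
            eid: EdgeBounds(**eb) for eid, eb in sid.get("edges", {}).items()
        },
        vertex_bounds={
            int(v): VertexBounds(**vb) for v, vb in sid.get("vertices", {}).items()
        },
        side_constraints=[
            SideConstraint(dict(c["coeffs"]), c["sense"], int(c["rhs"]))
            for c in d.get("side_constraints", [])
        ],
    )
    scd = d["chemical_spec"]
    chemical = ChemSpec(
        n_lb=int(scd["n_lb"]),
        n_star=int(scd["n_star"]),
        fringe_v={int(v): tuple(c) for v, c in scd.get("fringe_v", {}).items()},
        fringe_e=tuple(scd.get("fringe_e", ())),
        lambda_int_allowed=tuple(scd["lambda_int"]),
        lambda_star={
            int(v): tuple(a) for v, a in scd.get("lambda_star", {}).items()
        },
        gamma_int_allowed=None
        if scd.get("gamma_int") is None
        else tuple(((a, da), (b, db), m) for a, da, b, db, m in scd["gamma_int"]),
        na_lb=dict(scd.get("na_lb", {})),
        na_ub=dict(scd.get("na_ub", {})),
        na_int_lb=dict(scd.get("na_int_lb", {})),
        na_int_ub=dict(scd.get("na_int_ub", {})),
        ns_int_lb={_parse_symbol(k): v for k, v in scd.get("ns_int_lb", {}).items()},
        ns_int_ub={_parse_symbol(k): v for k, v in scd.get("ns_int_ub", {}).items()},
        ac_int_lb={
            tuple([*k.split(",")[:2], int(k.split(",")[2])]): v
            for k, v in scd.get("ac_int_lb", {}).items()
        },
        ac_int_ub={
            tuple([*k.split(",")[:2], int(k.split(",")[2])]): v
            for k, v in scd.get("ac_int_ub", {}).items()
        },
        ec_int_lb={_parse_gamma(k): v for k, v in scd.get("ec_int_lb", {}).items()},
        ec_int_ub={_parse_gamma(k): v for k, v in scd.get("ec_int_ub", {}).items()},
    )
    return TargetSpec(seed, interior, chemical, int(d["rho"]), table)


# ---------------------------------------------------------------------------
# Plans: the shared construction representation
# ---------------------------------------------------------------------------


@dataclass
class Plan:
    """One concrete set of construction choices for a specification."""

    lengths: Dict[str, int]  # seed edge id -> path length (0 = dropped)
    leaf_vertex: Dict[int, int]  # seed vertex -> leaf path length (0 = none)
    leaf_path: Dict[Tuple[str, int], int]  # (edge id, slot 1..l-1) -> length
    fringe: Dict[str, str]  # interior vertex key -> fringe code
    bonds: Dict[str, int]  # interior edge key -> bond multiplicity


def seed_vertex_key(i: int) -> str:
    return f"s{i}"


def interior_layout(
    seed: SeedGraph, lengths: Dict[str, int], leaf_vertex, leaf_path
) -> Tuple[List[str], List[Tuple[str, str, str]]]:
    """Deterministic interior vertex keys and edge triples (key, a, b)."""
    vkeys: List[str] = [seed_vertex_key(i) for i in range(seed.n_vertices)]
    ekeys: List[Tuple[str, str, str]] = []
    for e in seed.edges:
        l = lengths[e.id]
        if l == 0:
            continue
        chain = [seed_vertex_key(e.u)]
        for k in range(1, l):
            key = f"p:{e.id}:{k}"
            vkeys.append(key)
            chain.append(key)
        chain.append(seed_vertex_key(e.v))
        for k in range(l):
            ekeys.append((f"e:{e.id}:{k}", chain[k], chain[k + 1]))
    anchors: List[Tuple[str, str]] = []
    for i in range(seed.n_vertices):
        q = leaf_vertex.get(i, 0)
        if q > 0:
            anchors.append((seed_vertex_key(i), f"v{i}"))
    for (eid, slot), q in sorted(leaf_path.items()):
        if q > 0:
            anchors.append((f"p:{eid}:{slot}", f"p:{eid}:{slot}"))
    for anchor_vkey, tag in anchors:
        q = (
            leaf_vertex[int(tag[1:])]
            if tag.startswith("v")
            else leaf_path[(tag.split(":")[1], int(tag.split(":")[2]))]
        )
        chain = [anchor_vkey]
        for j in range(1, q + 1):
            key = f"q:{tag}:{j}"
            vkeys.append(key)
            chain.append(key)
        for j in range(q):
            ekeys.append((f"qe:{tag}:{j}", chain[j], chain[j + 1]))
    return vkeys, ekeys


def interior_degrees(vkeys, ekeys) -> Dict[str, int]:
    deg = {k: 0 for k in vkeys}
    for (_, a, b) in ekeys:
        deg[a] += 1
        deg[b] += 1
    return deg


def build_graph(plan: Plan, spec: TargetSpec) -> Tuple[ChemGraph, dict]:
    """Materialise a plan as a chemical graph.

    Returns the graph and a meta dict with the interior key -> vertex-id
    map.  Raises :class:`ChemGraphError` on structural impossibilities
    (parallel edges, valence violations, disconnection).
    """
    seed = spec.seed
    vkeys, ekeys = interior_layout(seed, plan.lengths, plan.leaf_vertex, plan.leaf_path)
    vid = {k: i for i, k in enumerate(vkeys)}
    n = len(vkeys)
    edges: List[Tuple[int, int]] = []
    beta: List[int] = []
    for (ek, a, b) in ekeys:
        edges.append((vid[a], vid[b]))
        beta.append(plan.bonds[ek])
    alpha: List[str] = [""] * n
    trees = {}
    for k in vkeys:
        code = plan.fringe[k]
        t = RootedTree.from_code(code)
        trees[k] = t
        alpha[vid[k]] = t.element
    # expand fringe trees
    next_id = n

    def expand(node: RootedTree, parent_id: int):
        nonlocal next_id
        for c in node.children:
            cid = next_id
            next_id += 1
            alpha.append(c.element)
            edges.append((parent_id, cid))
            beta.append(c.bond)
            expand(c, cid)

    for k in vkeys:
        expand(trees[k], vid[k])
    G = ChemGraph(next_id, edges, alpha, beta, spec.table)
    return G, {"vid": vid, "vkeys": vkeys, "ekeys": ekeys}


def check_plan(plan: Plan, spec: TargetSpec) -> Tuple[Optional[ChemGraph], ValidationReport]:
    """Check every interior and chemical bound for a plan; build the graph."""
    seed, si, sce = spec.seed, spec.interior, spec.chemical
    rep = ValidationReport()

    # --- structural sigma_int rules ------------------------------------
    for e in seed.edges:
        l = plan.lengths[e.id]
        lo, hi = _forced_length_range(e, si.eb(e.id), sce.n_star)
        if not lo <= l <= hi:
            rep.add("path-length", e.id, l, (lo, hi))
    for c in si.side_constraints:
        if not c.holds(plan.lengths):
            rep.add("side-constraint", str(c.coeffs), None, (c.sense, c.rhs))
    # parallel realisations of length 1 between one vertex pair
    pairs: Dict[Tuple[int, int], int] = {}
    for e in seed.edges:
        if plan.lengths[e.id] == 1:
            p = (min(e.u, e.v), max(e.u, e.v))
            pairs[p] = pairs.get(p, 0) + 1
    for p, cnt in pairs.items():
        if cnt > 1:
            rep.add("simple-graph", str(p), cnt, 1)

    for i in range(seed.n_vertices):
        vb = si.vb(i)
        q = plan.leaf_vertex.get(i, 0)
        ind = 1 if q > 0 else 0
        if not vb.bl_lb <= ind <= vb.bl_ub:
            rep.add("leaf-count-vertex", f"u{i}", ind, (vb.bl_lb, vb.bl_ub))
        if q > 0 and not vb.ch_lb <= q <= vb.ch_ub:
            rep.add("leaf-length-vertex", f"u{i}", q, (vb.ch_lb, vb.ch_ub))
    for e in seed.edges:
        eb = si.eb(e.id)
        slots = [
            (slot, q)
            for (eid, slot), q in plan.leaf_path.items()
            if eid == e.id and q > 0
        ]
        for (slot, q) in slots:
            if not 1 <= slot <= plan.lengths[e.id] - 1:
                rep.add("leaf-anchor", f"{e.id}:{slot}", slot, plan.lengths[e.id] - 1)
            if q > eb.ch_ub:
                rep.add("leaf-length-edge", f"{e.id}:{slot}", q, eb.ch_ub)
        cnt = len(slots)
        if not eb.bl_lb <= cnt <= eb.bl_ub:
            rep.add("leaf-count-edge", e.id, cnt, (eb.bl_lb, eb.bl_ub))
        if eb.ch_lb > 0 and cnt > 0 and max(q for _, q in slots) < eb.ch_lb:
            rep.add("leaf-maxlen-edge", e.id, max(q for _, q in slots), eb.ch_lb)

    vkeys, ekeys = interior_layout(seed, plan.lengths, plan.leaf_vertex, plan.leaf_path)
    n_int = len(vkeys)
    if not si.n_int_lb <= n_int <= si.n_int_ub:
        rep.add("n-interior", "G", n_int, (si.n_int_lb, si.n_int_ub))

    # per-seed-edge bond-multiplicity counts
    for e in seed.edges:
        eb = si.eb(e.id)
        ms = [
            plan.bonds[ek]
            for (ek, _, _) in ekeys
            if ek.startswith(f"e:{e.id}:")
        ]
        for m, lb, ub in ((2, eb.bd2_lb, eb.bd2_ub), (3, eb.bd3_lb, eb.bd3_ub)):
            cnt = sum(1 for x in ms if x == m)
            ub_eff = sce.n_star if ub is None else ub
            if not lb <= cnt <= ub_eff:
                rep.add(f"bd{m}", e.id, cnt, (lb, ub_eff))

    # --- fringe assignments --------------------------------------------
    deg = interior_degrees(vkeys, ekeys)
    for k in vkeys:
        code = plan.fringe.get(k)
        if code is None:
            rep.add("fringe-missing", k, None, None)
            continue
        t = RootedTree.from_code(code)
        sv = int(k[1:]) if k.startswith("s") else None
        cands = sce.candidates(sv)
        if code not in cands:
            rep.add("fringe-candidate", k, code, cands)
        if t.element not in sce.lambda_int_allowed:
            rep.add("lambda-int", k, t.element, sce.lambda_int_allowed)
        if sv is not None and sv in sce.lambda_star:
            if t.element not in sce.lambda_star[sv]:
                rep.add("lambda-star", k, t.element, sce.lambda_star[sv])
        if t.height > spec.rho:
            rep.add("fringe-height", k, t.height, spec.rho)
        if deg[k] == 1 and t.height != spec.rho:
            rep.add("fringe-height-leaf", k, t.height, spec.rho)
        if n_int > 1 and deg[k] == 0:
            rep.add("isolated-interior", k, 0, ">=1")

    if rep.violations:
        return None, rep

    try:
        G, meta = build_graph(plan, spec)
    except ChemGraphError as exc:
        rep.add("build", "G", str(exc), None)
        return None, rep

    _check_chemical_counts(G, spec, rep)
    return G, rep


def _check_chemical_counts(G: ChemGraph, spec: TargetSpec, rep: ValidationReport):
    """sigma_ce count bounds, computed on the actual graph."""
    sce = spec.chemical
    dec = decompose(G, spec.rho)
    if not sce.n_lb <= G.n <= sce.n_star:
        rep.add("n", "G", G.n, (sce.n_lb, sce.n_star))
    na: Dict[str, int] = {}
    na_int: Dict[str, int] = {}
    ns: Dict[Tuple[str, int], int] = {}
    for v in range(G.n):
        na[G.alpha[v]] = na.get(G.alpha[v], 0) + 1
    for v in dec.interior_vertices:
        a = G.alpha[v]
        na_int[a] = na_int.get(a, 0) + 1
        mu = chemical_symbol(G, v)
        ns[mu] = ns.get(mu, 0) + 1
    ac: Dict[AdjConfig, int] = {}
    ec: Dict[EdgeConfig, int] = {}
    for e in dec.interior_edges:
        nu = adjacency_config(G, e)
        ac[nu] = ac.get(nu, 0) + 1
        g = edge_config(G, e, dec)
        ec[g] = ec.get(g, 0) + 1
    if sce.gamma_int_allowed is not None:
        allowed = set(sce.gamma_int_allowed)
        for g in ec:
            if g not in allowed:
                rep.add("gamma-int", gamma_text(g), ec[g], "not allowed")

    def bounds(counts, lbs, ubs, rule):
        keys = set(counts) | set(lbs) | set(ubs)
        for k in keys:
            c = counts.get(k, 0)
            lb = lbs.get(k, 0)
            ub = ubs.get(k, sce.n_star)
            if not lb <= c <= ub:
                rep.add(rule, str(k), c, (lb, ub))

    bounds(na, sce.na_lb, sce.na_ub, "na")
    bounds(na_int, sce.na_int_lb, sce.na_int_ub, "na-int")
    bounds(ns, sce.ns_int_lb, sce.ns_int_ub, "ns-int")
    bounds(ac, sce.ac_int_lb, sce.ac_int_ub, "ac-int")
    bounds(ec, sce.ec_int_lb, sce.ec_int_ub, "ec-int")


# ---------------------------------------------------------------------------
# Recovering a plan from a concrete graph (validation)
# ---------------------------------------------------------------------------


def is_subdivision(S: nx.Graph, seed: SeedGraph, anchors: Dict[int, int]):
    """Edge -> path correspondence witnessing that ``S`` subdivides the seed
    with seed vertex ``i`` at ``anchors[i]``; ``None`` when none exists."""
    for plan_paths in _match_seed_edges(S, seed, anchors, set(anchors.values())):
        return plan_paths
    return None


def _match_seed_edges(
    S: nx.Graph, seed: SeedGraph, anchors: Dict[int, int], used: set
) -> Iterator[Dict[str, List[int]]]:
    """Yield assignments of internally disjoint paths to seed edges."""
    order = sorted(seed.edges, key=lambda e: e.id)
    imgs = set(anchors.values())

    def rec(i: int, used_v: set, used_e: set, acc: Dict[str, List[int]]):
        if i == len(order):
            yield dict(acc)
            return
        e = order[i]
        su, sv = anchors[e.u], anchors[e.v]
        options: List[List[int]] = []
        if e.cls == "zero_one":
            options.append([])  # dropped
        cutoff = _forced_length_range(e, InteriorSpec(0, 0).eb(e.id), S.number_of_nodes())[1]
        if e.cls in ("eq1", "zero_one"):
            if S.has_edge(su, sv) and (su, sv) not in used_e and (sv, su) not in used_e:
                options.append([su, sv])
        else:
            for path in nx.all_simple_paths(S, su, sv, cutoff=cutoff):
                if e.cls == "ge2" and len(path) < 3:
                    continue
                if any(w in imgs or w in used_v for w in path[1:-1]):
                    continue
                pe = list(zip(path, path[1:]))
                if any((a, b) in used_e or (b, a) in used_e for a, b in pe):
                    continue
                options.append(path)
        for path in options:
            nv = {w for w in path[1:-1]}
            ne = {(a, b) for a, b in zip(path, path[1:])}
            acc[e.id] = path
            yield from rec(i + 1, used_v | nv, used_e | ne | {(b, a) for a, b in ne}, acc)
            del acc[e.id]

    yield from rec(0, set(used), set(), {})


def _recover_plans(G: ChemGraph, spec: TargetSpec, limit: int = 200) -> Iterator[Plan]:
    """Backtracking search for plans whose built graph is exactly ``G``'s
    interior structure.  Anchors seed vertices on interior vertices."""
    seed, sce = spec.seed, spec.chemical
    dec = decompose(G, spec.rho)
    int_v = sorted(dec.interior_vertices)
    Hint = nx.Graph()
    Hint.add_nodes_from(int_v)
    Hint.add_edges_from(dec.interior_edges)
    code_of = {T.root: canonical_code(T) for T in dec.fringe_trees}

    # candidate interior vertices per seed vertex, cheap filters first
    req_deg = {i: 0 for i in range(seed.n_vertices)}
    for e in seed.edges:
        if e.cls != "zero_one":
            req_deg[e.u] += 1
            req_deg[e.v] += 1
    cand: Dict[int, List[int]] = {}
    for i in range(seed.n_vertices):
        cs = []
        for v in int_v:
            if Hint.degree(v) < req_deg[i]:
                continue
            if i in sce.lambda_star and G.alpha[v] not in sce.lambda_star[i]:
                continue
            if i in sce.fringe_v and code_of[v] not in sce.fringe_v[i]:
                continue
            cs.append(v)
        cand[i] = cs

    count = 0
    # anchor assignment order: most-constrained first, then favour vertices
    # linked by eq1 edges to already-placed ones (their images must be
    # adjacent in the interior, a strong incremental filter)
    eq1_pairs = [
        (e.u, e.v) for e in seed.edges if e.cls == "eq1"
    ]
    order: List[int] = []
    remaining = set(range(seed.n_vertices))
    while remaining:
        def score(i):
            links = sum(1 for (u, v) in eq1_pairs if (u == i and v in order) or (v == i and u in order))
            return (-links, len(cand[i]), i)
        nxt = min(remaining, key=score)
        order.append(nxt)
        remaining.remove(nxt)

    def consistent(placed: Dict[int, int]) -> bool:
        for (u, v) in eq1_pairs:
            if u in placed and v in placed and not Hint.has_edge(placed[u], placed[v]):
                return False
        return True

    for combo in _injective_assignments(order, cand, consistent):
        anchors = dict(combo)
        for paths in _match_seed_edges(Hint, seed, anchors, set(anchors.values())):
            plan = _paths_to_plan(G, spec, Hint, anchors, paths, code_of)
            if plan is not None:
                yield plan
                count += 1
                if count >= limit:
                    return


def _injective_assignments(order, cand, consistent=None):
    def rec(i, used, acc):
        if i == len(order):
            yield list(acc)
            return
        k = order[i]
        for v in cand[k]:
            if v in used:
                continue
            acc.append((k, v))
            if consistent is None or consistent(dict(acc)):
                yield from rec(i + 1, used | {v}, acc)
            acc.pop()

    yield from rec(0, set(), [])


def _paths_to_plan(G, spec, Hint, anchors, paths, code_of) -> Optional[Plan]:
    """Interpret the leftover interior vertices as leaf paths and assemble a
    plan; reject when the leftovers are not leaf-path shaped."""
    seed = spec.seed
    lengths = {e.id: max(0, len(paths[e.id]) - 1) for e in seed.edges}
    used = set(anchors.values())
    path_pos: Dict[int, Tuple[str, int]] = {}
    covered_edges = set()
    for e in seed.edges:
        p = paths[e.id]
        for k, w in enumerate(p[1:-1], start=1):
            used.add(w)
            path_pos[w] = (e.id, k)
        covered_edges |= {frozenset(x) for x in zip(p, p[1:])}

    rest = [v for v in Hint.nodes if v not in used]
    sub = Hint.subgraph(rest)
    leaf_vertex: Dict[int, int] = {}
    leaf_path: Dict[Tuple[str, int], int] = {}
    inv_anchor = {v: i for i, v in anchors.items()}
    chains: Dict[int, List[int]] = {}  # anchor interior vertex -> chain

    for comp in nx.connected_components(sub):
        comp_nodes = set(comp)
        # must be a path, attached to exactly one used vertex via one edge
        attach = [
            (w, u)
            for w in comp_nodes
            for u in Hint.neighbors(w)
            if u in used
        ]
        if len(attach) != 1:
            return None
        w0, anchor = attach[0]
        cg = sub.subgraph(comp_nodes)
        if any(d > 2 for _, d in cg.degree()):
            return None
        # walk the chain from w0
        chain = [w0]
        prev = None
        cur = w0
        while True:
            nxt = [x for x in cg.neighbors(cur) if x != prev]
            if not nxt:
                break
            if len(nxt) > 1:
                return None
            prev, cur = cur, nxt[0]
            chain.append(cur)
        if len(chain) != len(comp_nodes):
            return None
        covered_edges |= {frozenset((anchor, w0))}
        covered_edges |= {frozenset(x) for x in zip(chain, chain[1:])}
        q = len(chain)
        if anchor in inv_anchor:
            leaf_vertex[inv_anchor[anchor]] = q
            chains[anchor] = chain
        elif anchor in path_pos:
            leaf_path[path_pos[anchor]] = q
            chains[anchor] = chain
        else:
            return None  # attached to a leaf-path vertex: not allowed

    if covered_edges != {frozenset(e) for e in Hint.edges}:
        return None

    # assemble fringe codes and bonds keyed like interior_layout
    fringe: Dict[str, str] = {}
    bonds: Dict[str, int] = {}
    for i, v in anchors.items():
        fringe[seed_vertex_key(i)] = code_of[v]
    key_of: Dict[int, str] = {v: seed_vertex_key(i) for i, v in anchors.items()}
    for e in seed.edges:
        p = paths[e.id]
        for k, w in enumerate(p[1:-1], start=1):
            key_of[w] = f"p:{e.id}:{k}"
            fringe[key_of[w]] = code_of[w]
        for k in range(max(0, len(p) - 1)):
            a, b = p[k], p[k + 1]
            bonds[f"e:{e.id}:{k}"] = G.beta[(min(a, b), max(a, b))]
    for anchor, chain in chains.items():
        if anchor in inv_anchor:
            tag = f"v{inv_anchor[anchor]}"
        else:
            eid, slot = path_pos[anchor]
            tag = f"p:{eid}:{slot}"
        full = [anchor] + chain
        for j, w in enumerate(chain, start=1):
            key_of[w] = f"q:{tag}:{j}"
            fringe[key_of[w]] = code_of[w]
        for j in range(len(chain)):
            a, b = full[j], full[j + 1]
            bonds[f"qe:{tag}:{j}"] = G.beta[(min(a, b), max(a, b))]
    return Plan(lengths, leaf_vertex, leaf_path, fringe, bonds)


def validate_extension(
    G: ChemGraph, spec: TargetSpec, space: Optional[DescriptorSpace] = None
) -> ValidationReport:
    """Decide whether ``G`` is an extension of the specification.

    Decomposes ``G``, searches for a seed correspondence (the inverse of
    fringe-tree removal, leaf-path removal and path contraction) and checks
    every interior and chemical bound.  All failures are report entries.
    """
    if space is not None and space.rho != spec.rho:
        raise SpecError("descriptor space rho differs from specification rho")
    first_rep: Optional[ValidationReport] = None
    found = False
    for plan in _recover_plans(G, spec):
        found = True
        _, rep = check_plan(plan, spec)
        if rep.is_extension:
            return rep
        if first_rep is None:
            first_rep = rep
    if not found:
        rep = ValidationReport()
        rep.add("subdivision", "G", "no seed correspondence", None)
        return rep
    return first_rep


# ---------------------------------------------------------------------------
# Plan generation: exhaustive enumeration and random sampling
# ---------------------------------------------------------------------------


def _length_choices(spec: TargetSpec) -> Iterator[Dict[str, int]]:
    seed, si, sce = spec.seed, spec.interior, spec.chemical
    ranges = []
    for e in seed.edges:
        lo, hi = _forced_length_range(e, si.eb(e.id), sce.n_star)
        # a path of length l adds l-1 interior vertices; cap by interior budget
        hi = min(hi, si.n_int_ub - seed.n_vertices + 1)
        ranges.append([(e.id, l) for l in range(lo, hi + 1)])
    for combo in itertools.product(*ranges):
        lengths = dict(combo)
        if all(c.holds(lengths) for c in spec.interior.side_constraints):
            yield lengths


def _leaf_choices(spec: TargetSpec, lengths) -> Iterator[Tuple[Dict[int, int], Dict]]:
    seed, si = spec.seed, spec.interior
    v_opts = []
    for i in range(seed.n_vertices):
        vb = si.vb(i)
        opts = [0] if vb.bl_lb == 0 else []
        if vb.bl_ub >= 1:
            opts += list(range(max(1, vb.ch_lb), vb.ch_ub + 1))
        v_opts.append([(i, q) for q in opts])
    e_opts = []
    for e in seed.edges:
        eb = si.eb(e.id)
        slots = list(range(1, lengths[e.id]))
        choices = []
        for r in range(eb.bl_lb, min(eb.bl_ub, len(slots)) + 1):
            for subset in itertools.combinations(slots, r):
                for qs in itertools.product(range(1, eb.ch_ub + 1), repeat=r):
                    if r > 0 and eb.ch_lb > 0 and max(qs) < eb.ch_lb:
                        continue
                    choices.append({(e.id, s): q for s, q in zip(subset, qs)})
        if not choices and eb.bl_lb == 0:
            choices = [{}]
        e_opts.append(choices)
    for vcombo in itertools.product(*v_opts):
        lv = {i: q for i, q in vcombo if q > 0}
        for ecombo in itertools.product(*e_opts):
            lp: Dict[Tuple[str, int], int] = {}
            for d in ecombo:
                lp.update(d)
            yield lv, lp


def _fringe_candidates(spec: TargetSpec, vkeys, deg) -> Optional[Dict[str, List[str]]]:
    sce = spec.chemical
    out: Dict[str, List[str]] = {}
    for k in vkeys:
        sv = int(k[1:]) if k.startswith("s") else None
        cands = []
        for code in sce.candidates(sv):
            t = RootedTree.from_code(code)
            if t.element not in sce.lambda_int_allowed:
                continue
            if sv is not None and sv in sce.lambda_star and t.element not in sce.lambda_star[sv]:
                continue
            if t.height > spec.rho:
                continue
            if deg[k] == 1 and t.height != spec.rho:
                continue
            if deg[k] + t.root_degree > 4:
                continue
            if deg[k] + t.root_beta_sum > spec.table.valence(t.element):
                continue  # even all-single interior bonds would overflow
            cands.append(code)
        if not cands:
            return None
        out[k] = cands
    return out


def iter_extensions(
    spec: TargetSpec, limit: Optional[int] = None
) -> Iterator[Tuple[ChemGraph, Plan]]:
    """Exhaustively generate all extensions of a specification.

    Intended for toy-scale specifications; graphs are yielded in a
    deterministic order and are *not* deduplicated up to isomorphism.
    """
    count = 0
    for lengths in _length_choices(spec):
        for lv, lp in _leaf_choices(spec, lengths):
            vkeys, ekeys = interior_layout(spec.seed, lengths, lv, lp)
            n_int = len(vkeys)
            if not spec.interior.n_int_lb <= n_int <= spec.interior.n_int_ub:
                continue
            deg = interior_degrees(vkeys, ekeys)
            cands = _fringe_candidates(spec, vkeys, deg)
            if cands is None:
                continue
            for fr_combo in itertools.product(*(cands[k] for k in vkeys)):
                fringe = dict(zip(vkeys, fr_combo))
                n_total = sum(RootedTree.from_code(c).size for c in fr_combo)
                if not spec.chemical.n_lb <= n_total <= spec.chemical.n_star:
                    continue
                caps = {
                    k: spec.table.valence(RootedTree.from_code(fringe[k]).element)
                    - RootedTree.from_code(fringe[k]).root_beta_sum
                    for k in vkeys
                }
                for bond_combo in _bond_choices(vkeys, ekeys, caps):
                    plan = Plan(dict(lengths), dict(lv), dict(lp), fringe, bond_combo)
                    G, rep = check_plan(plan, spec)
                    if G is not None and rep.is_extension:
                        yield G, plan
                        count += 1
                        if limit is not None and count >= limit:
                            return


def _bond_choices(vkeys, ekeys, caps) -> Iterator[Dict[str, int]]:
    """All bond assignments respecting per-vertex residual valence."""
    keys = [ek for ek, _, _ in ekeys]
    ends = {ek: (a, b) for ek, a, b in ekeys}

    def rec(i, left, acc):
        if i == len(keys):
            yield dict(acc)
            return
        ek = keys[i]
        a, b = ends[ek]
        remaining_a = sum(1 for k in keys[i:] if a in ends[k])
        remaining_b = sum(1 for k in keys[i:] if b in ends[k])
        for m in (1, 2, 3):
            if left[a] - m < remaining_a - 1 or left[b] - m < remaining_b - 1:
                continue
            left[a] -= m
            left[b] -= m
            acc[ek] = m
            yield from rec(i + 1, left, acc)
            del acc[ek]
            left[a] += m
            left[b] += m

    yield from rec(0, dict(caps), {})


def random_extension(
    spec: TargetSpec,
    rng_seed: int = 0,
    attempts: int = 2000,
) -> Optional[ChemGraph]:
    """Rejection-sample one extension of a specification.

    Follows the construction order (subdivide, attach leaf paths, assign
    fringe trees and bonds); returns ``None`` when ``attempts`` random
    plans all fail the bounds.
    """
    g = random_extension_plan(spec, rng_seed, attempts)
    return g[0] if g is not None else None


def random_extension_plan(
    spec: TargetSpec, rng_seed: int = 0, attempts: int = 2000
) -> Optional[Tuple[ChemGraph, Plan]]:
    rng = np.random.default_rng(rng_seed)
    seed, si, sce = spec.seed, spec.interior, spec.chemical
    for _ in range(attempts):
        lengths = {}
        ok = True
        for e in seed.edges:
            lo, hi = _forced_length_range(e, si.eb(e.id), sce.n_star)
            hi = min(hi, si.n_int_ub - seed.n_vertices + 1)
            if lo > hi:
                ok = False
                break
            lengths[e.id] = int(rng.integers(lo, hi + 1))
        if not ok or not all(c.holds(lengths) for c in si.side_constraints):
            continue
        lv: Dict[int, int] = {}
        for i in range(seed.n_vertices):
            vb = si.vb(i)
            if vb.bl_ub >= 1 and (vb.bl_lb == 1 or rng.random() < 0.5):
                lv[i] = int(rng.integers(max(1, vb.ch_lb), vb.ch_ub + 1))
        lp: Dict[Tuple[str, int], int] = {}
        for e in seed.edges:
            eb = si.eb(e.id)
            slots = list(range(1, lengths[e.id]))
            if not slots or eb.bl_ub == 0:
                continue
            r = int(rng.integers(eb.bl_lb, min(eb.bl_ub, len(slots)) + 1))
            for s in rng.choice(slots, size=r, replace=False):
                lp[(e.id, int(s))] = int(rng.integers(1, eb.ch_ub + 1))
        vkeys, ekeys = interior_layout(seed, lengths, lv, lp)
        deg = interior_degrees(vkeys, ekeys)
        cands = _fringe_candidates(spec, vkeys, deg)
        if cands is None:
            continue
        fringe = {k: cands[k][int(rng.integers(len(cands[k])))] for k in vkeys}
        caps = {
            k: spec.table.valence(RootedTree.from_code(fringe[k]).element)
            - RootedTree.from_code(fringe[k]).root_beta_sum
            for k in vkeys
        }
        bonds = None
        for cand_bonds in _bond_choices(vkeys, ekeys, caps):
            if rng.random() < 0.5:
                bonds = cand_bonds
                break
            bonds = cand_bonds
        if bonds is None:
            continue
        plan = Plan(lengths, lv, lp, fringe, bonds)
        G, rep = check_plan(plan, spec)
        if G is not None and rep.is_extension:
            return G, plan
    return None
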