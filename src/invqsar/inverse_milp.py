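"""Inverting the property regressor with a mixed-integer linear program.

The MILP jointly encodes (i) construction of a chemical graph from the seed
graph — integer path lengths realised as prefix-activated vertex slots,
leaf-path slots, fringe-tree assignment binaries (which fix each interior
vertex's element) and bond-multiplicity binaries; (ii) the descriptor
counts as linear sums over those binaries; and (iii) the ReLU forward pass
of the trained network via big-M constraints with interval-propagated
per-neuron bounds.  Integer-feasible points decode to specification-
conforming chemical graphs whose predicted property lies in
``[y* - eps, y* + eps]``; every decode is re-verified from scratch.

Solved with HiGHS through :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .chemgraph import ChemGraph, ChemGraphError, DisconnectedError
from .descriptors import (
    DescriptorSpace,
    RootedTree,
    feature_vector,
    gamma_text,
)
from .predictor import Predictor
from .specification import (
    Plan,
    TargetSpec,
    _forced_length_range,
    build_graph,
    check_plan,
    seed_vertex_key,
    validate_extension,
)
from .twolayer import decompose


class MILPError(ChemGraphError):
    pass


Expr = Dict[int, float]  # variable index -> coefficient


def _add(*terms) -> Expr:
    out: Expr = {}
    for t in terms:
        for i, c in t.items():
            out[i] = out.get(i, 0.0) + c
    return {i: c for i, c in out.items() if c != 0.0}


def _scale(e: Expr, s: float) -> Expr:
    return {i: c * s for i, c in e.items()}


def _symkey(table, mu):
    return (table.order_index(mu[0]), mu[1])


class _Builder:
    def __init__(self):
        self.lb: List[float] = []
        self.ub: List[float] = []
        self.integer: List[bool] = []
        self.names: List[str] = []
        self.rows: List[Tuple[Expr, float, float]] = []

    def var(self, name, lb, ub, integer=True) -> int:
        self.names.append(name)
        self.lb.append(float(lb))
        self.ub.append(float(ub))
        self.integer.append(integer)
        return len(self.names) - 1

    def binary(self, name) -> int:
        return self.var(name, 0, 1, True)

    def con(self, expr: Expr, lb: float, ub: float, const: float = 0.0):
        self.rows.append((expr, lb - const, ub - const))

    def eq(self, expr: Expr, rhs: float, const: float = 0.0):
        self.con(expr, rhs, rhs, const)


@dataclass
class MILPInstance:
    """A formulated inversion instance plus its decoding recipe."""

    builder: _Builder
    spec: TargetSpec
    space: DescriptorSpace
    predictor: Predictor
    y_star: float
    epsilon: float
    decode_info: dict
    objective: Optional[np.ndarray] = None

    @property
    def num_variables(self) -> int:
        return len(self.builder.names)

    @property
    def num_constraints(self) -> int:
        return len(self.builder.rows)

    def to_scipy(self):
        b = self.builder
        nv = len(b.names)
        data, rows, cols, clb, cub = [], [], [], [], []
        for r, (expr, lo, hi) in enumerate(b.rows):
            for i, c in expr.items():
                rows.append(r)
                cols.append(i)
                data.append(c)
            clb.append(lo)
            cub.append(hi)
        A = csr_matrix((data, (rows, cols)), shape=(len(b.rows), nv))
        lc = LinearConstraint(A, clb, cub)
        c = self.objective if self.objective is not None else np.zeros(nv)
        return c, lc, np.array(b.integer, dtype=int), Bounds(b.lb, b.ub)

    def decode(self, x: np.ndarray) -> Plan:
        return _decode_plan(self, x)


@dataclass
class InferenceResult:
    status: str  # "feasible" | "infeasible" | "timeout"
    graph: Optional[ChemGraph] = None
    plan: Optional[Plan] = None
    feature_vector: Optional[np.ndarray] = None
    predicted: Optional[float] = None
    y_star: float = 0.0
    epsilon: float = 0.0
    solve_time: float = 0.0
    n_solves: int = 1
    verified: bool = False
    diagnostics: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Formulation
# ---------------------------------------------------------------------------


def formulate(
    spec: TargetSpec,
    predictor: Predictor,
    space: DescriptorSpace,
    y_star: float,
    epsilon: float = 0.0,
    objective: Optional[str] = None,
) -> MILPInstance:
    """Build the inversion MILP for a specification and a (reduced) model.

    ``space`` must be the descriptor space the predictor was trained or
    reduced against (``predictor.K == space.K``); the specification's
    candidate fringe codes and allowed edge-configurations must be encoded
    by the space.
    """
    if predictor.K != space.K:
        raise MILPError(f"predictor K={predictor.K} != space K={space.K}")
    seed, si, sce = spec.seed, spec.interior, spec.chemical
    table = spec.table
    rho = spec.rho
    if spec.rho != space.rho:
        raise MILPError("spec rho differs from space rho")

    space_codes = set(space.fringe_codes)
    bad = [c for c in sce.f_star() if c not in space_codes]
    if bad:
        raise MILPError("spec fringe codes absent from space: " + ", ".join(bad))
    gammas = tuple(space.gamma_int)
    if sce.gamma_int_allowed is not None:
        allowed = set(sce.gamma_int_allowed)
        bad_g = [gamma_text(g) for g in allowed - set(space.gamma_int)]
        if bad_g:
            raise MILPError("spec edge-configurations absent from space: " + ", ".join(bad_g))
        gammas = tuple(g for g in space.gamma_int if g in allowed)

    b = _Builder()
    one: Expr = {}  # empty expr + const handled via con(..., const=...)

    # ---- path lengths and vertex slots --------------------------------
    n_int_budget = si.n_int_ub - seed.n_vertices
    act: Dict[Tuple[str, int], int] = {}  # (edge id, slot k) -> var
    use: Dict[str, int] = {}
    length_expr: Dict[str, Tuple[Expr, float]] = {}  # expr, const
    direct_expr: Dict[str, Tuple[Expr, float]] = {}
    for e in seed.edges:
        lo, hi = _forced_length_range(e, si.eb(e.id), sce.n_star)
        hi = min(hi, n_int_budget + 1) if e.cls in ("ge1", "ge2") else hi
        if lo > hi:
            raise MILPError(f"edge {e.id}: empty length range [{lo},{hi}]")
        if e.cls == "eq1":
            length_expr[e.id] = ({}, 1.0)
            direct_expr[e.id] = ({}, 1.0)
        elif e.cls == "zero_one":
            u = b.binary(f"use[{e.id}]")
            if lo >= 1:
                b.lb[u] = 1
            if hi <= 0:
                b.ub[u] = 0
            use[e.id] = u
            length_expr[e.id] = ({u: 1.0}, 0.0)
            direct_expr[e.id] = ({u: 1.0}, 0.0)
        else:
            kmax = hi - 1
            for k in range(1, kmax + 1):
                act[(e.id, k)] = b.binary(f"act[{e.id},{k}]")
                if k <= lo - 1:
                    b.lb[act[(e.id, k)]] = 1  # force minimum length
                if k > 1:
                    b.con({act[(e.id, k - 1)]: 1, act[(e.id, k)]: -1}, 0, 1)
            length_expr[e.id] = (
                {act[(e.id, k)]: 1.0 for k in range(1, kmax + 1)},
                1.0,
            )
            if e.cls == "ge2":
                direct_expr[e.id] = ({}, 0.0)
            else:
                d = {act[(e.id, 1)]: -1.0} if kmax >= 1 else {}
                direct_expr[e.id] = (d, 1.0)

    # simple-graph rule: at most one length-1 realisation per vertex pair
    pair_edges: Dict[Tuple[int, int], List[str]] = {}
    for e in seed.edges:
        pair_edges.setdefault((min(e.u, e.v), max(e.u, e.v)), []).append(e.id)
    for pair, eids in pair_edges.items():
        if len(eids) > 1:
            expr = _add(*(direct_expr[i][0] for i in eids))
            const = sum(direct_expr[i][1] for i in eids)
            b.con(expr, -np.inf, 1, const=const)

    for c in si.side_constraints:
        expr: Expr = {}
        const = 0.0
        for eid, coef in c.coeffs.items():
            ex, cst = length_expr[eid]
            expr = _add(expr, _scale(ex, coef))
            const += coef * cst
        lo = c.rhs if c.sense in (">=", "==") else -np.inf
        hi = c.rhs if c.sense in ("<=", "==") else np.inf
        b.con(expr, lo, hi, const=const)

    # ---- leaf-path slots ----------------------------------------------
    lact: Dict[Tuple[str, int], int] = {}  # (anchor tag, j) -> var
    anchor_tags: List[Tuple[str, Optional[int], Optional[Tuple[str, int]]]] = []
    for i in range(seed.n_vertices):
        vb = si.vb(i)
        if vb.bl_ub >= 1 and vb.ch_ub >= 1:
            tag = f"v{i}"
            anchor_tags.append((tag, i, None))
            for j in range(1, vb.ch_ub + 1):
                lact[(tag, j)] = b.binary(f"lact[{tag},{j}]")
                if j > 1:
                    b.con({lact[(tag, j - 1)]: 1, lact[(tag, j)]: -1}, 0, 1)
            if vb.bl_lb >= 1:
                b.lb[lact[(tag, 1)]] = 1
                if vb.ch_lb >= 1:
                    b.lb[lact[(tag, min(vb.ch_lb, vb.ch_ub))]] = 1
            elif vb.ch_lb >= 1:
                # length >= ch_lb whenever the path exists
                b.con(
                    {lact[(tag, vb.ch_lb)]: 1, lact[(tag, 1)]: -1}, 0, 1
                )
    for e in seed.edges:
        eb = si.eb(e.id)
        if e.cls not in ("ge1", "ge2") or eb.bl_ub == 0 or eb.ch_ub == 0:
            continue
        kmax = len([1 for (eid, _) in act if eid == e.id])
        slots = []
        for k in range(1, kmax + 1):
            tag = f"p:{e.id}:{k}"
            anchor_tags.append((tag, None, (e.id, k)))
            for j in range(1, eb.ch_ub + 1):
                lact[(tag, j)] = b.binary(f"lact[{tag},{j}]")
                if j > 1:
                    b.con({lact[(tag, j - 1)]: 1, lact[(tag, j)]: -1}, 0, 1)
            b.con({lact[(tag, 1)]: 1, act[(e.id, k)]: -1}, -np.inf, 0)
            slots.append(tag)
        if slots:
            cnt = {lact[(t, 1)]: 1.0 for t in slots}
            b.con(cnt, eb.bl_lb, eb.bl_ub)
            if eb.ch_lb >= 1:
                for t in slots:
                    b.con(
                        _add({lact[(s, eb.ch_lb)]: 1.0 for s in slots}, {lact[(t, 1)]: -1.0}),
                        0,
                        np.inf,
                    )
        elif eb.bl_lb > 0:
            raise MILPError(f"edge {e.id}: bl_lb > 0 but no internal slots possible")

    # ---- vertex slot registry -----------------------------------------
    # key -> (active expr, active const, candidate seed vertex or None)
    vslots: Dict[str, Tuple[Expr, float, Optional[int]]] = {}
    for i in range(seed.n_vertices):
        vslots[seed_vertex_key(i)] = ({}, 1.0, i)
    for (eid, k), var in act.items():
        vslots[f"p:{eid}:{k}"] = ({var: 1.0}, 0.0, None)
    for (tag, j), var in lact.items():
        vslots[f"q:{tag}:{j}"] = ({var: 1.0}, 0.0, None)

    # ---- edge slot registry -------------------------------------------
    # key -> (active expr, const, endpoint vertex keys)
    eslots: Dict[str, Tuple[Expr, float, str, str]] = {}
    seed_edge_slots: Dict[str, List[str]] = {e.id: [] for e in seed.edges}
    for e in seed.edges:
        su, sv = seed_vertex_key(e.u), seed_vertex_key(e.v)
        if e.cls in ("eq1", "zero_one"):
            ex, cst = direct_expr[e.id]
            key = f"D:{e.id}"
            eslots[key] = (ex, cst, su, sv)
            seed_edge_slots[e.id].append(key)
            continue
        kmax = len([1 for (eid, _) in act if eid == e.id])
        ex, cst = direct_expr[e.id]
        if cst != 0.0 or ex:
            key = f"D:{e.id}"
            eslots[key] = (ex, cst, su, sv)
            seed_edge_slots[e.id].append(key)
        for k in range(0, kmax):
            # chain edge from node_k to node_{k+1}; active iff act[k+1]
            a = su if k == 0 else f"p:{e.id}:{k}"
            key = f"C:{e.id}:{k}"
            eslots[key] = ({act[(e.id, k + 1)]: 1.0}, 0.0, a, f"p:{e.id}:{k+1}")
            seed_edge_slots[e.id].append(key)
        for k in range(1, kmax + 1):
            # closing edge node_k -> v; active iff act[k] - act[k+1]
            ex2: Expr = {act[(e.id, k)]: 1.0}
            if (e.id, k + 1) in act:
                ex2[act[(e.id, k + 1)]] = -1.0
            key = f"Z:{e.id}:{k}"
            eslots[key] = (ex2, 0.0, f"p:{e.id}:{k}", sv)
            seed_edge_slots[e.id].append(key)
    for (tag, j), var in lact.items():
        if tag.startswith("v"):
            anchor_key = seed_vertex_key(int(tag[1:]))
        else:
            _, eid, k = tag.split(":")
            anchor_key = f"p:{eid}:{k}"
        a = anchor_key if j == 1 else f"q:{tag}:{j-1}"
        eslots[f"L:{tag}:{j}"] = ({var: 1.0}, 0.0, a, f"q:{tag}:{j}")

    # ---- fringe candidates and assignment binaries ---------------------
    trees = {c: space.fringe_trees[c] for c in space.fringe_codes}

    def candidate_codes(sv: Optional[int]) -> List[str]:
        out = []
        for code in sce.candidates(sv):
            t = trees.get(code)
            if t is None:
                continue
            if t.element not in sce.lambda_int_allowed:
                continue
            if t.element not in space.lambda_int:
                continue
            if sv is not None and sv in sce.lambda_star and t.element not in sce.lambda_star[sv]:
                continue
            if t.height > rho:
                continue
            ext = t.element_counts(include_root=False)
            if any(a not in space.lambda_ex for a in ext):
                continue
            out.append(code)
        return sorted(out)

    fr: Dict[Tuple[str, str], int] = {}
    vcands: Dict[str, List[str]] = {}
    for vk, (aex, acst, sv) in vslots.items():
        cands = candidate_codes(sv)
        if not cands and sv is not None:
            raise MILPError(f"seed vertex u{sv} has no usable fringe candidate")
        vcands[vk] = cands
        for code in cands:
            fr[(vk, code)] = b.binary(f"fr[{vk},{code}]")
        b.con(
            _add({fr[(vk, c)]: 1.0 for c in cands}, _scale(aex, -1.0)),
            acst, acst,
        )

    # ---- bond multiplicity binaries ------------------------------------
    bm: Dict[Tuple[str, int], int] = {}
    for ek, (aex, acst, _, _) in eslots.items():
        for m in (1, 2, 3):
            bm[(ek, m)] = b.binary(f"bm[{ek},{m}]")
        b.con(
            _add({bm[(ek, m)]: 1.0 for m in (1, 2, 3)}, _scale(aex, -1.0)),
            acst, acst,
        )

    def beta_expr(ek: str) -> Expr:
        return {bm[(ek, m)]: float(m) for m in (1, 2, 3)}

    # per-seed-edge double/triple bond counts
    for e in seed.edges:
        eb = si.eb(e.id)
        for m, lb_, ub_ in ((2, eb.bd2_lb, eb.bd2_ub), (3, eb.bd3_lb, eb.bd3_ub)):
            ub_eff = sce.n_star if ub_ is None else ub_
            expr = {bm[(ek, m)]: 1.0 for ek in seed_edge_slots[e.id]}
            b.con(expr, lb_, ub_eff)

    # ---- degrees, valence, symbols -------------------------------------
    incident: Dict[str, List[str]] = {vk: [] for vk in vslots}
    for ek, (_, _, a, c) in eslots.items():
        incident[a].append(ek)
        incident[c].append(ek)

    def int_deg_expr(vk: str) -> Tuple[Expr, float]:
        ex: Expr = {}
        cst = 0.0
        for ek in incident[vk]:
            aex, acst, _, _ = eslots[ek]
            ex = _add(ex, aex)
            cst += acst
        return ex, cst

    n_v = seed.n_vertices
    tdg: Dict[Tuple[str, int], int] = {}
    idg: Dict[Tuple[str, int], int] = {}
    hyi: Dict[Tuple[str, int], int] = {}
    cs_var: Dict[Tuple[str, Tuple[str, int]], int] = {}
    connected_min_deg = 1 if (n_v >= 2 or any(si.vb(0).bl_ub >= 1 for _ in [0])) else 0
    for vk, (aex, acst, sv) in vslots.items():
        dex, dcst = int_deg_expr(vk)
        rootdeg = {c: trees[c].root_degree for c in vcands[vk]}
        total_deg = _add(
            dex, {fr[(vk, c)]: float(rootdeg[c]) for c in vcands[vk]}
        )
        for d in range(0, 5):
            tdg[(vk, d)] = b.binary(f"tdg[{vk},{d}]")
            idg[(vk, d)] = b.binary(f"idg[{vk},{d}]")
        b.con({tdg[(vk, d)]: 1.0 for d in range(5)}, 1, 1)
        b.con({idg[(vk, d)]: 1.0 for d in range(5)}, 1, 1)
        b.con(
            _add({tdg[(vk, d)]: float(d) for d in range(5)}, _scale(total_deg, -1.0)),
            dcst, dcst,
        )
        b.con(
            _add({idg[(vk, d)]: float(d) for d in range(5)}, _scale(dex, -1.0)),
            dcst, dcst,
        )
        # an active vertex of a connected molecule with >=2 atoms has a bond
        if sce.n_lb >= 2:
            b.con(_add({tdg[(vk, 0)]: 1.0}, aex), -np.inf, 1 - acst)
        # interior leaves carry fringe trees of height exactly rho
        off_height = [c for c in vcands[vk] if trees[c].height != rho]
        if n_v >= 2 or len(vslots) > 1:
            if off_height:
                b.con(
                    _add({fr[(vk, c)]: 1.0 for c in off_height}, {idg[(vk, 1)]: 1.0}),
                    -np.inf, 1,
                )
        # valence: sum of interior bond multiplicities <= residual valence
        res = {
            c: table.valence(trees[c].element) - trees[c].root_beta_sum
            for c in vcands[vk]
        }
        bsum: Expr = {}
        for ek in incident[vk]:
            bsum = _add(bsum, beta_expr(ek))
        b.con(
            _add(bsum, {fr[(vk, c)]: -float(res[c]) for c in vcands[vk]}),
            -np.inf, 0,
        )
        # hydrogen degree of the root
        for d in range(0, 4):
            hyi[(vk, d)] = b.binary(f"hyi[{vk},{d}]")
        b.con(
            _add({hyi[(vk, d)]: 1.0 for d in range(4)}, _scale(aex, -1.0)),
            acst, acst,
        )
        b.con(
            _add(
                {hyi[(vk, d)]: float(d) for d in range(4)},
                {fr[(vk, c)]: -float(res[c]) for c in vcands[vk]},
                bsum,
            ),
            0, 0,
        )
        # chemical symbols via AND of element indicator and degree indicator
        elems = sorted({trees[c].element for c in vcands[vk]})
        for a in elems:
            eind = {fr[(vk, c)]: 1.0 for c in vcands[vk] if trees[c].element == a}
            for d in range(1, 5):
                mu = (a, d)
                v = b.binary(f"cs[{vk},{a}{d}]")
                cs_var[(vk, mu)] = v
                b.con(_add({v: 1.0}, _scale(eind, -1.0)), -np.inf, 0)
                b.con({v: 1.0, tdg[(vk, d)]: -1.0}, -np.inf, 0)
                b.con(
                    _add({v: -1.0}, eind, {tdg[(vk, d)]: 1.0}), -np.inf, 1
                )
        b.con(
            _add(
                {cs_var[(vk, mu)]: 1.0 for mu in list({(a, d) for a in elems for d in range(1, 5)})},
                _scale(aex, -1.0),
            ),
            acst, acst,
        )

    # chemical-symbol frequency bounds (ns)
    all_mu = sorted({mu for (_, mu) in cs_var}, key=lambda mu: (mu[0], mu[1]))
    for mu in all_mu:
        expr = {v: 1.0 for (vk, m), v in cs_var.items() if m == mu}
        lb_ = sce.ns_int_lb.get(mu, 0)
        ub_ = sce.ns_int_ub.get(mu, sce.n_star)
        b.con(expr, lb_, ub_)
    for mu, lb_ in sce.ns_int_lb.items():
        if mu not in all_mu and lb_ > 0:
            raise MILPError(f"ns lower bound on unrealisable symbol {mu}")

    # ---- edge-configuration indicators ---------------------------------
    ecv: Dict[Tuple[str, int], int] = {}
    for ek, (aex, acst, vk1, vk2) in eslots.items():
        for gi, (mu, xi, m) in enumerate(gammas):
            v = b.binary(f"ec[{ek},{gi}]")
            ecv[(ek, gi)] = v
            pairs = [(mu, xi)] if mu == xi else [(mu, xi), (xi, mu)]
            for (p, q) in pairs:
                if (vk1, p) in cs_var and (vk2, q) in cs_var:
                    # the true configuration of an active edge forces its
                    # indicator on (>= side)
                    b.con(
                        {
                            v: -1.0,
                            cs_var[(vk1, p)]: 1.0,
                            cs_var[(vk2, q)]: 1.0,
                            bm[(ek, m)]: 1.0,
                        },
                        -np.inf, 2,
                    )
            # indicators can only be on when the edge genuinely matches:
            # each endpoint carries mu or xi, and the multiplicity is m
            side1 = {
                cs_var[(vk1, s)]: 1.0
                for s in {mu, xi}
                if (vk1, s) in cs_var
            }
            side2 = {
                cs_var[(vk2, s)]: 1.0
                for s in {mu, xi}
                if (vk2, s) in cs_var
            }
            b.con(_add({v: 1.0}, _scale(side1, -1.0)), -np.inf, 0)
            b.con(_add({v: 1.0}, _scale(side2, -1.0)), -np.inf, 0)
            b.con({v: 1.0, bm[(ek, m)]: -1.0}, -np.inf, 0)
        # forbid configurations outside the allowed set outright
        sym1 = sorted({s for (w, s) in cs_var if w == vk1})
        sym2 = sorted({s for (w, s) in cs_var if w == vk2})
        allowed_set = set(gammas)
        for p in sym1:
            for q in sym2:
                canon = (p, q) if _symkey(table, p) <= _symkey(table, q) else (q, p)
                for m in (1, 2, 3):
                    if (canon[0], canon[1], m) in allowed_set:
                        continue
                    b.con(
                        {
                            cs_var[(vk1, p)]: 1.0,
                            cs_var[(vk2, q)]: 1.0,
                            bm[(ek, m)]: 1.0,
                        },
                        -np.inf, 2,
                    )
        b.con(
            _add({ecv[(ek, gi)]: 1.0 for gi in range(len(gammas))}, _scale(aex, -1.0)),
            acst, acst,
        )

    ec_count: List[Expr] = []
    for gi in range(len(gammas)):
        ec_count.append({v: 1.0 for (ek, g), v in ecv.items() if g == gi})
        g = gammas[gi]
        b.con(
            ec_count[gi],
            sce.ec_int_lb.get(g, 0),
            sce.ec_int_ub.get(g, sce.n_star),
        )
    for g, lb_ in sce.ec_int_lb.items():
        if g not in gammas and lb_ > 0:
            raise MILPError(f"ec lower bound on disallowed configuration {gamma_text(g)}")

    # adjacency-configuration bounds derived from ec counts
    from .descriptors import ac_of_gamma

    ac_groups: Dict[Tuple[str, str, int], Expr] = {}
    for gi, g in enumerate(gammas):
        nu = ac_of_gamma(g, table)
        ac_groups[nu] = _add(ac_groups.get(nu, {}), ec_count[gi])
    for nu, expr in ac_groups.items():
        b.con(expr, sce.ac_int_lb.get(nu, 0), sce.ac_int_ub.get(nu, sce.n_star))
    for nu, lb_ in sce.ac_int_lb.items():
        if nu not in ac_groups and lb_ > 0:
            raise MILPError(f"ac lower bound on disallowed configuration {nu}")

    # ---- element counts and size ---------------------------------------
    def na_int_expr(a: str) -> Expr:
        return {
            fr[(vk, c)]: 1.0
            for vk in vslots
            for c in vcands[vk]
            if trees[c].element == a
        }

    def na_ex_expr(a: str) -> Expr:
        out: Expr = {}
        for vk in vslots:
            for c in vcands[vk]:
                cnt = trees[c].element_counts(include_root=False).get(a, 0)
                if cnt:
                    out[fr[(vk, c)]] = out.get(fr[(vk, c)], 0.0) + cnt
        return out

    elements = sorted(set(space.lambda_int) | set(space.lambda_ex), key=table.order_index)
    for a in elements:
        nai = na_int_expr(a)
        nae = na_ex_expr(a)
        b.con(nai, sce.na_int_lb.get(a, 0), sce.na_int_ub.get(a, sce.n_star))
        b.con(_add(nai, nae), sce.na_lb.get(a, 0), sce.na_ub.get(a, sce.n_star))

    n_expr = {
        fr[(vk, c)]: float(trees[c].size) for vk in vslots for c in vcands[vk]
    }
    b.con(n_expr, sce.n_lb, sce.n_star)
    n_int_expr: Expr = {}
    n_int_const = 0.0
    for vk, (aex, acst, _) in vslots.items():
        n_int_expr = _add(n_int_expr, aex)
        n_int_const += acst
    b.con(n_int_expr, si.n_int_lb - n_int_const, si.n_int_ub - n_int_const)

    # ---- descriptor variables x ----------------------------------------
    max_eint = len(eslots)
    mass_vals = [table.mass10(a) for a in elements]
    x_lo = np.zeros(space.K)
    x_hi = np.zeros(space.K)
    x_idx: List[int] = []

    def x_var(i, name, lo, hi, integer=True):
        v = b.var(f"x[{name}]", lo, hi, integer)
        x_idx.append(v)
        x_lo[i], x_hi[i] = lo, hi
        return v

    names = space.slot_names()
    xv_n = x_var(0, names[0], sce.n_lb, sce.n_star)
    b.con(_add(n_expr, {xv_n: -1.0}), 0, 0)
    xv_nint = x_var(1, names[1], si.n_int_lb, si.n_int_ub)
    b.con(_add(n_int_expr, {xv_nint: -1.0}), -n_int_const, -n_int_const)
    xv_ms = x_var(2, names[2], min(mass_vals), max(mass_vals), integer=False)
    mass_expr = {
        fr[(vk, c)]: float(trees[c].mass_sum(table))
        for vk in vslots
        for c in vcands[vk]
    }
    big_m = sce.n_star * max(mass_vals) + 10.0
    nn = {}
    for k in range(sce.n_lb, sce.n_star + 1):
        nn[k] = b.binary(f"nn[{k}]")
        b.con(
            _add({xv_ms: float(k)}, _scale(mass_expr, -1.0), {nn[k]: big_m}),
            -np.inf, big_m,
        )
        b.con(
            _add({xv_ms: float(k)}, _scale(mass_expr, -1.0), {nn[k]: -big_m}),
            -big_m, np.inf,
        )
    b.con({v: 1.0 for v in nn.values()}, 1, 1)
    b.con(_add({nn[k]: float(k) for k in nn}, _scale(n_expr, -1.0)), 0, 0)

    for d in range(1, 5):
        v = x_var(3 + d - 1, names[3 + d - 1], 0, si.n_int_ub)
        b.con(_add({tdg[(vk, d)]: 1.0 for vk in vslots}, {v: -1.0}), 0, 0)
    for d in range(1, 5):
        v = x_var(7 + d - 1, names[7 + d - 1], 0, si.n_int_ub)
        b.con(_add({idg[(vk, d)]: 1.0 for vk in vslots}, {v: -1.0}), 0, 0)
    for d in range(0, 4):
        v = x_var(11 + d, names[11 + d], 0, sce.n_star)
        expr = {hyi[(vk, d)]: 1.0 for vk in vslots}
        hist_expr: Expr = {}
        for vk in vslots:
            for c in vcands[vk]:
                cnt = trees[c].non_root_hyd_histogram(table).get(d, 0)
                if cnt:
                    hist_expr[fr[(vk, c)]] = hist_expr.get(fr[(vk, c)], 0.0) + cnt
        b.con(_add(expr, hist_expr, {v: -1.0}), 0, 0)
    for m in (2, 3):
        v = x_var(15 + m - 2, names[15 + m - 2], 0, max_eint)
        b.con(_add({bm[(ek, m)]: 1.0 for ek in eslots}, {v: -1.0}), 0, 0)
    for i, a in enumerate(space.lambda_int):
        v = x_var(space.na_int_offset + i, names[space.na_int_offset + i], 0, si.n_int_ub)
        b.con(_add(na_int_expr(a), {v: -1.0}), 0, 0)
    for i, a in enumerate(space.lambda_ex):
        v = x_var(space.na_ex_offset + i, names[space.na_ex_offset + i], 0, sce.n_star)
        b.con(_add(na_ex_expr(a), {v: -1.0}), 0, 0)
    gamma_pos = {g: i for i, g in enumerate(space.gamma_int)}
    used_gamma = set(gammas)
    for g, i in gamma_pos.items():
        if g in used_gamma:
            gi = gammas.index(g)
            v = x_var(space.ec_offset + i, names[space.ec_offset + i], 0, max_eint)
            b.con(_add(ec_count[gi], {v: -1.0}), 0, 0)
        else:
            x_var(space.ec_offset + i, names[space.ec_offset + i], 0, 0)
    for i, code in enumerate(space.fringe_codes):
        expr = {
            fr[(vk, code)]: 1.0 for vk in vslots if code in vcands[vk]
        }
        if expr:
            v = x_var(space.fc_offset + i, names[space.fc_offset + i], 0, si.n_int_ub)
            b.con(_add(expr, {v: -1.0}), 0, 0)
        else:
            x_var(space.fc_offset + i, names[space.fc_offset + i], 0, 0)

    # ---- ReLU forward pass ---------------------------------------------
    h_prev = [{x_idx[i]: 1.0} for i in range(space.K)]
    lo_prev, hi_prev = x_lo.copy(), x_hi.copy()
    for li, (W, bias) in enumerate(zip(predictor.weights, predictor.biases)):
        is_out = li == len(predictor.weights) - 1
        width = W.shape[1]
        h_new, lo_new, hi_new = [], np.zeros(width), np.zeros(width)
        for j in range(width):
            z_expr: Expr = {}
            for i in range(W.shape[0]):
                if W[i, j] != 0.0:
                    z_expr = _add(z_expr, _scale(h_prev[i], W[i, j]))
            z_const = float(bias[j])
            z_lo = z_const + sum(
                min(W[i, j] * lo_prev[i], W[i, j] * hi_prev[i]) for i in range(W.shape[0])
            )
            z_hi = z_const + sum(
                max(W[i, j] * lo_prev[i], W[i, j] * hi_prev[i]) for i in range(W.shape[0])
            )
            if is_out:
                yv = b.var("y_out", z_lo, z_hi, integer=False)
                b.con(_add(z_expr, {yv: -1.0}), -z_const, -z_const)
                h_new.append({yv: 1.0})
                lo_new[j], hi_new[j] = z_lo, z_hi
                continue
            hv = b.var(f"h[{li},{j}]", 0, max(0.0, z_hi), integer=False)
            if z_hi <= 0:
                b.ub[hv] = 0.0
            elif z_lo >= 0:
                b.con(_add(z_expr, {hv: -1.0}), -z_const, -z_const)
            else:
                sv_ = b.binary(f"s[{li},{j}]")
                # h >= z
                b.con(_add({hv: 1.0}, _scale(z_expr, -1.0)), z_const, np.inf)
                # h <= z - z_lo (1 - s):  h - z_expr - z_lo s <= z_const - z_lo
                b.con(
                    _add({hv: 1.0}, _scale(z_expr, -1.0), {sv_: -z_lo}),
                    -np.inf, z_const - z_lo,
                )
                # h <= z_hi * s
                b.con({hv: 1.0, sv_: -z_hi}, -np.inf, 0)
            h_new.append({hv: 1.0})
            lo_new[j], hi_new[j] = max(0.0, z_lo), max(0.0, z_hi)
        h_prev, lo_prev, hi_prev = h_new, lo_new, hi_new

    y_var = next(iter(h_prev[0]))
    b.con({y_var: 1.0}, y_star - epsilon, y_star + epsilon)

    obj = None
    if objective == "min_n":
        obj = np.zeros(len(b.names))
        for i, c in n_expr.items():
            obj[i] = c

    decode_info = {
        "act": act,
        "use": use,
        "lact": lact,
        "fr": fr,
        "bm": bm,
        "eslots": {k: (vk1, vk2) for k, (_, _, vk1, vk2) in eslots.items()},
        "x_idx": x_idx,
        "y_var": y_var,
    }
    return MILPInstance(b, spec, space, predictor, y_star, epsilon, decode_info, obj)


# ---------------------------------------------------------------------------
# Decoding and solving
# ---------------------------------------------------------------------------


def _decode_plan(inst: MILPInstance, x: np.ndarray) -> Plan:
    info = inst.decode_info
    spec = inst.spec
    seed = spec.seed

    def val(i):
        return int(round(x[i]))

    lengths: Dict[str, int] = {}
    for e in seed.edges:
        if e.cls == "eq1":
            lengths[e.id] = 1
        elif e.cls == "zero_one":
            lengths[e.id] = val(info["use"][e.id])
        else:
            lengths[e.id] = 1 + sum(
                val(v) for (eid, _), v in info["act"].items() if eid == e.id
            )
    leaf_vertex: Dict[int, int] = {}
    leaf_path: Dict[Tuple[str, int], int] = {}
    for (tag, j), v in info["lact"].items():
        if val(v) == 0:
            continue
        if tag.startswith("v"):
            i = int(tag[1:])
            leaf_vertex[i] = max(leaf_vertex.get(i, 0), j)
        else:
            _, eid, k = tag.split(":")
            key = (eid, int(k))
            leaf_path[key] = max(leaf_path.get(key, 0), j)

    fringe: Dict[str, str] = {}
    for (vk, code), v in info["fr"].items():
        if val(v) == 1:
            fringe[vk] = code

    # map MILP edge slots to plan bond keys given the decoded lengths
    bonds: Dict[str, int] = {}

    def slot_m(ek):
        return sum(m for m in (1, 2, 3) if val(info["bm"][(ek, m)]) == 1)

    for e in seed.edges:
        l = lengths[e.id]
        if l == 0:
            continue
        if e.cls in ("eq1", "zero_one"):
            bonds[f"e:{e.id}:0"] = slot_m(f"D:{e.id}")
            continue
        if l == 1:
            bonds[f"e:{e.id}:0"] = slot_m(f"D:{e.id}")
            continue
        for k in range(0, l - 1):
            bonds[f"e:{e.id}:{k}"] = slot_m(f"C:{e.id}:{k}")
        bonds[f"e:{e.id}:{l-1}"] = slot_m(f"Z:{e.id}:{l-1}")
    for (tag, j), v in info["lact"].items():
        if val(v) == 1:
            bonds[f"qe:{tag}:{j-1}"] = slot_m(f"L:{tag}:{j}")

    return Plan(lengths, leaf_vertex, leaf_path, fringe, bonds)


def solve_inverse(
    instance: MILPInstance,
    time_limit: Optional[float] = None,
    max_cut_rounds: int = 20,
) -> InferenceResult:
    """Solve an inversion instance and decode/verify the incumbent.

    Dropped optional seed edges can in principle disconnect the interior;
    disconnected decodes are excluded with no-good cuts and the instance is
    re-solved, which terminates after at most 2^|E(0/1)| rounds.
    """
    t0 = time.time()
    result = InferenceResult(
        status="infeasible", y_star=instance.y_star, epsilon=instance.epsilon
    )
    for round_ in range(max_cut_rounds + 1):
        c, lc, integrality, bounds = instance.to_scipy()
        options = {}
        if time_limit is not None:
            remaining = time_limit - (time.time() - t0)
            if remaining <= 0:
                result.status = "timeout"
                break
            options["time_limit"] = remaining
        res = milp(
            c, constraints=[lc], integrality=integrality, bounds=bounds,
            options=options,
        )
        result.n_solves = round_ + 1
        if res.status == 1:  # iteration/time limit
            result.status = "timeout"
            break
        if res.status != 0 or res.x is None:
            result.status = "infeasible"
            break
        plan = instance.decode(res.x)
        try:
            G, _ = build_graph(plan, instance.spec)
        except DisconnectedError:
            dropped = [
                eid for eid, v in instance.decode_info["use"].items()
                if int(round(res.x[v])) == 0
            ]
            if not dropped:
                raise MILPError("disconnected decode without optional edges")
            instance.builder.con(
                {instance.decode_info["use"][eid]: 1.0 for eid in dropped},
                1, np.inf,
            )
            continue
        result.status = "feasible"
        result.graph = G
        result.plan = plan
        result.feature_vector = np.array(
            [res.x[i] for i in instance.decode_info["x_idx"]]
        )
        result.predicted = float(res.x[instance.decode_info["y_var"]])
        break
    result.solve_time = time.time() - t0
    if result.status == "feasible":
        result.verified = verify_inference(
            result, instance.predictor, instance.space, instance.spec
        )
    return result


def verify_inference(
    result: InferenceResult,
    predictor: Predictor,
    space: DescriptorSpace,
    spec: TargetSpec,
    tol: float = 1e-6,
) -> bool:
    """Re-derive everything about a feasible result from scratch.

    Checks specification validity, equality of the decoded graph's
    descriptor vector with the MILP's, and that the recomputed network
    output hits the target window.  Appends a diagnosis per failure.
    """
    if result.status != "feasible" or result.graph is None:
        result.diagnostics.append("result is not feasible")
        return False
    ok = True
    rep = validate_extension(result.graph, spec)
    if not rep.is_extension:
        result.diagnostics.append(f"spec violations: {rep.violations[:5]}")
        ok = False
    try:
        x = feature_vector(result.graph, space)
    except ChemGraphError as exc:
        result.diagnostics.append(f"feature vector: {exc}")
        return False
    if result.feature_vector is not None:
        ints = np.ones(space.K, dtype=bool)
        ints[2] = False
        if not np.array_equal(
            np.round(x[ints]).astype(int),
            np.round(result.feature_vector[ints]).astype(int),
        ):
            bad = [
                space.slot_names()[i]
                for i in np.nonzero(
                    np.round(x) != np.round(result.feature_vector)
                )[0]
                if i != 2
            ]
            result.diagnostics.append(f"descriptor mismatch: {bad[:8]}")
            ok = False
        # the solver's continuous mass-average copy is only as tight as the
        # LP feasibility tolerance; the exact value is pinned by the
        # integer element counts, which are compared exactly above
        if abs(x[2] - result.feature_vector[2]) > 1e-5:
            result.diagnostics.append("ms_avg mismatch")
            ok = False
    eta = predictor.predict(x)
    if abs(eta - result.y_star) > result.epsilon + tol:
        result.diagnostics.append(
            f"|eta - y*| = {abs(eta - result.y_star):.3g} > eps + {tol}"
        )
        ok = False
    return ok


def encode_forward_pass(predictor: Predictor, fixed_x: Sequence[float]) -> float:
    """Evaluate the network via its MILP encoding with the inputs fixed.

    Used to certify that the big-M ReLU constraints determine the forward
    pass exactly; agrees with :meth:`Predictor.predict` to ~1e-6.
    """
    x = np.asarray(fixed_x, dtype=float)
    if x.shape != (predictor.K,):
        raise MILPError("input length mismatch")
    b = _Builder()
    xv = [b.var(f"x[{i}]", x[i], x[i], integer=False) for i in range(predictor.K)]
    h_prev = [{v: 1.0} for v in xv]
    # widen the propagation box so the big-M branching constraints, not
    # degenerate bound fixing, determine every activation
    lo_prev = x - 10.0
    hi_prev = x + 10.0
    y_var = None
    for li, (W, bias) in enumerate(zip(predictor.weights, predictor.biases)):
        is_out = li == len(predictor.weights) - 1
        h_new, lo_new, hi_new = [], [], []
        for j in range(W.shape[1]):
            z_expr: Expr = {}
            for i in range(W.shape[0]):
                if W[i, j] != 0.0:
                    z_expr = _add(z_expr, _scale(h_prev[i], W[i, j]))
            z_const = float(bias[j])
            z_lo = z_const + sum(min(W[i, j] * lo_prev[i], W[i, j] * hi_prev[i]) for i in range(W.shape[0]))
            z_hi = z_const + sum(max(W[i, j] * lo_prev[i], W[i, j] * hi_prev[i]) for i in range(W.shape[0]))
            if is_out:
                yv = b.var("y", z_lo - 1, z_hi + 1, integer=False)
                b.con(_add(z_expr, {yv: -1.0}), -z_const, -z_const)
                y_var = yv
                h_new.append({yv: 1.0})
                lo_new.append(z_lo)
                hi_new.append(z_hi)
                continue
            hv = b.var(f"h[{li},{j}]", 0, max(0.0, z_hi), integer=False)
            if z_hi <= 0:
                b.ub[hv] = 0.0
            elif z_lo >= 0:
                b.con(_add(z_expr, {hv: -1.0}), -z_const, -z_const)
            else:
                sv_ = b.binary(f"s[{li},{j}]")
                b.con(_add({hv: 1.0}, _scale(z_expr, -1.0)), z_const, np.inf)
                b.con(
                    _add({hv: 1.0}, _scale(z_expr, -1.0), {sv_: -z_lo}),
                    -np.inf, z_const - z_lo,
                )
                b.con({hv: 1.0, sv_: -z_hi}, -np.inf, 0)
            h_new.append({hv: 1.0})
            lo_new.append(max(0.0, z_lo))
            hi_new.append(max(0.0, z_hi))
        h_prev, lo_prev, hi_prev = h_new, np.array(lo_new), np.array(hi_new)

    inst = _solve_builder(b)
    return float(inst[y_var])


def _solve_builder(b: _Builder) -> np.ndarray:
    nv = len(b.names)
    data, rows, cols, clb, cub = [], [], [], [], []
    for r, (expr, lo, hi) in enumerate(b.rows):
        for i, c in expr.items():
            rows.append(r)
            cols.append(i)
            data.append(c)
        clb.append(lo)
        cub.append(hi)
    A = csr_matrix((data, (rows, cols)), shape=(len(b.rows), nv))
    res = milp(
        np.zeros(nv),
        constraints=[LinearConstraint(A, clb, cub)],
        integrality=np.array(b.integer, dtype=int),
        bounds=Bounds(b.lb, b.ub),
    )
    if res.status != 0 or res.x is None:
        raise MILPError(f"forward-pass MILP not solved: {res.message}")
    return res.x


def feasibility_scan(
    spec: TargetSpec,
    predictor: Predictor,
    space: DescriptorSpace,
    y_grid: Sequence[float],
    epsilon: float = 0.0,
    time_limit: Optional[float] = None,
) -> List[Tuple[float, str]]:
    """Feasibility status of the inversion MILP over a grid of targets.

    The observed feasible range endpoints among the grid estimate the
    attainable property interval of the specification under the model.
    """
    out = []
    for y in y_grid:
        inst = formulate(spec, predictor, space, y, epsilon)
        res = solve_inverse(inst, time_limit=time_limit)
        out.append((float(y), res.status))
    return out


def feasible_range(scan: List[Tuple[float, str]]) -> Optional[Tuple[float, float]]:
    ys = [y for y, s in scan if s == "feasible"]
    if not ys:
        return None
    return (min(ys), max(ys))
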