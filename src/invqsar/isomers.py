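"""Chemical isomers of an inferred graph (Stage 5).

Given an inferred graph G-dagger, its *chemical isomers* are the other
specification-conforming graphs with the identical feature vector.  At the
fixed interior topology of G-dagger these arise from reassigning fringe
trees over the interior vertices (the fringe-code multiset is pinned by the
fc descriptors) and from permuting bond multiplicities over interior edges
(pinned by the ec descriptors).  Enumeration explores exactly this
assignment space, filters on feature-vector equality, deduplicates up to
isomorphism, and truncates at a configurable cap.

The lower-bound count collapses interchangeable assignment sites: interior
vertices are grouped by interior degree and root signature (element, root
degree, root bond sum), and the count is the number of ways to distribute
the fixed code multiset over the groups, each group restricted to codes
admissible at *every* one of its sites.  Distinct distributions cannot be
related by a graph automorphism, so the count never exceeds the true number
of isomers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._canon import graph_invariant, is_isomorphic
from .chemgraph import ChemGraph, ChemGraphError
from .descriptors import DescriptorSpace, RootedTree, feature_vector
from .specification import (
    Plan,
    TargetSpec,
    _recover_plans,
    build_graph,
    check_plan,
    interior_degrees,
    interior_layout,
)


class IsomerError(ChemGraphError):
    pass


@dataclass
class IsomerEnumeration:
    lower_bound: int
    graphs: List[ChemGraph]
    exhausted: bool
    explored: int = 0


def _conforming_plan(g_dagger: ChemGraph, spec: TargetSpec) -> Plan:
    """First recovered construction plan that satisfies every bound."""
    last = None
    for plan in _recover_plans(g_dagger, spec):
        _, rep = check_plan(plan, spec)
        if rep.is_extension:
            return plan
        last = rep
    if last is None:
        raise IsomerError("graph does not match the specification's seed structure")
    raise IsomerError(f"graph violates the specification: {last.violations[:3]}")


def _position_candidates(
    plan: Plan, spec: TargetSpec, space: DescriptorSpace
) -> Tuple[List[str], Dict[str, List[str]], Dict[str, int]]:
    """Interior vertex keys, their admissible fringe codes, and degrees."""
    vkeys, ekeys = interior_layout(
        spec.seed, plan.lengths, plan.leaf_vertex, plan.leaf_path
    )
    deg = interior_degrees(vkeys, ekeys)
    sce = spec.chemical
    space_codes = set(space.fringe_codes)
    cands: Dict[str, List[str]] = {}
    for k in vkeys:
        sv = int(k[1:]) if k.startswith("s") else None
        out = []
        for code in sce.candidates(sv):
            if code not in space_codes:
                continue
            t = space.fringe_trees[code]
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
                continue
            out.append(code)
        cands[k] = sorted(out)
    return vkeys, cands, deg


def enumerate_isomers(
    g_dagger: ChemGraph,
    spec: TargetSpec,
    space: DescriptorSpace,
    limit: int = 100,
) -> IsomerEnumeration:
    """Enumerate the feature-preserving class of ``g_dagger``.

    Searches all assignments of the (fixed) fringe-code multiset to the
    interior vertices and all bond reassignments at the fixed interior
    topology, keeps those whose feature vector equals ``f(g_dagger)`` and
    that validate against the specification, and deduplicates up to
    isomorphism.  Deterministic output order; at most ``limit`` graphs.
    """
    if limit < 1:
        raise IsomerError("limit must be >= 1")
    plan0 = _conforming_plan(g_dagger, spec)
    target = feature_vector(g_dagger, space)

    vkeys, cands, deg = _position_candidates(plan0, spec, space)
    multiset = Counter(plan0.fringe[k] for k in vkeys)
    ekeys_full = interior_layout(
        spec.seed, plan0.lengths, plan0.leaf_vertex, plan0.leaf_path
    )[1]
    bond_keys = [ek for ek, _, _ in ekeys_full]
    bond_multiset = Counter(plan0.bonds[ek] for ek in bond_keys)

    found: List[Tuple[str, ChemGraph]] = []
    exhausted = True
    explored = 0
    order = sorted(vkeys, key=lambda k: len(cands[k]))

    def assign_fringe(i: int, remaining: Counter, acc: Dict[str, str]):
        nonlocal exhausted, explored
        if not exhausted:
            return
        if i == len(order):
            yield dict(acc)
            return
        k = order[i]
        for code in cands[k]:
            if remaining[code] <= 0:
                continue
            remaining[code] -= 1
            acc[k] = code
            yield from assign_fringe(i + 1, remaining, acc)
            del acc[k]
            remaining[code] += 1

    def bond_assignments(i: int, remaining: Counter, caps: Dict[str, int], acc):
        """Permutations of the fixed bond multiset over the interior edges,
        respecting per-vertex residual valence."""
        if i == len(bond_keys):
            yield dict(acc)
            return
        ek = bond_keys[i]
        a, bkey = _ends[ek]
        for m in sorted(set(remaining)):
            if remaining[m] <= 0:
                continue
            if caps[a] - m < _rem_after[i][a] or caps[bkey] - m < _rem_after[i][bkey]:
                continue
            remaining[m] -= 1
            caps[a] -= m
            caps[bkey] -= m
            acc[ek] = m
            yield from bond_assignments(i + 1, remaining, caps, acc)
            del acc[ek]
            caps[a] += m
            caps[bkey] += m
            remaining[m] += 1

    _ends = {ek: (a, b) for ek, a, b in ekeys_full}
    # minimal residual multiplicity still to be placed at each vertex
    _rem_after: List[Dict[str, int]] = []
    for i in range(len(bond_keys)):
        d: Dict[str, int] = {k: 0 for k in vkeys}
        for ek in bond_keys[i + 1 :]:
            a, bkey = _ends[ek]
            d[a] += 1
            d[bkey] += 1
        _rem_after.append(d)

    seen: Dict[str, List[ChemGraph]] = {}
    for fringe in assign_fringe(0, Counter(multiset), {}):
        caps = {
            k: spec.table.valence(space.fringe_trees[fringe[k]].element)
            - space.fringe_trees[fringe[k]].root_beta_sum
            for k in vkeys
        }
        for bonds in bond_assignments(0, Counter(bond_multiset), dict(caps), {}):
            explored += 1
            plan = Plan(
                dict(plan0.lengths),
                dict(plan0.leaf_vertex),
                dict(plan0.leaf_path),
                fringe,
                bonds,
            )
            G, rep = check_plan(plan, spec)
            if G is None or not rep.is_extension:
                continue
            try:
                x = feature_vector(G, space)
            except ChemGraphError:
                continue  # uses a configuration outside the space

            if not np.array_equal(
                np.round(x[3:]).astype(int), np.round(target[3:]).astype(int)
            ) or abs(x[2] - target[2]) > 1e-9 or x[0] != target[0] or x[1] != target[1]:
                continue
            inv = graph_invariant(G)
            bucket = seen.setdefault(inv, [])
            if any(is_isomorphic(G, h) for h in bucket):
                continue
            bucket.append(G)
            found.append((inv, G))
            if len(found) >= limit:
                exhausted = False
                break
        if not exhausted:
            break

    found.sort(key=lambda t: t[0])
    graphs = [g for _, g in found]
    if exhausted:
        lb = len(graphs)
    else:
        lb = max(count_lower_bound(g_dagger, spec, space), len(graphs))
    return IsomerEnumeration(lb, graphs, exhausted, explored)


def count_lower_bound(
    g_dagger: ChemGraph, spec: TargetSpec, space: DescriptorSpace
) -> int:
    """Count feature-preserving fringe redistributions without building them.

    Groups interior vertices by (interior degree, root signature); within a
    signature the code multiset may be split among the groups in any way
    admissible at every site of each group.  Distinct splits give
    non-isomorphic graphs, so the count is a lower bound (at least 1).
    """
    plan0 = _conforming_plan(g_dagger, spec)
    vkeys, cands, deg = _position_candidates(plan0, spec, space)

    def signature(code: str) -> Tuple[str, int, int]:
        t = space.fringe_trees[code]
        return (t.element, t.root_degree, t.root_beta_sum)

    groups: Dict[Tuple, List[str]] = {}
    for k in vkeys:
        sig = signature(plan0.fringe[k])
        groups.setdefault((deg[k], sig), []).append(k)

    total = 1
    by_sig: Dict[Tuple, List[Tuple]] = {}
    for key in groups:
        by_sig.setdefault(key[1], []).append(key)
    for sig, keys in by_sig.items():
        # codes of this signature available globally
        pool = Counter(
            plan0.fringe[k] for k in vkeys if signature(plan0.fringe[k]) == sig
        )
        sizes = [len(groups[key]) for key in keys]
        # codes admissible at every site of each group
        allowed = []
        for key in keys:
            inter = None
            for k in groups[key]:
                s = {c for c in cands[k] if signature(c) == sig}
                inter = s if inter is None else inter & s
            allowed.append(inter or set())
        total *= _count_distributions(pool, sizes, allowed)
    return max(1, total)


def _count_distributions(pool: Counter, sizes: List[int], allowed: List[set]) -> int:
    """Number of ways to split a code multiset into per-group sub-multisets
    of prescribed sizes with per-group support restrictions."""
    types = sorted(pool)
    from functools import lru_cache

    def rec(t: int, caps: Tuple[int, ...]) -> int:
        if t == len(types):
            return 1 if all(c == 0 for c in caps) else 0
        code = types[t]
        c = pool[code]
        elig = [g for g in range(len(sizes)) if code in allowed[g]]
        out = 0

        def place(i: int, left: int, caps_now: Tuple[int, ...]):
            nonlocal out
            if i == len(elig):
                if left == 0:
                    out += rec(t + 1, caps_now)
                return
            g = elig[i]
            for k in range(0, min(left, caps_now[g]) + 1):
                caps2 = list(caps_now)
                caps2[g] -= k
                place(i + 1, left - k, tuple(caps2))

        place(0, c, caps)
        return out

    return rec(0, tuple(sizes))
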