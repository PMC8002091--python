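"""Two-layered decomposition of a chemical graph.

Repeatedly stripping the degree-1 vertices of a graph assigns every removed
vertex a *height*: the round in which it disappears.  Vertices that survive
forever (cycle cores, path centers) are treated as infinitely high.  Given
a branch-parameter ``rho``, the *exterior* is the set of vertices of height
below ``rho`` together with their incident edges; the *interior* is the
rest.  Each connected component of exterior edges is a *fringe tree* rooted
at its unique highest vertex, which is interior; interior vertices with no
exterior edge own a trivial single-vertex fringe tree, so every interior
vertex roots exactly one fringe tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .chemgraph import ChemGraph, ChemGraphError, Edge

#: Height of vertices never removed by leaf stripping.
SENTINEL_NEVER_REMOVED = math.inf


class EmptyInteriorError(ChemGraphError):
    """The whole graph lies below height rho; no interior exists.

    Carries the graph so callers may treat it as a single rooted tree.
    """

    def __init__(self, graph: ChemGraph):
        self.graph = graph
        super().__init__("graph has no interior vertex at this rho")


def height_map(G: ChemGraph) -> Dict[int, float]:
    """Removal round of every vertex under iterated leaf deletion."""
    deg = {v: G.degree(v) for v in range(G.n)}
    alive = set(range(G.n))
    ht: Dict[int, float] = {v: SENTINEL_NEVER_REMOVED for v in range(G.n)}
    k = 0
    while True:
        leaves = [v for v in alive if deg[v] == 1]
        if not leaves:
            break
        for v in leaves:
            ht[v] = k
            alive.remove(v)
        for v in leaves:
            for u in G.neighbors(v):
                if u in alive:
                    deg[u] -= 1
        k += 1
    return ht


@dataclass
class FringeTree:
    """A fringe tree of the decomposition, labels inherited from the graph."""

    root: int
    vertices: Tuple[int, ...]  # root first
    edges: Tuple[Edge, ...]
    alpha: Dict[int, str]
    beta: Dict[Edge, int]
    height: int

    @property
    def is_trivial(self) -> bool:
        return len(self.vertices) == 1

    def children(self, v: int) -> List[int]:
        """Children of ``v`` in the rooted orientation."""
        parent = self._parents()
        return [w for w in self.vertices if parent.get(w) == v]

    def _parents(self) -> Dict[int, int]:
        parent: Dict[int, int] = {}
        adj: Dict[int, List[int]] = {v: [] for v in self.vertices}
        for (u, v) in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        stack = [self.root]
        seen = {self.root}
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    parent[w] = u
                    stack.append(w)
        return parent


@dataclass
class TwoLayerDecomposition:
    rho: int
    interior_vertices: frozenset
    exterior_vertices: frozenset
    interior_edges: frozenset
    exterior_edges: frozenset
    fringe_trees: List[FringeTree]
    height: Dict[int, float]
    graph: ChemGraph


def decompose(G: ChemGraph, rho: int) -> TwoLayerDecomposition:
    """Partition ``G`` into interior and exterior at branch-parameter ``rho``."""
    if rho < 0:
        raise ChemGraphError("rho must be non-negative")
    ht = height_map(G)
    ext_v = frozenset(v for v in range(G.n) if ht[v] < rho)
    int_v = frozenset(range(G.n)) - ext_v
    if not int_v:
        raise EmptyInteriorError(G)
    ext_e = frozenset(e for e in G.edges if e[0] in ext_v or e[1] in ext_v)
    int_e = frozenset(G.edges) - ext_e
    trees = _fringe_trees(G, ht, int_v, ext_e, rho)
    return TwoLayerDecomposition(
        rho=rho,
        interior_vertices=int_v,
        exterior_vertices=ext_v,
        interior_edges=int_e,
        exterior_edges=ext_e,
        fringe_trees=trees,
        height=ht,
        graph=G,
    )


def _fringe_trees(G, ht, int_v, ext_e, rho) -> List[FringeTree]:
    # components of the exterior edge set; each contains exactly one
    # interior vertex (its root, the vertex of maximum height)
    adj: Dict[int, List[int]] = {}
    for (u, v) in ext_e:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    seen = set()
    root_to_tree: Dict[int, FringeTree] = {}
    for start in sorted(adj):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        roots = [v for v in comp if v in int_v]
        assert len(roots) == 1, "exterior component must touch one interior vertex"
        root = roots[0]
        verts = [root] + sorted(comp - {root})
        edges = tuple(
            e for e in sorted(ext_e) if e[0] in comp and e[1] in comp
        )
        depth = _tree_height(root, verts, edges)
        assert depth <= rho
        root_to_tree[root] = FringeTree(
            root=root,
            vertices=tuple(verts),
            edges=edges,
            alpha={v: G.alpha[v] for v in verts},
            beta={e: G.beta[e] for e in edges},
            height=depth,
        )
    trees = []
    for v in sorted(int_v):
        if v in root_to_tree:
            trees.append(root_to_tree[v])
        else:
            trees.append(
                FringeTree(
                    root=v,
                    vertices=(v,),
                    edges=(),
                    alpha={v: G.alpha[v]},
                    beta={},
                    height=0,
                )
            )
    return trees


def _tree_height(root, verts, edges) -> int:
    adj: Dict[int, List[int]] = {v: [] for v in verts}
    for (u, v) in edges:
        adj[u].append(v)
        adj[v].append(u)
    best = 0
    stack = [(root, None, 0)]
    while stack:
        u, par, d = stack.pop()
        best = max(best, d)
        for w in adj[u]:
            if w != par:
                stack.append((w, u, d + 1))
    return best


def fringe_trees(dec: TwoLayerDecomposition) -> List[FringeTree]:
    """The fringe trees of a decomposition, one per interior vertex."""
    return list(dec.fringe_trees)


def is_k_lean(G: ChemGraph, k: int, root: int | None = None) -> bool:
    """At most one leaf k-branch per pendant (rooted) tree.

    For a cyclic graph the non-core edges induce trees, one rooted at each
    core vertex; the graph is k-lean when every such tree has at most one
    vertex of height exactly ``k``.  An acyclic graph is tested as a rooted
    tree: at the given ``root``, or by default at an end of a longest path
    (which makes every plain path k-lean for every k).  In a rooted tree
    the root is never stripped, so a vertex's height is the height of the
    subtree hanging below it.
    """
    from .chemgraph import core_vertices

    cv = core_vertices(G)
    if cv:
        for r in sorted(cv):
            cnt = 0
            for first in G.neighbors(r):
                if first in cv:
                    continue
                cnt += sum(
                    1 for h in _subtree_heights(G, r, first, cv).values() if h == k
                )
            if cnt > 1:
                return False
        return True
    if root is None:
        import networkx as nx

        ecc = nx.eccentricity(G.to_nx())
        root = min(v for v, e in ecc.items() if e == max(ecc.values()))
    cnt = 0
    for first in G.neighbors(root):
        cnt += sum(1 for h in _subtree_heights(G, root, first, set()).values() if h == k)
    return cnt <= 1


def _subtree_heights(G, root, first, forbidden) -> Dict[int, int]:
    """Height of the down-subtree of each vertex on the pendant tree
    entered from ``root`` via ``first``."""
    heights: Dict[int, int] = {}

    def rec(u, par) -> int:
        hs = [
            rec(w, u)
            for w in G.neighbors(u)
            if w != par and w not in forbidden
        ]
        heights[u] = 1 + max(hs) if hs else 0
        return heights[u]

    rec(first, root)
    return heights
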