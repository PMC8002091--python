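"""Hydrogen-suppressed chemical graphs.

A compound is modelled as a simple connected undirected graph whose vertices
carry non-hydrogen element labels and whose edges carry bond multiplicities
in 1..3.  Hydrogens are implicit: each vertex ``v`` can host
``val(alpha(v)) - beta_sum(v)`` hydrogen atoms (its *hydro-degree*), and the
valence condition ``beta_sum(v) <= val(alpha(v))`` must hold everywhere.

Vertices are dense 0-based integers.  Edges are stored as sorted vertex
pairs ``(u, v)`` with ``u < v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx

Edge = Tuple[int, int]


class ChemGraphError(ValueError):
    """Base error for invalid chemical-graph input."""


class ValenceError(ChemGraphError):
    def __init__(self, vertex: int, element: str, beta_sum: int, valence: int):
        self.vertex = vertex
        self.element = element
        self.beta_sum = beta_sum
        self.valence = valence
        super().__init__(
            f"valence violation at vertex {vertex} ({element}): "
            f"bond sum {beta_sum} > valence {valence}"
        )


class DisconnectedError(ChemGraphError):
    pass


@dataclass(frozen=True)
class ElementInfo:
    symbol: str
    valence: int
    mass10: int  # floor(10 * standard atomic mass)

    def __post_init__(self):
        if not 1 <= self.valence <= 4:
            raise ChemGraphError(f"valence of {self.symbol} must be in [1,4]")
        if self.mass10 <= 0:
            raise ChemGraphError(f"mass10 of {self.symbol} must be positive")


class ElementTable:
    """A finite set of elements with valences, masses and a fixed total order.

    The order is ascending lexicographic over the symbols; it is only used
    to orient configuration tuples, so any fixed order would do, but this
    one is stable across serialization.
    """

    def __init__(self, elements: Iterable[ElementInfo]):
        infos = sorted(elements, key=lambda e: e.symbol)
        self._by_symbol: Dict[str, ElementInfo] = {}
        for info in infos:
            if info.symbol in self._by_symbol:
                raise ChemGraphError(f"duplicate element {info.symbol}")
            self._by_symbol[info.symbol] = info
        self._order: Dict[str, int] = {
            s: i for i, s in enumerate(self._by_symbol)
        }

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __iter__(self):
        return iter(self._by_symbol)

    def symbols(self) -> Tuple[str, ...]:
        return tuple(self._by_symbol)

    def valence(self, symbol: str) -> int:
        return self._info(symbol).valence

    def mass10(self, symbol: str) -> int:
        return self._info(symbol).mass10

    def order_index(self, symbol: str) -> int:
        self._info(symbol)
        return self._order[symbol]

    def _info(self, symbol: str) -> ElementInfo:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise ChemGraphError(f"unknown element {symbol!r}") from None

    def to_dict(self) -> dict:
        return {
            s: {"valence": e.valence, "mass10": e.mass10}
            for s, e in self._by_symbol.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElementTable":
        return cls(
            ElementInfo(s, v["valence"], v["mass10"]) for s, v in d.items()
        )


#: Default table: C, N, O, S, Cl with standard atomic masses.  Sulfur is
#: modelled divalent; the table is fully user-overridable.
DEFAULT_TABLE = ElementTable(
    [
        ElementInfo("C", 4, 120),
        ElementInfo("N", 3, 140),
        ElementInfo("O", 2, 159),
        ElementInfo("S", 2, 320),
        ElementInfo("Cl", 1, 354),
    ]
)


class ChemGraph:
    """A validated hydrogen-suppressed chemical graph."""

    def __init__(
        self,
        n: int,
        edges: Sequence[Edge],
        alpha: Sequence[str],
        beta: Sequence[int],
        table: ElementTable = DEFAULT_TABLE,
    ):
        if n <= 0:
            raise ChemGraphError("graph must have at least one vertex")
        if len(alpha) != n:
            raise ChemGraphError("alpha must label every vertex")
        if len(beta) != len(edges):
            raise ChemGraphError("beta must label every edge")
        norm: List[Edge] = []
        seen = set()
        for (u, v) in edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ChemGraphError(f"edge ({u},{v}) out of range")
            if u == v:
                raise ChemGraphError(f"loop at vertex {u}")
            e = (min(u, v), max(u, v))
            if e in seen:
                raise ChemGraphError(f"parallel edge {e}")
            seen.add(e)
            norm.append(e)
        for a in alpha:
            table.valence(a)  # raises on unknown element
        for (e, m) in zip(norm, beta):
            if not 1 <= int(m) <= 3:
                raise ChemGraphError(f"multiplicity {m} of edge {e} not in [1,3]")

        self.n = n
        self.edges: Tuple[Edge, ...] = tuple(norm)
        self.alpha: Tuple[str, ...] = tuple(alpha)
        self.beta: Dict[Edge, int] = {e: int(m) for e, m in zip(norm, beta)}
        self.table = table
        self._adj: List[List[int]] = [[] for _ in range(n)]
        for (u, v) in self.edges:
            self._adj[u].append(v)
            self._adj[v].append(u)

        self._check_connected()
        for v in range(n):
            bs = self.beta_sum(v)
            val = table.valence(self.alpha[v])
            if bs > val:
                raise ValenceError(v, self.alpha[v], bs, val)

    # -- basic accessors -------------------------------------------------

    def neighbors(self, v: int) -> List[int]:
        self._check_vertex(v)
        return list(self._adj[v])

    def degree(self, v: int) -> int:
        self._check_vertex(v)
        return len(self._adj[v])

    def beta_sum(self, v: int) -> int:
        """Sum of bond multiplicities over the edges incident to ``v``."""
        self._check_vertex(v)
        return sum(self.beta[(min(v, u), max(v, u))] for u in self._adj[v])

    def hydro_degree(self, v: int) -> int:
        """Implicit hydrogen count: valence minus incident bond sum."""
        return self.table.valence(self.alpha[self._check_vertex(v)]) - self.beta_sum(v)

    def edge(self, u: int, v: int) -> Edge:
        e = (min(u, v), max(u, v))
        if e not in self.beta:
            raise ChemGraphError(f"no edge {e}")
        return e

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        for v in range(self.n):
            g.add_node(v, element=self.alpha[v])
        for e in self.edges:
            g.add_edge(*e, beta=self.beta[e])
        return g

    def relabel(self, perm: Sequence[int]) -> "ChemGraph":
        """Return the isomorphic graph with vertex ``v`` renamed ``perm[v]``."""
        inv = [0] * self.n
        for v, p in enumerate(perm):
            inv[p] = v
        edges = [(perm[u], perm[v]) for (u, v) in self.edges]
        beta = [self.beta[e] for e in self.edges]
        alpha = [self.alpha[inv[w]] for w in range(self.n)]
        return ChemGraph(self.n, edges, alpha, beta, self.table)

    # -- internals -------------------------------------------------------

    def _check_vertex(self, v: int) -> int:
        if not 0 <= v < self.n:
            raise ChemGraphError(f"unknown vertex {v}")
        return v

    def _check_connected(self):
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for w in self._adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != self.n:
            raise DisconnectedError(
                f"graph is disconnected ({len(seen)} of {self.n} vertices reachable)"
            )

    def __repr__(self):
        return f"ChemGraph(n={self.n}, m={len(self.edges)})"


def make_chem_graph(
    vertices: int | Sequence[int],
    edges: Sequence[Edge],
    alpha: Sequence[str] | Dict[int, str],
    beta: Sequence[int] | Dict[Edge, int],
    table: ElementTable = DEFAULT_TABLE,
) -> ChemGraph:
    """Validate and build a :class:`ChemGraph`.

    ``vertices`` may be a count or an explicit range; ``alpha``/``beta``
    may be dicts keyed by vertex / sorted edge pair.
    """
    n = vertices if isinstance(vertices, int) else len(list(vertices))
    if isinstance(alpha, dict):
        alpha = [alpha[v] for v in range(n)]
    if isinstance(beta, dict):
        beta = [beta[(min(u, v), max(u, v))] for (u, v) in edges]
    return ChemGraph(n, edges, alpha, beta, table)


def graph_rank(G: ChemGraph | nx.Graph) -> int:
    """Cycle rank |E| - |V| + 1 of a connected graph.

    Equals the minimum number of edges whose removal leaves the graph
    acyclic.
    """
    g = G.to_nx() if isinstance(G, ChemGraph) else G
    if g.number_of_nodes() == 0:
        raise ChemGraphError("empty graph")
    if not nx.is_connected(g):
        raise DisconnectedError("rank is defined here for connected graphs")
    return g.number_of_edges() - g.number_of_nodes() + 1


def core_edges(G: ChemGraph | nx.Graph) -> set:
    """Core edges: edges on a cycle, plus bridges separating two cyclic parts."""
    g = G.to_nx() if isinstance(G, ChemGraph) else G
    bridges = set(frozenset(e) for e in nx.bridges(g))
    core = set()
    for (u, v) in g.edges():
        e = (min(u, v), max(u, v))
        if frozenset(e) not in bridges:
            core.add(e)  # non-bridge edge of a connected graph lies on a cycle
        else:
            h = g.copy()
            h.remove_edge(u, v)
            comps = list(nx.connected_components(h))
            cyclic_sides = 0
            for comp in comps:
                sub = h.subgraph(comp)
                if sub.number_of_edges() >= sub.number_of_nodes():
                    cyclic_sides += 1
            if cyclic_sides == 2:
                core.add(e)
    return core


def core_vertices(G: ChemGraph | nx.Graph) -> set:
    return {v for e in core_edges(G) for v in e}


@dataclass
class Dataset:
    """A property data set: chemical graphs with observed property values."""

    graphs: List[ChemGraph]
    values: List[float]
    property_name: str = "property"
    skip_log: List[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.graphs) != len(self.values):
            raise ChemGraphError("graphs and values differ in length")
        tables = {id(g.table) for g in self.graphs}
        if len(tables) > 1:
            # allow equal-content tables created separately
            dicts = {tuple(sorted(g.table.to_dict().items())) for g in self.graphs}
            if len(dicts) > 1:
                raise ChemGraphError("all graphs must share one element table")

    def __len__(self):
        return len(self.graphs)

    def __iter__(self):
        return iter(zip(self.graphs, self.values))
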