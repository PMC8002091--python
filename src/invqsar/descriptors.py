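"""Descriptors of the two-layered model.

The feature vector of a chemical graph has ``K = 17 + |Lambda_int| +
|Lambda_ex| + |Gamma_int| + |F|`` slots: 17 global counts (size, interior
size, average atomic mass, degree / interior-degree / hydrogen-degree
histograms, interior double/triple bond counts) followed by the frequency
of each interior element, exterior element, interior edge-configuration and
fringe-tree isomorphism class observed in the training data.

Fringe trees are compared up to *r-isomorphism*: a bijection preserving
element labels, bond multiplicities and the root.  The canonical code of a
rooted tree is the recursive minimal string ``(elem[~bond] children...)``
with children sorted lexicographically, so two trees share a code exactly
when they are r-isomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemgraph import ChemGraph, ChemGraphError, Dataset, ElementTable, Edge
from .twolayer import FringeTree, TwoLayerDecomposition, decompose

ChemicalSymbol = Tuple[str, int]  # (element, degree)
EdgeConfig = Tuple[ChemicalSymbol, ChemicalSymbol, int]
AdjConfig = Tuple[str, str, int]

#: Number of fixed (set-independent) descriptor slots.
N_FIXED_SLOTS = 17


class FeatureError(ChemGraphError):
    """A graph uses elements / configurations absent from the space."""

    def __init__(self, missing: List[str]):
        self.missing = list(missing)
        super().__init__("out-of-space symbols: " + ", ".join(self.missing))


# ---------------------------------------------------------------------------
# Rooted chemical trees and canonical codes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RootedTree:
    """An element-labelled rooted tree with bond multiplicities to parents.

    ``bond`` is ``None`` on the root.  The structure is immutable; use
    :meth:`canonical` for the child-order-normalised form.
    """

    element: str
    bond: Optional[int]
    children: Tuple["RootedTree", ...] = ()

    # -- structure -------------------------------------------------------

    @property
    def size(self) -> int:
        return 1 + sum(c.size for c in self.children)

    @property
    def height(self) -> int:
        return 0 if not self.children else 1 + max(c.height for c in self.children)

    @property
    def root_degree(self) -> int:
        return len(self.children)

    @property
    def root_beta_sum(self) -> int:
        return sum(c.bond for c in self.children)

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def element_counts(self, include_root: bool = True) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for node in self.iter_nodes():
            if node is self and not include_root:
                continue
            out[node.element] = out.get(node.element, 0) + 1
        return out

    def mass_sum(self, table: ElementTable) -> int:
        return sum(table.mass10(n.element) for n in self.iter_nodes())

    def non_root_hyd_histogram(self, table: ElementTable) -> Dict[int, int]:
        """Hydro-degree histogram of the non-root vertices.

        A non-root vertex's bond sum is its parent bond plus its children
        bonds, both internal to the tree, so the histogram is independent
        of where the tree is attached.
        """
        hist: Dict[int, int] = {}

        def rec(node: RootedTree):
            for c in node.children:
                hyd = table.valence(c.element) - c.bond - c.root_beta_sum
                hist[hyd] = hist.get(hyd, 0) + 1
                rec(c)

        rec(self)
        return hist

    def validate(self, table: ElementTable):
        """Check valences of non-root vertices and bond ranges."""
        for node in self.iter_nodes():
            if node.bond is not None and not 1 <= node.bond <= 3:
                raise ChemGraphError(f"bond {node.bond} not in [1,3]")
            internal = (node.bond or 0) + node.root_beta_sum
            if internal > table.valence(node.element):
                raise ChemGraphError(
                    f"fringe-tree valence violation at {node.element}"
                )

    # -- canonical form --------------------------------------------------

    def code(self) -> str:
        """Canonical code; equal iff r-isomorphic."""
        head = self.element if self.bond is None else f"{self.element}~{self.bond}"
        return "(" + head + "".join(sorted(c.code() for c in self.children)) + ")"

    def canonical(self) -> "RootedTree":
        kids = tuple(
            sorted((c.canonical() for c in self.children), key=RootedTree.code)
        )
        return RootedTree(self.element, self.bond, kids)

    # -- conversions -----------------------------------------------------

    def to_literal(self):
        """JSON-compatible nested-list form ``[elem, bond, [children...]]``."""
        return [self.element, self.bond, [c.to_literal() for c in self.children]]

    @classmethod
    def from_literal(cls, lit) -> "RootedTree":
        elem, bond, kids = lit
        return cls(elem, bond, tuple(cls.from_literal(k) for k in kids))

    @classmethod
    def from_code(cls, code: str) -> "RootedTree":
        tree, rest = cls._parse(code, 0)
        if rest != len(code):
            raise ChemGraphError(f"trailing characters in code {code!r}")
        return tree

    @classmethod
    def _parse(cls, s: str, i: int) -> Tuple["RootedTree", int]:
        if i >= len(s) or s[i] != "(":
            raise ChemGraphError(f"bad tree code at position {i} in {s!r}")
        i += 1
        j = i
        while j < len(s) and s[j] not in "()~":
            j += 1
        elem = s[i:j]
        if not elem:
            raise ChemGraphError(f"missing element at position {i} in {s!r}")
        bond = None
        i = j
        if i < len(s) and s[i] == "~":
            bond = int(s[i + 1])
            i += 2
        kids = []
        while i < len(s) and s[i] == "(":
            child, i = cls._parse(s, i)
            kids.append(child)
        if i >= len(s) or s[i] != ")":
            raise ChemGraphError(f"unbalanced tree code {s!r}")
        return cls(elem, bond, tuple(kids)), i + 1

    @classmethod
    def from_fringe(cls, T: FringeTree) -> "RootedTree":
        def build(v: int, parent: Optional[int]) -> "RootedTree":
            adj = [u for e in T.edges for u in e if v in e and u != v]
            kids = tuple(
                build(u, v) for u in adj if u != parent
            )
            bond = None
            if parent is not None:
                e = (min(v, parent), max(v, parent))
                bond = T.beta[e]
            return cls(T.alpha[v], bond, kids)

        return build(T.root, None).canonical()


def canonical_code(T: FringeTree | RootedTree) -> str:
    """Canonical r-isomorphism-class code of a (chemical) rooted tree."""
    if isinstance(T, FringeTree):
        return RootedTree.from_fringe(T).code()
    return T.canonical().code()


# ---------------------------------------------------------------------------
# Per-vertex / per-edge configurations
# ---------------------------------------------------------------------------


def chemical_symbol(G: ChemGraph, v: int) -> ChemicalSymbol:
    """(element, degree) of a vertex in the hydrogen-suppressed graph."""
    d = G.degree(v)
    if d > 4:
        raise ChemGraphError(f"vertex {v} has non-chemical degree {d}")
    return (G.alpha[v], d)


def _symbol_key(table: ElementTable, mu: ChemicalSymbol):
    return (table.order_index(mu[0]), mu[1])


def adjacency_config(G: ChemGraph, e: Edge) -> AdjConfig:
    """(a, b, m) with a <= b under the element order."""
    (u, v) = G.edge(*e)
    a, b = G.alpha[u], G.alpha[v]
    if G.table.order_index(a) > G.table.order_index(b):
        a, b = b, a
    return (a, b, G.beta[(u, v)])


def edge_config(G: ChemGraph, e: Edge, dec: TwoLayerDecomposition) -> EdgeConfig:
    """(mu, xi, m) over the chemical symbols of an interior edge's endpoints."""
    (u, v) = G.edge(*e)
    if (u, v) not in dec.interior_edges:
        raise ChemGraphError(f"edge {(u, v)} is not interior; ec is undefined")
    mu, xi = chemical_symbol(G, u), chemical_symbol(G, v)
    if _symbol_key(G.table, mu) > _symbol_key(G.table, xi):
        mu, xi = xi, mu
    return (mu, xi, G.beta[(u, v)])


def gamma_text(gamma: EdgeConfig) -> str:
    (a, d), (b, d2), m = gamma
    return f"({a}{d},{b}{d2},{m})"


def ac_of_gamma(gamma: EdgeConfig, table: ElementTable) -> AdjConfig:
    (a, _), (b, _), m = gamma
    if table.order_index(a) > table.order_index(b):
        a, b = b, a
    return (a, b, m)


# ---------------------------------------------------------------------------
# Descriptor space
# ---------------------------------------------------------------------------


def feature_vector_length(
    n_lambda_int: int, n_lambda_ex: int, n_gamma_int: int, n_fringe: int
) -> int:
    """K = 17 + |Lambda_int| + |Lambda_ex| + |Gamma_int| + |F|."""
    for x in (n_lambda_int, n_lambda_ex, n_gamma_int, n_fringe):
        if x < 0:
            raise ChemGraphError("set cardinalities must be non-negative")
    return N_FIXED_SLOTS + n_lambda_int + n_lambda_ex + n_gamma_int + n_fringe


@dataclass
class DescriptorSpace:
    """The encodings of the set-valued descriptor slots for one data set."""

    lambda_int: Tuple[str, ...]
    lambda_ex: Tuple[str, ...]
    gamma_int: Tuple[EdgeConfig, ...]
    fringe_codes: Tuple[str, ...]
    rho: int
    table: ElementTable
    fringe_trees: Dict[str, RootedTree] = field(default_factory=dict)

    def __post_init__(self):
        if not self.fringe_trees:
            self.fringe_trees = {
                c: RootedTree.from_code(c) for c in self.fringe_codes
            }

    @property
    def K(self) -> int:
        return feature_vector_length(
            len(self.lambda_int),
            len(self.lambda_ex),
            len(self.gamma_int),
            len(self.fringe_codes),
        )

    def slot_names(self) -> List[str]:
        names = (
            ["n", "n_int", "ms_avg"]
            + [f"dg_{d}" for d in range(1, 5)]
            + [f"dg_int_{d}" for d in range(1, 5)]
            + [f"hydg_{d}" for d in range(0, 4)]
            + ["bd_int_2", "bd_int_3"]
        )
        names += [f"na_int_{a}" for a in self.lambda_int]
        names += [f"na_ex_{a}" for a in self.lambda_ex]
        names += [f"ec_{gamma_text(g)}" for g in self.gamma_int]
        names += [f"fc_{c}" for c in self.fringe_codes]
        return names

    # slot offsets -------------------------------------------------------

    @property
    def na_int_offset(self) -> int:
        return N_FIXED_SLOTS

    @property
    def na_ex_offset(self) -> int:
        return self.na_int_offset + len(self.lambda_int)

    @property
    def ec_offset(self) -> int:
        return self.na_ex_offset + len(self.lambda_ex)

    @property
    def fc_offset(self) -> int:
        return self.ec_offset + len(self.gamma_int)

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "lambda_int": list(self.lambda_int),
            "lambda_ex": list(self.lambda_ex),
            "gamma_int": [
                [g[0][0], g[0][1], g[1][0], g[1][1], g[2]] for g in self.gamma_int
            ],
            "fringe_codes": list(self.fringe_codes),
            "element_table": self.table.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSpace":
        return cls(
            lambda_int=tuple(d["lambda_int"]),
            lambda_ex=tuple(d["lambda_ex"]),
            gamma_int=tuple(
                ((a, da), (b, db), m) for a, da, b, db, m in d["gamma_int"]
            ),
            fringe_codes=tuple(d["fringe_codes"]),
            rho=int(d["rho"]),
            table=ElementTable.from_dict(d["element_table"]),
        )


def build_descriptor_space(dataset: Dataset, rho: int) -> DescriptorSpace:
    """Union the interior/exterior element, edge-configuration and fringe
    sets over a data set and freeze their encodings.

    An element counts as exterior only if it labels at least one exterior
    vertex somewhere in the data set.
    """
    if len(dataset) == 0:
        raise ChemGraphError("cannot build a descriptor space from no graphs")
    table = dataset.graphs[0].table
    lam_int, lam_ex = set(), set()
    gammas = set()
    codes: Dict[str, RootedTree] = {}
    for G, _ in dataset:
        dec = decompose(G, rho)
        for v in dec.interior_vertices:
            lam_int.add(G.alpha[v])
        for v in dec.exterior_vertices:
            lam_ex.add(G.alpha[v])
        for e in dec.interior_edges:
            gammas.add(edge_config(G, e, dec))
        for T in dec.fringe_trees:
            rt = RootedTree.from_fringe(T)
            codes.setdefault(rt.code(), rt)
    return DescriptorSpace(
        lambda_int=tuple(sorted(lam_int, key=table.order_index)),
        lambda_ex=tuple(sorted(lam_ex, key=table.order_index)),
        gamma_int=tuple(sorted(gammas, key=gamma_text)),
        fringe_codes=tuple(sorted(codes)),
        rho=rho,
        table=table,
        fringe_trees=codes,
    )


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------


def feature_vector(
    G: ChemGraph,
    space: DescriptorSpace,
    dec: Optional[TwoLayerDecomposition] = None,
) -> np.ndarray:
    """The K-slot descriptor vector of ``G`` in ``space``.

    Raises :class:`FeatureError` naming every element, edge-configuration
    or fringe code of ``G`` that the space does not encode.
    """
    if dec is None:
        dec = decompose(G, space.rho)
    table = space.table
    x = np.zeros(space.K)

    missing: List[str] = []
    li = {a: i for i, a in enumerate(space.lambda_int)}
    le = {a: i for i, a in enumerate(space.lambda_ex)}
    gi = {g: i for i, g in enumerate(space.gamma_int)}
    fi = {c: i for i, c in enumerate(space.fringe_codes)}

    x[0] = G.n
    x[1] = len(dec.interior_vertices)
    x[2] = sum(table.mass10(a) for a in G.alpha) / G.n

    int_deg = {v: 0 for v in dec.interior_vertices}
    for (u, v) in dec.interior_edges:
        int_deg[u] += 1
        int_deg[v] += 1
    for v in dec.interior_vertices:
        d = G.degree(v)
        if 1 <= d <= 4:
            x[3 + d - 1] += 1
        di = int_deg[v]
        if 1 <= di <= 4:
            x[7 + di - 1] += 1
    for v in range(G.n):
        h = G.hydro_degree(v)
        if 0 <= h <= 3:
            x[11 + h] += 1
    for e in dec.interior_edges:
        m = G.beta[e]
        if m in (2, 3):
            x[15 + m - 2] += 1

    for v in dec.interior_vertices:
        a = G.alpha[v]
        if a in li:
            x[space.na_int_offset + li[a]] += 1
        else:
            missing.append(f"interior element {a}")
    for v in dec.exterior_vertices:
        a = G.alpha[v]
        if a in le:
            x[space.na_ex_offset + le[a]] += 1
        else:
            missing.append(f"exterior element {a}")
    for e in dec.interior_edges:
        g = edge_config(G, e, dec)
        if g in gi:
            x[space.ec_offset + gi[g]] += 1
        else:
            missing.append(f"edge-configuration {gamma_text(g)}")
    for T in dec.fringe_trees:
        c = canonical_code(T)
        if c in fi:
            x[space.fc_offset + fi[c]] += 1
        else:
            missing.append(f"fringe code {c}")
    if missing:
        raise FeatureError(sorted(set(missing)))
    return x


def feature_matrix(dataset: Dataset, space: DescriptorSpace):
    """Feature vectors of a data set as a pandas DataFrame with slot names."""
    import pandas as pd

    rows = [feature_vector(G, space) for G, _ in dataset]
    return pd.DataFrame(np.asarray(rows), columns=space.slot_names())
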