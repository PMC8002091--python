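"""Isomorphism utilities for whole chemical graphs.

Deduplication uses a Weisfeiler-Lehman style invariant to bucket graphs
and exact VF2 matching (element labels and bond multiplicities preserved)
inside buckets.  Exercised at toy-to-moderate sizes only.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, List, Tuple

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .chemgraph import ChemGraph


def graph_invariant(G: ChemGraph) -> str:
    """Isomorphism-invariant digest via iterated neighbourhood refinement."""
    colors = {
        v: f"{G.alpha[v]}|{G.degree(v)}|{G.beta_sum(v)}" for v in range(G.n)
    }
    for _ in range(max(1, G.n)):
        new = {}
        for v in range(G.n):
            nbrs = sorted(
                f"{G.beta[(min(v, u), max(v, u))]}:{colors[u]}"
                for u in G.neighbors(v)
            )
            new[v] = hashlib.sha256(
                (colors[v] + "||" + ";".join(nbrs)).encode()
            ).hexdigest()[:16]
        if sorted(new.values()) == sorted(colors.values()):
            colors = new
            break
        colors = new
    return hashlib.sha256(",".join(sorted(colors.values())).encode()).hexdigest()


def is_isomorphic(G1: ChemGraph, G2: ChemGraph) -> bool:
    """Exact isomorphism preserving elements and bond multiplicities."""
    if G1.n != G2.n or len(G1.edges) != len(G2.edges):
        return False
    if sorted(G1.alpha) != sorted(G2.alpha):
        return False
    m = nxiso.GraphMatcher(
        G1.to_nx(),
        G2.to_nx(),
        node_match=nxiso.categorical_node_match("element", None),
        edge_match=nxiso.categorical_edge_match("beta", None),
    )
    return m.is_isomorphic()


def dedup_graphs(graphs: Iterable[ChemGraph]) -> List[ChemGraph]:
    """Keep one representative per isomorphism class, preserving first-seen
    order within an invariant bucket; output sorted by invariant digest."""
    buckets: dict = {}
    for g in graphs:
        key = graph_invariant(g)
        reps = buckets.setdefault(key, [])
        if not any(is_isomorphic(g, r) for r in reps):
            reps.append(g)
    out: List[ChemGraph] = []
    for key in sorted(buckets):
        out.extend(buckets[key])
    return out
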