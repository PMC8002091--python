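"""Synthetic chemical-graph fixtures with a known ground-truth property.

The generator emits valence-valid connected chemical graphs with a
controllable interior (random tree plus optional extra cycle edges) and
exterior (fringe trees drawn from a random candidate pool of height at
most rho).  Property values follow a stated ground truth: a linear form
over the 17 fixed descriptor slots plus Gaussian noise, so training and
inversion can be exercised end to end with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemgraph import ChemGraph, ChemGraphError, DEFAULT_TABLE, Dataset, ElementTable
from .descriptors import DescriptorSpace, RootedTree, feature_vector
from .specification import TargetSpec, random_extension
from .twolayer import decompose

#: Ground-truth coefficients over the 17 fixed descriptor slots
#: (n, n_int, ms_avg, dg_1..4, dg_int_1..4, hydg_0..3, bd_int_2, bd_int_3).
DEFAULT_COEFFICIENTS = (
    2.0, 1.0, 0.05, 0.6, -0.4, 0.3, -0.2, 0.25, -0.15, 0.1, -0.05,
    0.5, -0.3, 0.2, -0.1, 1.5, 2.5,
)


@dataclass
class SyntheticConfig:
    elements: Tuple[str, ...] = ("C", "N", "O")
    rho: int = 2
    n_interior: Tuple[int, int] = (4, 8)
    extra_cycle_edges: Tuple[int, int] = (0, 1)
    fringe_pool_size: int = 8
    max_fringe_vertices: int = 4
    n_samples: int = 60
    coefficients: Tuple[float, ...] = DEFAULT_COEFFICIENTS
    noise_sd: float = 0.0
    table: ElementTable = DEFAULT_TABLE

    def __post_init__(self):
        if self.n_interior[0] < 1 or self.n_interior[0] > self.n_interior[1]:
            raise ChemGraphError("impossible interior size range")
        if len(self.coefficients) != 17:
            raise ChemGraphError("ground truth needs 17 coefficients")


def fixed_descriptors(G: ChemGraph, rho: int) -> np.ndarray:
    """The 17 set-independent descriptor slots of a graph."""
    from .chemgraph import Dataset as _DS
    from .descriptors import build_descriptor_space

    space = build_descriptor_space(_DS([G], [0.0]), rho)
    return feature_vector(G, space)[:17]


def true_property(G: ChemGraph, cfg: SyntheticConfig) -> float:
    """Noise-free ground-truth property value of a graph."""
    x = fixed_descriptors(G, cfg.rho)
    return float(np.dot(np.asarray(cfg.coefficients), x))


def _random_fringe_tree(rng, cfg: SyntheticConfig, root_element=None) -> RootedTree:
    table = cfg.table
    elements = cfg.elements

    def grow(element: str, budget: int, depth: int, used_bond: int) -> RootedTree:
        cap = table.valence(element) - used_bond
        kids: List[RootedTree] = []
        while budget > 0 and cap > 0 and depth < cfg.rho and rng.random() < 0.6:
            child_elem = elements[rng.integers(len(elements))]
            bond = 1 + int(rng.integers(0, min(2, cap, table.valence(child_elem))))
            sub_budget = int(rng.integers(0, budget))
            kid = grow(child_elem, sub_budget, depth + 1, bond)
            kids.append(kid)
            cap -= bond
            budget -= kid.size
        return RootedTree(element, None if depth == 0 else used_bond, tuple(kids))

    elem = root_element or elements[rng.integers(len(elements))]
    return grow(elem, cfg.max_fringe_vertices - 1, 0, 0).canonical()


def generate_random_chem_graph(rng, cfg: SyntheticConfig, pool: Sequence[RootedTree]):
    """One valence-valid connected graph: random interior + pooled fringes."""
    table = cfg.table
    k = int(rng.integers(cfg.n_interior[0], cfg.n_interior[1] + 1))
    # random tree on k interior vertices, degrees capped at 4
    deg = [0] * k
    edges = []
    for v in range(1, k):
        open_slots = [u for u in range(v) if deg[u] < 4]
        u = int(open_slots[rng.integers(len(open_slots))])
        edges.append((u, v))
        deg[u] += 1
        deg[v] += 1
    extra = int(rng.integers(cfg.extra_cycle_edges[0], cfg.extra_cycle_edges[1] + 1))
    have = {(min(u, v), max(u, v)) for (u, v) in edges}
    for _ in range(extra * 4):
        if extra <= 0 or k < 3:
            break
        u, v = rng.integers(0, k, size=2)
        u, v = int(min(u, v)), int(max(u, v))
        if u != v and (u, v) not in have and deg[u] < 4 and deg[v] < 4:
            edges.append((u, v))
            have.add((u, v))
            deg[u] += 1
            deg[v] += 1
            extra -= 1
    alpha: List[str] = [""] * k
    all_edges = list(edges)
    beta = [1] * len(all_edges)
    next_id = k
    for v in range(k):
        # a fringe whose root element can carry the interior degree
        for _ in range(50):
            t = pool[rng.integers(len(pool))]
            if deg[v] + t.root_degree > 4:
                continue
            if deg[v] + t.root_beta_sum <= table.valence(t.element):
                break
        else:
            t = RootedTree("C", None)
        alpha[v] = t.element

        def expand(node: RootedTree, parent: int):
            nonlocal next_id
            for c in node.children:
                cid = next_id
                next_id += 1
                alpha.append(c.element)
                all_edges.append((parent, cid))
                beta.append(c.bond)
                expand(c, cid)

        expand(t, v)
    # occasional double bonds where both endpoints have slack
    G = ChemGraph(next_id, all_edges, alpha, beta, table)
    for i, e in enumerate(G.edges):
        if rng.random() < 0.15 and G.hydro_degree(e[0]) >= 1 and G.hydro_degree(e[1]) >= 1:
            beta2 = [G.beta[x] for x in G.edges]
            beta2[i] += 1
            try:
                G = ChemGraph(G.n, list(G.edges), list(G.alpha), beta2, table)
            except ChemGraphError:
                pass
    return G


def generate_synthetic_dataset(cfg: SyntheticConfig, seed: int = 0) -> Dataset:
    """Reproducible data set of random graphs with ground-truth values."""
    rng = np.random.default_rng(seed)
    pool = [_random_fringe_tree(rng, cfg) for _ in range(cfg.fringe_pool_size)]
    # make sure plain single-vertex roots are available for every element
    pool += [RootedTree(a, None) for a in cfg.elements]
    graphs: List[ChemGraph] = []
    values: List[float] = []
    while len(graphs) < cfg.n_samples:
        G = generate_random_chem_graph(rng, cfg, pool)
        try:
            decompose(G, cfg.rho)
        except ChemGraphError:
            continue
        y = true_property(G, cfg)
        if cfg.noise_sd > 0:
            y += float(rng.normal(0.0, cfg.noise_sd))
        graphs.append(G)
        values.append(y)
    return Dataset(graphs, values, "synthetic")


def spec_conforming_dataset(
    spec: TargetSpec,
    cfg: SyntheticConfig,
    n_samples: int,
    seed: int = 0,
) -> Dataset:
    """Data set of random extensions of a specification with ground-truth
    values; the witness graphs make inversion targets attainable."""
    rng = np.random.default_rng(seed)
    graphs: List[ChemGraph] = []
    values: List[float] = []
    tries = 0
    while len(graphs) < n_samples and tries < n_samples * 200:
        tries += 1
        G = random_extension(spec, rng_seed=int(rng.integers(2**31)))
        if G is None:
            continue
        y = true_property(G, cfg)
        if cfg.noise_sd > 0:
            y += float(rng.normal(0.0, cfg.noise_sd))
        graphs.append(G)
        values.append(y)
    if len(graphs) < n_samples:
        raise ChemGraphError("could not sample enough extensions")
    return Dataset(graphs, values, "synthetic")
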