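"""Molecular Complex Detection (MCODE): dense-subgraph extraction with seed
identification.

Three stages, following the published algorithm:

1. *Vertex weighting.*  Each vertex is weighted by the density of the
   highest k-core of its closed neighborhood times that core's ``k``
   (the "core-clustering coefficient" weighting, which damps the effect of
   lone low-degree spokes on an otherwise dense neighborhood).
2. *Complex prediction.*  Starting from the highest-weighted unassigned
   vertex (the complex *seed*), the complex grows outward, admitting
   neighbors whose weight is within ``node_score_cutoff`` of the seed
   weight.  Each vertex belongs to at most one complex.
3. *Post-processing.*  Complexes that do not contain a ``k_core``-core are
   dropped; with ``haircut`` the complex is trimmed to its 2-core.

A complex's score is its density times its size, ``2·E/(n−1)``, so a clique
K_n scores n.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import ValidationError
from .graph_core import InteractionNetwork

__all__ = ["Complex", "score_nodes", "find_complexes", "complex_score"]


@dataclass(frozen=True)
class Complex:
    """An MCODE cluster: its members, seed vertex and density-based score."""

    members: frozenset[str]
    seed: str
    n_nodes: int
    n_edges: int
    score: float

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValidationError("complex seed must be a member")


def complex_score(n_nodes: int, n_edges: int) -> float:
    """Density x size = ``2*e / (n - 1)`` for n >= 2."""
    if n_nodes < 2:
        raise ValidationError("complex score requires at least 2 nodes")
    return 2.0 * n_edges / (n_nodes - 1)


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Max k with a nonempty k-core, and that core subgraph.

    Computed by repeated pruning so it stays independent of library
    convenience wrappers' tie conventions.
    """
    if g.number_of_nodes() == 0:
        return 0, g
    core_numbers = nx.core_number(g) if g.number_of_edges() else {v: 0 for v in g}
    k = max(core_numbers.values())
    members = [v for v, c in core_numbers.items() if c >= k]
    return k, g.subgraph(members)


def score_nodes(net: InteractionNetwork) -> dict[str, float]:
    """MCODE vertex weights: k * density of the highest k-core of the
    closed neighborhood.  Isolated vertices weigh 0."""
    g = net.graph
    weights: dict[str, float] = {}
    for v in g:
        nbhd = list(g.neighbors(v)) + [v]
        if len(nbhd) < 2:
            weights[v] = 0.0
            continue
        sub = g.subgraph(nbhd)
        k, core = _highest_k_core(sub)
        nc = core.number_of_nodes()
        if k == 0 or nc < 2:
            weights[v] = 0.0
            continue
        core_density = 2.0 * core.number_of_edges() / (nc * (nc - 1))
        weights[v] = k * core_density
    return weights


def _grow_complex(g, weights, seed, assigned, node_score_cutoff, max_depth):
    # admission is inclusive: a node exactly at (1 - cutoff) x seed weight
    # joins the complex (small epsilon guards float round-off)
    threshold = weights[seed] * (1.0 - node_score_cutoff) - 1e-12
    members = {seed}
    frontier = [(seed, 0)]
    while frontier:
        v, depth = frontier.pop()
        if depth >= max_depth:
            continue
        for u in sorted(g.neighbors(v)):
            if u in members or u in assigned:
                continue
            if weights[u] >= threshold:
                members.add(u)
                frontier.append((u, depth + 1))
    return members


def find_complexes(
    net: InteractionNetwork,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    max_depth: int = 100,
) -> list[Complex]:
    """Detect non-overlapping dense complexes, highest score first.

    Defaults are the published MCODE defaults (node score cutoff 0.2,
    k-core filter 2, haircut on, fluff off).  Ties in the output ordering
    are broken by size (larger first) then seed symbol; ties in seed
    selection by symbol order, so the result is deterministic.
    """
    if not 0.0 <= node_score_cutoff <= 1.0:
        raise ValidationError("node_score_cutoff must be in [0, 1]")
    if k_core < 0 or max_depth < 1:
        raise ValidationError("k_core must be >= 0 and max_depth >= 1")
    if fluff:
        raise ValidationError("fluff expansion is not supported")

    g = net.graph
    weights = score_nodes(net)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _grow_complex(g, weights, seed, assigned,
                                node_score_cutoff, max_depth)
        assigned |= members
        sub = g.subgraph(members)
        # k-core filter: the complex must contain a k_core-core
        core_k, _ = _highest_k_core(sub)
        if core_k < k_core:
            continue
        if haircut:
            sub = nx.k_core(sub, 2)
            members = set(sub.nodes)
            if not members:
                continue
            if seed not in members:
                # seed trimmed away: reseed on the heaviest surviving member
                seed = max(members, key=lambda v: (weights[v], v))
        if len(members) < 2:
            continue
        complexes.append(Complex(
            members=frozenset(members),
            seed=seed,
            n_nodes=sub.number_of_nodes(),
            n_edges=sub.number_of_edges(),
            score=complex_score(sub.number_of_nodes(), sub.number_of_edges()),
        ))
    complexes.sort(key=lambda c: (-c.score, -c.n_nodes, c.seed))
    return complexes
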