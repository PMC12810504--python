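"""Undirected simple-graph engine: construction from edge tables and the
standard interaction-network topology panel.

The conventions mirror Cytoscape's NetworkAnalyzer, the de-facto standard for
reporting PPI network topology:

* betweenness is normalized by ``(n-1)(n-2)/2`` with endpoints excluded;
* closeness is the reciprocal of the mean shortest-path distance to the
  nodes a vertex can reach (0 for an isolated vertex);
* distance statistics (diameter, radius, characteristic path length) are
  taken over connected ordered pairs only, so they remain defined after a
  removal disconnects the graph;
* the network clustering coefficient is the plain mean of local clustering
  coefficients with degree-<2 vertices contributing 0;
* heterogeneity is the coefficient of variation of the degree distribution
  (population variance), and centralization is Freeman degree
  centralization, ``(n/(n-2)) * (max_deg/(n-1) - density)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError
from .evidence import normalize_symbol

__all__ = [
    "InteractionNetwork",
    "MetricPanel",
    "build_network",
    "degrees",
    "betweenness",
    "closeness",
    "node_metrics",
    "metric_panel",
    "rank_hubs",
]

PANEL_METRICS = [
    "n_nodes", "n_edges", "avg_neighbors", "diameter", "radius",
    "characteristic_path_length", "clustering_coefficient", "density",
    "heterogeneity", "centralization",
]


class InteractionNetwork:
    """An undirected simple graph over gene symbols.

    Self-loops and duplicate edges are dropped at construction; symbols are
    normalized (uppercased, trimmed).
    """

    def __init__(self, graph: nx.Graph):
        self._g = graph

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(normalize_symbol(n) for n in nodes)
        n_loops = 0
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if not a or not b:
                raise ValidationError("empty node symbol in edge list")
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
        g.graph["self_loops_dropped"] = n_loops
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self._g.copy())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(map(sorted, self._g.edges())):
                fh.write(f"{a}\t{b}\n")

    def __eq__(self, other) -> bool:
        return (isinstance(other, InteractionNetwork)
                and self.nodes == other.nodes and self.edges == other.edges)

    def __repr__(self) -> str:
        return f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class MetricPanel:
    """Whole-network topology statistics (the standard NetworkAnalyzer panel)."""

    n_nodes: int
    n_edges: int
    avg_neighbors: float
    diameter: int
    radius: int
    characteristic_path_length: float
    clustering_coefficient: float
    density: float
    heterogeneity: float
    centralization: float
    n_components: int = 1

    def to_dict(self, ndigits: int | None = None) -> dict:
        d = asdict(self)
        if ndigits is not None:
            d = {k: (round(v, ndigits) if isinstance(v, float) else v)
                 for k, v in d.items()}
        return d


def _parse_tsv_edges(lines: list[str], path: str):
    edges = []
    start = 1 if lines and "\t" in lines[0] and any(
        c.isalpha() for c in lines[0]) and lines[0].lower().split("\t")[0] in (
            "node_a", "source", "node1", "from", "gene_a", "protein_a") else 0
    for i, ln in enumerate(lines, start=1):
        if i <= start or not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ParseError("edge line needs 2 tab-separated nodes", path, i)
        edges.append((parts[0], parts[1]))
    return edges


def _parse_sif_edges(lines: list[str], path: str):
    # SIF: node [relation node node ...]; a line with one token is an
    # isolated node, 3+ tokens fan out from the first node.
    edges, nodes = [], []
    for i, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) == 1:
            nodes.append(parts[0])
        elif len(parts) == 2:
            raise ParseError("SIF line has a relation but no target", path, i)
        else:
            src = parts[0]
            edges.extend((src, tgt) for tgt in parts[2:])
    return edges, nodes


def build_network(path: str | Path, dialect: str = "tsv") -> InteractionNetwork:
    """Read an edge table (2-column TSV, optional header, or SIF)."""
    lines = Path(path).read_text().splitlines()
    if dialect == "tsv":
        edges = _parse_tsv_edges(lines, str(path))
        return InteractionNetwork.from_edges(edges)
    if dialect == "sif":
        edges, nodes = _parse_sif_edges(lines, str(path))
        return InteractionNetwork.from_edges(edges, nodes=nodes)
    raise ValidationError(f"unknown edge-table dialect {dialect!r}")


def degrees(net: InteractionNetwork) -> dict[str, int]:
    """Number of direct interaction partners per node."""
    return dict(net.graph.degree())


def betweenness(net: InteractionNetwork, normalized: bool = True) -> dict[str, float]:
    """Exact shortest-path betweenness (Brandes), endpoints excluded.

    Normalized by ``(n-1)(n-2)/2`` so a path's middle vertex scores 1.
    """
    return nx.betweenness_centrality(net.graph, normalized=normalized)


def closeness(net: InteractionNetwork) -> dict[str, float]:
    """Reciprocal mean distance to reachable nodes; 0 for isolated nodes."""
    return nx.closeness_centrality(net.graph, wf_improved=False)


def node_metrics(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node degree, betweenness and closeness, one row per gene."""
    deg = degrees(net)
    bet = betweenness(net)
    clo = closeness(net)
    rows = [[g, deg[g], bet[g], clo[g]] for g in sorted(net.nodes)]
    return pd.DataFrame(rows, columns=["gene", "degree", "betweenness",
                                       "closeness"])


def _distance_stats(g: nx.Graph):
    """(diameter, radius, mean distance, connected ordered pairs) over
    connected pairs only; nodes with no reachable partner are ignored for
    eccentricity."""
    total = 0
    n_pairs = 0
    eccentricities = []
    for src in g:
        dist = nx.single_source_shortest_path_length(g, src)
        dist.pop(src, None)
        if dist:
            eccentricities.append(max(dist.values()))
            total += sum(dist.values())
            n_pairs += len(dist)
    if not eccentricities:
        return 0, 0, 0.0, 0
    return max(eccentricities), min(eccentricities), total / n_pairs, n_pairs


def metric_panel(net: InteractionNetwork) -> MetricPanel:
    """Compute the full topology panel for a network with >= 2 nodes."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValidationError("metric panel requires at least 2 nodes")
    degs = [d for _, d in g.degree()]
    mean_deg = sum(degs) / n
    density = 2 * e / (n * (n - 1))
    var_deg = sum((d - mean_deg) ** 2 for d in degs) / n
    heterogeneity = math.sqrt(var_deg) / mean_deg if mean_deg > 0 else 0.0
    centralization = (n / (n - 2)) * (max(degs) / (n - 1) - density) if n > 2 else 0.0
    clustering = nx.average_clustering(g, count_zeros=True)
    diameter, radius, cpl, _ = _distance_stats(g)
    return MetricPanel(
        n_nodes=n,
        n_edges=e,
        avg_neighbors=mean_deg,
        diameter=diameter,
        radius=radius,
        characteristic_path_length=cpl,
        clustering_coefficient=clustering,
        density=density,
        heterogeneity=heterogeneity,
        centralization=centralization,
        n_components=nx.number_connected_components(g),
    )


def rank_hubs(metrics: pd.DataFrame) -> pd.DataFrame:
    """Rank nodes by degree, then betweenness, then closeness (all
    descending), with the gene symbol as a deterministic final tie-break."""
    out = metrics.sort_values(
        by=["degree", "betweenness", "closeness", "gene"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.index += 1
    out.index.name = "rank"
    return out
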