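"""Over-representation analysis with fold enrichment and BH-FDR, plus
kappa-similarity clustering of enriched terms.

The test is the exact upper-tail hypergeometric (one-tailed Fisher): for a
hit list of size ``n`` drawn from a universe of size ``N``, a term covering
``K`` universe genes, and ``k`` hits in the term,

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)
    fold enrichment = (k/n) / (K/N)

FDR is Benjamini-Hochberg within each annotation category.  Redundant terms
are then merged by Cohen's kappa agreement of their gene-membership vectors
(restricted to the hit list by default): single-linkage connected
components of the kappa >= threshold graph, each represented by its most
significant member.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError
from .evidence import normalize_symbol

__all__ = [
    "Annotation",
    "TermCluster",
    "load_gmt",
    "enrich",
    "kappa",
    "cluster_terms",
]


@dataclass(frozen=True)
class Annotation:
    """A named gene set (GO term, pathway, ...) within a category."""

    term_id: str
    term_name: str
    genes: frozenset[str]
    category: str = "default"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"annotation {self.term_id!r} has no genes")


@dataclass(frozen=True)
class TermCluster:
    """Kappa-linked group of enriched terms and its representative."""

    members: tuple[str, ...]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValidationError("cluster representative must be a member")


def load_gmt(path: str | Path, category: str = "default") -> list[Annotation]:
    """Read a GMT-style TSV: term_id <TAB> description <TAB> gene1 <TAB> ..."""
    annotations = []
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ParseError("GMT line needs term, description and >=1 gene",
                             str(path), i)
        genes = frozenset(normalize_symbol(g) for g in parts[2:] if g.strip())
        annotations.append(Annotation(term_id=parts[0], term_name=parts[1],
                                      genes=genes, category=category))
    return annotations


def enrich(
    hits: set[str],
    annotations: list[Annotation],
    universe: set[str],
    min_hits: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the hit list.

    Terms are intersected with the universe first; only terms with at least
    ``min_hits`` hits are tested.  Returns one row per tested term with
    columns term_id, term_name, category, k, n, K, N, fold_enrichment,
    p_value and fdr (BH within category), sorted by p ascending.
    """
    offenders = sorted(hits - universe)
    if offenders:
        raise ValidationError(f"hit genes outside the universe: {offenders}")
    n = len(hits)
    N = len(universe)
    rows = []
    for ann in annotations:
        term_genes = ann.genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(hits & term_genes)
        if k < min_hits:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append([ann.term_id, ann.term_name, ann.category,
                     k, n, K, N, fold, min(p, 1.0)])
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "category",
                                      "k", "n", "K", "N",
                                      "fold_enrichment", "p_value"])
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        return out
    out["fdr"] = 1.0
    for cat, idx in out.groupby("category").groups.items():
        out.loc[idx, "fdr"] = multipletests(out.loc[idx, "p_value"],
                                            method="fdr_bh")[1]
    out = out.sort_values(["p_value", "term_id"], kind="mergesort")
    return out.reset_index(drop=True)


def kappa(term_a: set[str], term_b: set[str], domain: set[str]) -> float:
    """Cohen's kappa between two terms' membership vectors over ``domain``.

    The 2x2 agreement table counts domain genes in both terms, in one only,
    and in neither; kappa = (po - pe) / (1 - pe).  Perfect forced agreement
    (pe = po = 1, e.g. both terms equal the domain) returns 1.0.
    """
    if len(domain) < 2:
        raise ValidationError("kappa domain must contain at least 2 genes")
    a = term_a & domain
    b = term_b & domain
    m = len(domain)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = m - both - only_a - only_b
    po = (both + neither) / m
    pe = ((both + only_a) * (both + only_b)
          + (only_b + neither) * (only_a + neither)) / (m * m)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def cluster_terms(
    rows: pd.DataFrame,
    annotations: list[Annotation],
    threshold: float = 0.3,
    domain: set[str] | None = None,
) -> list[TermCluster]:
    """Group enriched terms into single-linkage kappa clusters.

    Terms are linked when their membership kappa (over ``domain``, default:
    the hit list the rows were computed from) meets ``threshold``; clusters
    are the connected components of that link graph.  The representative is
    the member with the smallest p-value (ties: larger term, then term_id);
    clusters are ordered by their representative's p-value.
    """
    if rows.empty:
        raise ValidationError("no enrichment rows to cluster")
    by_id = {a.term_id: a for a in annotations}
    missing = [t for t in rows["term_id"] if t not in by_id]
    if missing:
        raise ValidationError(f"enriched terms missing from annotation: {missing}")
    if domain is None:
        # pass the hit list as domain to mirror Metascape; the fallback is
        # the union of the enriched terms' genes
        domain = set().union(*(by_id[t].genes for t in rows["term_id"]))
    term_ids = list(rows["term_id"])
    link = nx.Graph()
    link.add_nodes_from(term_ids)
    for i, t1 in enumerate(term_ids):
        for t2 in term_ids[i + 1:]:
            if kappa(set(by_id[t1].genes), set(by_id[t2].genes), domain) >= threshold:
                link.add_edge(t1, t2)
    stats = rows.set_index("term_id")
    clusters = []
    for comp in nx.connected_components(link):
        members = sorted(comp)
        rep = min(members, key=lambda t: (stats.loc[t, "p_value"],
                                          -stats.loc[t, "K"], t))
        clusters.append(TermCluster(members=tuple(members), representative=rep))
    clusters.sort(key=lambda c: (stats.loc[c.representative, "p_value"],
                                 c.representative))
    return clusters
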