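"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its parameters (seed included): the
same call yields the same output, and every piece of planted structure is
returned in a companion ``truth`` dictionary so downstream recovery tests
never re-derive the ground truth.  The generators emulate:

* multi-source disease-gene lists with an exact planted Venn design;
* interaction networks with an exactly prescribed degree sequence;
* background networks with one planted dense cluster (clique);
* term annotations with one planted over-represented term;
* TF-regulon tables with one planted full-coverage regulator.
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import Annotation
from .errors import ValidationError
from .evidence import EvidenceGeneSet
from .graph_core import InteractionNetwork

__all__ = [
    "gene_universe",
    "gen_source_lists",
    "gen_degree_sequence_graph",
    "gen_planted_cluster_graph",
    "gen_annotation",
    "gen_tf_table",
    "write_run",
]


def gene_universe(size: int, prefix: str = "G") -> list[str]:
    """Deterministic synthetic gene symbols G0001, G0002, ..."""
    width = max(4, len(str(size)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, size + 1)]


def gen_source_lists(
    design: dict[int, int],
    n_sources: int = 3,
    universe_size: int = 1000,
    seed: int = 0,
) -> tuple[list[EvidenceGeneSet], dict]:
    """Source gene lists with an exact support design.

    ``design`` maps a support level ``s`` (how many of the ``n_sources``
    sources contain a gene) to the number of genes planted at exactly that
    support; which ``s`` sources hold each gene is drawn uniformly.  The
    truth records per-gene support, exact Venn-region counts and the
    retained count for every possible ``min_sources``.
    """
    if any(s < 1 or s > n_sources for s in design):
        raise ValidationError("support levels must lie in 1..n_sources")
    total = sum(design.values())
    if total > universe_size:
        raise ValidationError(
            f"design places {total} genes but universe has {universe_size}")
    rng = np.random.default_rng(seed)
    universe = gene_universe(universe_size)
    chosen = list(rng.choice(universe, size=total, replace=False))
    names = [f"source_{i + 1}" for i in range(n_sources)]
    members: dict[str, set[str]] = {nm: set() for nm in names}
    support: dict[str, int] = {}
    region_counts: dict[str, int] = {}
    idx = 0
    for level in sorted(design):
        for _ in range(design[level]):
            gene = chosen[idx]
            idx += 1
            holders = rng.choice(n_sources, size=level, replace=False)
            for h in holders:
                members[names[h]].add(gene)
            support[gene] = level
            key = "".join("1" if h in holders else "0" for h in range(n_sources))
            region_counts[key] = region_counts.get(key, 0) + 1
    sets = [EvidenceGeneSet(source_name=nm, genes=frozenset(members[nm]))
            for nm in names]
    truth = {
        "seed": seed,
        "design": {str(k): v for k, v in design.items()},
        "support": support,
        "venn_regions": region_counts,
        "retained_at": {str(m): sum(c for s, c in design.items() if s >= m)
                        for m in range(1, n_sources + 1)},
    }
    return sets, truth


def gen_degree_sequence_graph(
    sequence: list[int],
    seed: int = 0,
    labels: list[str] | None = None,
) -> InteractionNetwork:
    """A random simple graph whose degrees equal ``sequence`` exactly.

    The sequence is checked with the Erdős–Gallai condition, realized by
    Havel–Hakimi construction (largest degree first), and randomized with
    seeded degree-preserving double edge swaps — so the degrees are exact
    by construction, with no repair loop.
    """
    if sum(sequence) % 2 != 0:
        raise ValidationError("degree sequence has odd sum; not graphical")
    if not nx.is_graphical(sequence):
        raise ValidationError(
            "degree sequence fails the Erdős–Gallai condition")
    if labels is not None and len(labels) != len(sequence):
        raise ValidationError("labels must match the sequence length")
    g = nx.havel_hakimi_graph(sorted(sequence, reverse=True))
    if g.number_of_nodes() >= 4 and g.number_of_edges() >= 2:
        try:
            nx.double_edge_swap(g, nswap=4 * g.number_of_edges(),
                                max_tries=200 * g.number_of_edges(),
                                seed=seed)
        except nx.NetworkXException:
            pass  # rigid graphs (e.g. stars) admit no swap
    if labels is None:
        labels = [f"N{i + 1:03d}" for i in range(len(sequence))]
    # pair nodes and labels by descending degree so labels[i] gets degree
    # sequence[i]
    deg_of = dict(g.degree())
    nodes_sorted = sorted(g.nodes, key=lambda v: (-deg_of[v], v))
    label_order = sorted(range(len(sequence)), key=lambda i: -sequence[i])
    mapping = {node: labels[idx]
               for node, idx in zip(nodes_sorted, label_order)}
    g = nx.relabel_nodes(g, mapping)
    return InteractionNetwork(g)


def gen_planted_cluster_graph(
    n_background: int,
    p_background: float,
    clique_size: int,
    seed: int = 0,
) -> tuple[InteractionNetwork, dict]:
    """Erdős–Rényi background with an embedded clique.

    The clique occupies the first ``clique_size`` node labels; background
    edges are drawn over all nodes at ``p_background``.  With p = 1 the
    clique is indistinguishable from the background and the truth flags the
    design as degenerate.
    """
    if not 0.0 <= p_background <= 1.0:
        raise ValidationError("p_background must be in [0, 1]")
    if clique_size < 0:
        raise ValidationError("clique_size must be >= 0")
    n_total = n_background + clique_size
    labels = gene_universe(n_total, prefix="V")
    g = nx.gnp_random_graph(n_total, p_background, seed=seed)
    g = nx.relabel_nodes(g, dict(enumerate(labels)))
    clique = labels[:clique_size]
    for i, a in enumerate(clique):
        for b in clique[i + 1:]:
            g.add_edge(a, b)
    truth = {
        "seed": seed,
        "clique_members": clique,
        "p_background": p_background,
        "degenerate": p_background >= 1.0,
    }
    return InteractionNetwork(g), truth


def gen_annotation(
    universe: list[str],
    hits: list[str],
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 50),
    planted_term_effect: float | None = 5.0,
    seed: int = 0,
) -> tuple[list[Annotation], dict]:
    """Random annotation terms plus one term over-represented in ``hits``.

    Background terms are uniform draws from the universe.  The planted term
    samples its members without replacement with hit genes weighted
    ``planted_term_effect``-fold over non-hits, so its expected hit count
    exceeds the null.  ``planted_term_effect=None`` plants nothing;
    values <= 1 are rejected.
    """
    lo, hi = term_size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ValidationError("term_size_range incompatible with universe")
    if planted_term_effect is not None and planted_term_effect <= 1.0:
        raise ValidationError("planted term effect must exceed 1")
    hit_set = set(hits)
    if not hit_set <= set(universe):
        raise ValidationError("hits must be drawn from the universe")
    rng = np.random.default_rng(seed)
    annotations = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        annotations.append(Annotation(
            term_id=f"T{t + 1:04d}", term_name=f"background term {t + 1}",
            genes=frozenset(genes), category="synthetic"))
    truth: dict = {"seed": seed, "planted_term": None}
    if planted_term_effect is not None:
        size = int(rng.integers(lo, hi + 1))
        if np.isinf(planted_term_effect):
            take = min(size, len(hits))
            members = list(rng.choice(sorted(hit_set), size=take,
                                      replace=False))
            rest = [g for g in universe if g not in set(members)]
            members += list(rng.choice(rest, size=size - take, replace=False))
        else:
            weights = np.array([planted_term_effect if g in hit_set else 1.0
                                for g in universe])
            members = list(rng.choice(universe, size=size, replace=False,
                                      p=weights / weights.sum()))
        term_id = "T_PLANTED"
        annotations.append(Annotation(
            term_id=term_id, term_name="planted enriched term",
            genes=frozenset(members), category="synthetic"))
        truth["planted_term"] = term_id
        truth["planted_k"] = len(hit_set & set(members))
        truth["planted_size"] = size
    return annotations, truth


def gen_tf_table(
    n_tfs: int,
    target_range: tuple[int, int],
    planted_tf_key_genes: list[str],
    universe: list[str],
    seed: int = 0,
    planted_tf: str = "TF_PLANTED",
) -> tuple[list[tuple[str, str, str, str]], dict]:
    """TRRUST-dialect rows with one planted full-coverage regulator.

    Background regulons draw their targets from the universe minus the
    first key gene (reserved to the planted TF), so only the planted TF can
    cover the full key set and recovery is unambiguous.  Rows are returned
    as (TF, target, mode, reference) tuples.
    """
    key = [g for g in planted_tf_key_genes]
    if not set(key) <= set(universe):
        raise ValidationError("key genes must be in the universe")
    lo, hi = target_range
    if lo < 1 or hi > len(universe):
        raise ValidationError("target_range incompatible with universe")
    rng = np.random.default_rng(seed)
    pool = [g for g in universe if not key or g != key[0]]
    rows: list[tuple[str, str, str, str]] = []
    modes = ["Activation", "Repression", "Unknown"]
    for t in range(n_tfs):
        tf = f"TF{t + 1:03d}"
        size = int(rng.integers(lo, min(hi, len(pool)) + 1))
        targets = rng.choice(pool, size=size, replace=False)
        for tgt in sorted(targets):
            rows.append((tf, tgt, modes[int(rng.integers(3))], f"PMID:{seed}"))
    if key:
        size = max(len(key), lo)
        extras = [g for g in pool if g not in set(key)]
        n_extra = min(size - len(key), len(extras))
        chosen = list(key) + (list(rng.choice(extras, size=n_extra,
                                              replace=False))
                              if n_extra > 0 else [])
        for tgt in sorted(chosen):
            rows.append((planted_tf, tgt, "Unknown", f"PMID:{seed}"))
    truth = {"seed": seed, "planted_tf": planted_tf if key else None,
             "key_genes": key}
    return rows, truth


def write_run(outdir: str | Path, files: dict[str, str], truth: dict,
              seed: int) -> Path:
    """Write generated text files plus a truth JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, content in files.items():
        (outdir / name).write_text(content)
    truth = dict(truth)
    truth.setdefault("seed", seed)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return outdir
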