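"""Multi-source disease-gene evidence: loading, identifier unification and
k-of-n retention.

Disease-gene lists pulled from different curated repositories overlap only
partially; requiring a gene to be reported by at least ``min_sources`` of the
supplied sources filters out single-database artifacts.  The module keeps the
full per-source membership matrix so that Venn-region accounting can be
reported alongside the retained set.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EvidenceGeneSet",
    "EvidenceMatrix",
    "normalize_symbol",
    "load_gene_list",
    "load_synonym_map",
    "unify_identifiers",
    "multi_evidence_intersect",
]


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol. No ortholog or alias mapping."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class EvidenceGeneSet:
    """A named evidence source and its set of normalized gene symbols."""

    source_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValidationError(
                f"source {self.source_name!r} contains an empty gene symbol")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EvidenceMatrix:
    """Per-gene source membership of the retained genes plus Venn accounting.

    ``table`` has one row per retained gene with boolean per-source columns
    and an integer ``support`` column.  ``venn`` maps a membership pattern
    (e.g. ``"110"``, one character per source in ``sources`` order) to the
    number of genes in the *union of all sources* falling in that exact
    region; it is populated only for up to 5 sources.
    """

    sources: list[str]
    table: pd.DataFrame
    venn: dict[str, int] = field(default_factory=dict)
    min_sources: int = 2

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_gene_list(path: str | Path, source_name: str) -> EvidenceGeneSet:
    """Read a gene list file: one symbol per line, or a 2-column TSV with a
    header where the gene symbol is the last column.

    Duplicate symbols (after normalization) are collapsed and counted.
    """
    path = Path(path)
    try:
        raw = path.read_text().splitlines()
    except OSError as exc:
        raise OSError(f"cannot read gene list for {source_name!r}: {exc}") from exc
    lines = [ln for ln in raw if ln.strip()]
    if not lines:
        raise ValidationError(f"gene list for source {source_name!r} is empty: {path}")

    symbols: list[str] = []
    if "\t" in lines[0]:
        # 2-column TSV with header: (source, gene) — take the last column
        for ln in lines[1:]:
            parts = ln.split("\t")
            symbols.append(parts[-1])
    else:
        symbols = lines

    normalized = [normalize_symbol(s) for s in symbols]
    normalized = [s for s in normalized if s]
    genes = frozenset(normalized)
    n_dupes = len(normalized) - len(genes)
    if n_dupes:
        logger.info("source %s: collapsed %d duplicate symbol(s)",
                    source_name, n_dupes)
    return EvidenceGeneSet(source_name=source_name, genes=genes)


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV alias→canonical table; aliases must be unique."""
    mapping: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ParseError("synonym table needs 2 columns", str(path), i)
        alias = normalize_symbol(parts[0])
        canonical = normalize_symbol(parts[1])
        if alias in mapping and mapping[alias] != canonical:
            raise ValidationError(
                f"alias {alias!r} maps to both {mapping[alias]!r} and {canonical!r}")
        mapping[alias] = canonical
    return mapping


def unify_identifiers(
    sets: list[EvidenceGeneSet],
    synonym_map: dict[str, str] | None = None,
) -> list[EvidenceGeneSet]:
    """Replace every alias by its canonical symbol in each evidence set.

    Merging two aliases of one gene shrinks the set accordingly.  An empty or
    absent synonym map is the identity.
    """
    if not synonym_map:
        return list(sets)
    canonical_targets: dict[str, str] = {}
    for alias, canon in synonym_map.items():
        if alias in canonical_targets and canonical_targets[alias] != canon:
            raise ValidationError(
                f"alias {alias!r} has conflicting canonical targets")
        canonical_targets[alias] = canon
    out = []
    for es in sets:
        mapped = frozenset(synonym_map.get(g, g) for g in es.genes)
        out.append(EvidenceGeneSet(source_name=es.source_name, genes=mapped))
    return out


def _venn_counts(sets: list[EvidenceGeneSet]) -> dict[str, int]:
    union = set().union(*(s.genes for s in sets))
    counts: dict[str, int] = {}
    for pattern in itertools.product("01", repeat=len(sets)):
        key = "".join(pattern)
        if key == "0" * len(sets):
            continue
        counts[key] = 0
    for g in union:
        key = "".join("1" if g in s.genes else "0" for s in sets)
        counts[key] += 1
    return counts


def multi_evidence_intersect(
    sets: list[EvidenceGeneSet],
    min_sources: int = 2,
) -> EvidenceMatrix:
    """Retain genes present in at least ``min_sources`` of the given sources.

    Returns the retained-gene membership matrix; Venn-region counts over the
    union are included for up to 5 sources (beyond that only the support
    column is informative).
    """
    if min_sources < 1:
        raise ValidationError("min_sources must be >= 1")
    if min_sources > len(sets):
        raise ValidationError(
            f"min_sources={min_sources} exceeds the number of sources ({len(sets)})")
    names = [s.source_name for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate source names in evidence sets")

    union = sorted(set().union(*(s.genes for s in sets)))
    rows = []
    for g in union:
        flags = [g in s.genes for s in sets]
        support = sum(flags)
        if support >= min_sources:
            rows.append([g, *flags, support])
    table = pd.DataFrame(rows, columns=["gene", *names, "support"])
    venn = _venn_counts(sets) if len(sets) <= 5 else {}
    return EvidenceMatrix(sources=names, table=table, venn=venn,
                          min_sources=min_sources)
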