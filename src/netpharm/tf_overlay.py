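"""Transcription-factor regulon overlay: which curated regulators cover a
set of key hub genes.

Input is a literature-curated TF->target table in the TRRUST dialect
(TSV: TF, target gene, mode of regulation, PubMed ids).  For a query set of
hub genes the module reports, per TF, which hubs it targets, how many
network genes it targets overall, and a transparent hypergeometric overlap
p-value computed against an explicit, user-supplied gene universe.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .errors import ParseError, ValidationError
from .evidence import normalize_symbol

__all__ = ["Regulon", "load_trrust", "tf_coverage"]


@dataclass
class Regulon:
    """A transcription factor and its curated target genes."""

    tf: str
    targets: set[str]
    modes: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"regulon {self.tf!r} has no targets")


def load_trrust(path: str | Path) -> list[Regulon]:
    """Parse a TRRUST-dialect TSV (TF, target[, mode[, references]]).

    Rows are aggregated per TF; duplicate TF-target pairs are collapsed
    (first-seen mode wins).  An empty file yields an empty list.
    """
    regulons: dict[str, Regulon] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError("TRRUST line needs at least TF and target",
                             str(path), i)
        tf = normalize_symbol(parts[0])
        target = normalize_symbol(parts[1])
        mode = parts[2].strip() if len(parts) > 2 else ""
        refs = parts[3].strip() if len(parts) > 3 else ""
        if tf not in regulons:
            regulons[tf] = Regulon(tf=tf, targets={target})
        reg = regulons[tf]
        reg.targets.add(target)
        if target not in reg.modes and mode:
            reg.modes[target] = mode
        if target not in reg.provenance and refs:
            reg.provenance[target] = refs
    return [regulons[tf] for tf in sorted(regulons)]


def tf_coverage(
    regulons: list[Regulon],
    key_genes: set[str],
    network_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Rank TFs by how many of the key hub genes they target.

    Requires ``key_genes`` to lie inside ``network_genes`` and those inside
    ``universe``.  TFs with no target in the network are excluded.  The
    p-value is the upper-tail hypergeometric overlap between the TF's
    universe-restricted target set and the network genes.  Rows are sorted
    by coverage (descending), then p-value, then TF symbol.
    """
    if not key_genes:
        raise ValidationError("key gene set is empty")
    if not key_genes <= network_genes:
        raise ValidationError(
            f"key genes outside the network: {sorted(key_genes - network_genes)}")
    if not network_genes <= universe:
        raise ValidationError(
            f"network genes outside the universe: "
            f"{sorted(network_genes - universe)[:10]}")
    N = len(universe)
    n = len(network_genes)
    rows = []
    for reg in regulons:
        in_universe = reg.targets & universe
        in_network = reg.targets & network_genes
        if not in_network:
            continue
        covered = sorted(reg.targets & key_genes)
        K = len(in_universe)
        k = len(in_network)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append([reg.tf, ",".join(covered), len(covered), k, K, p])
    out = pd.DataFrame(rows, columns=["tf", "covered", "n_covered",
                                      "k_in_network", "n_targets_in_universe",
                                      "p_value"])
    out = out.sort_values(["n_covered", "p_value", "tf"],
                          ascending=[False, True, True], kind="mergesort")
    return out.reset_index(drop=True)
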