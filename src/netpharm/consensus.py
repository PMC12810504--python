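"""Drug-target consensus across in-silico target predictors, and the overlap
of the consensus targets with a disease gene set.

Each drug is screened by several independent target predictors; a gene is
accepted as a consensus target when at least ``min_agreement`` predictors
report it (the same k-of-n rule used for disease evidence).  The disease
overlap is then either the disease genes hit by *every* drug ("all_drugs",
the default) or by *any* drug ("any_drug").
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError
from .evidence import normalize_symbol

__all__ = [
    "DrugTargetSet",
    "OverlapResult",
    "load_drug_targets",
    "consensus_targets",
    "consensus_by_drug",
    "disease_overlap",
]

POLICIES = ("all_drugs", "any_drug")


@dataclass(frozen=True)
class DrugTargetSet:
    """One predictor's target list for one drug."""

    drug: str
    predictor: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.predictor:
            raise ValidationError("predictor label must be nonempty")


@dataclass
class OverlapResult:
    """Consensus target sets per drug and their overlap with a disease set."""

    consensus: dict[str, set[str]]
    disease: set[str]
    shared: set[str]
    policy: str
    per_drug_shared: dict[str, set[str]] = field(default_factory=dict)


def load_drug_targets(path: str | Path) -> list[DrugTargetSet]:
    """Read a 3-column TSV (drug, predictor, gene) with a header row."""
    grouped: dict[tuple[str, str], set[str]] = defaultdict(set)
    lines = Path(path).read_text().splitlines()
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ParseError("drug-target table needs 3 columns", str(path), i)
        drug, predictor, gene = parts[0].strip(), parts[1].strip(), parts[2]
        grouped[(drug, predictor)].add(normalize_symbol(gene))
    return [DrugTargetSet(drug=d, predictor=p, genes=frozenset(g))
            for (d, p), g in sorted(grouped.items())]


def consensus_targets(
    predictions: list[DrugTargetSet],
    min_agreement: int = 2,
) -> set[str]:
    """Genes predicted for one drug by at least ``min_agreement`` predictors."""
    if not predictions:
        raise ValidationError("no predictor sets supplied")
    drugs = {p.drug for p in predictions}
    if len(drugs) != 1:
        raise ValidationError(f"mixed drugs in consensus input: {sorted(drugs)}")
    predictors = [p.predictor for p in predictions]
    if len(set(predictors)) != len(predictors):
        raise ValidationError("duplicate predictor labels for one drug")
    if min_agreement < 1 or min_agreement > len(predictions):
        raise ValidationError(
            f"min_agreement={min_agreement} out of range for "
            f"{len(predictions)} predictors")
    votes: Counter[str] = Counter()
    for p in predictions:
        votes.update(p.genes)
    return {g for g, c in votes.items() if c >= min_agreement}


def consensus_by_drug(
    predictions: list[DrugTargetSet],
    min_agreement: int = 2,
) -> dict[str, set[str]]:
    """Apply :func:`consensus_targets` per drug over a mixed prediction list."""
    by_drug: dict[str, list[DrugTargetSet]] = defaultdict(list)
    for p in predictions:
        by_drug[p.drug].append(p)
    return {d: consensus_targets(preds, min_agreement)
            for d, preds in sorted(by_drug.items())}


def disease_overlap(
    consensus: dict[str, set[str]],
    disease: set[str],
    policy: str = "all_drugs",
) -> OverlapResult:
    """Overlap of per-drug consensus targets with the disease gene set.

    ``all_drugs`` intersects the disease set with the intersection over all
    drugs' consensus sets; ``any_drug`` uses their union.  Per-drug overlaps
    are reported either way.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown overlap policy {policy!r}; "
                              f"expected one of {POLICIES}")
    if not consensus:
        raise ValidationError("no drugs in consensus map")
    if not disease:
        raise ValidationError("disease gene set is empty")
    per_drug = {d: disease & targets for d, targets in consensus.items()}
    sets = list(consensus.values())
    pooled = set.intersection(*sets) if policy == "all_drugs" else set.union(*sets)
    return OverlapResult(
        consensus={d: set(t) for d, t in consensus.items()},
        disease=set(disease),
        shared=disease & pooled,
        policy=policy,
        per_drug_shared=per_drug,
    )


def overlap_to_frame(result: OverlapResult) -> pd.DataFrame:
    """Tabulate the shared genes with per-drug membership flags."""
    drugs = sorted(result.consensus)
    rows = [[g, *(g in result.consensus[d] for d in drugs)]
            for g in sorted(result.shared)]
    return pd.DataFrame(rows, columns=["gene", *drugs])
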