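"""Packaged worked-example fixtures: the 14-gene MDD drug-target network.

The worked example is a 14-node / 31-edge interaction network linking
genes shared between MDD evidence sources and the consensus targets of
fluoxetine, ketamine and esketamine, together with per-node centralities,
a whole-network topology panel before and after removal of the three hubs
(OPRM1, EGFR, GSK3B), and an 11-row table of curated transcription-factor
regulons over those genes.

The exact edge list behind the published statistics was never deposited;
only the degree sequence and the derived metrics were.  ``FROZEN_EDGES``
is one fixed realization of that degree sequence, found by a constraint
search over degree-preserving edge swaps so that it also reproduces the
published wiring-dependent statistics; it is frozen here so every value
derived from it is reproducible byte-for-byte.

The per-drug predictor target lists and the disease evidence list are
synthetic stand-ins (the originals depend on live database snapshots and
were not deposited); they are constructed so the documented consensus and
overlap rules yield exactly the published 14-gene shared set.
"""
from __future__ import annotations

from pathlib import Path

from .consensus import DrugTargetSet
from .evidence import EvidenceGeneSet
from .graph_core import InteractionNetwork
from .tf_overlay import Regulon

__all__ = [
    "TABLE1_METRICS",
    "FROZEN_PANEL",
    "DEGREE_SEQUENCE",
    "HUB_GENES",
    "SHARED_GENES",
    "FROZEN_EDGES",
    "TABLE3_REGULONS",
    "fixture_network",
    "fixture_regulons",
    "fixture_drug_predictions",
    "fixture_disease_set",
    "packaged_fixtures",
]

# gene -> (degree, betweenness, closeness) as printed in the study's
# node-metrics table
TABLE1_METRICS: dict[str, tuple[int, float, float]] = {
    "OPRM1": (7, 0.342, 0.684),
    "GSK3B": (6, 0.208, 0.590),
    "EGFR": (6, 0.286, 0.649),
    "MAOA": (6, 0.090, 0.619),
    "SLC6A3": (5, 0.022, 0.520),
    "MAOB": (5, 0.070, 0.565),
    "SLC6A4": (5, 0.022, 0.520),
    "PIK3CA": (4, 0.011, 0.481),
    "PARP1": (4, 0.011, 0.481),
    "OPRD1": (4, 0.017, 0.481),
    "KDR": (3, 0.000, 0.433),
    "SLC6A2": (3, 0.005, 0.481),
    "ADORA1": (2, 0.000, 0.448),
    "PNOC": (2, 0.000, 0.433),
}

DEGREE_SEQUENCE: list[int] = sorted(
    (v[0] for v in TABLE1_METRICS.values()), reverse=True)

HUB_GENES: list[str] = ["OPRM1", "EGFR", "GSK3B"]

#: The 14 genes shared between the disease evidence set and the consensus
#: targets of all three drugs.
SHARED_GENES: frozenset[str] = frozenset(TABLE1_METRICS)

#: One frozen 31-edge realization of the printed degree sequence that also
#: reproduces the printed wiring-dependent topology statistics.
FROZEN_EDGES: list[tuple[str, str]] = [
    ("ADORA1", "EGFR"),
    ("ADORA1", "GSK3B"),
    ("EGFR", "GSK3B"),
    ("EGFR", "KDR"),
    ("EGFR", "OPRM1"),
    ("EGFR", "PARP1"),
    ("EGFR", "PIK3CA"),
    ("GSK3B", "MAOA"),
    ("GSK3B", "MAOB"),
    ("GSK3B", "PARP1"),
    ("GSK3B", "PIK3CA"),
    ("KDR", "PARP1"),
    ("KDR", "PIK3CA"),
    ("MAOA", "MAOB"),
    ("MAOA", "OPRM1"),
    ("MAOA", "SLC6A2"),
    ("MAOA", "SLC6A3"),
    ("MAOA", "SLC6A4"),
    ("MAOB", "SLC6A2"),
    ("MAOB", "SLC6A3"),
    ("MAOB", "SLC6A4"),
    ("OPRD1", "OPRM1"),
    ("OPRD1", "PNOC"),
    ("OPRD1", "SLC6A3"),
    ("OPRD1", "SLC6A4"),
    ("OPRM1", "PNOC"),
    ("OPRM1", "SLC6A2"),
    ("OPRM1", "SLC6A3"),
    ("OPRM1", "SLC6A4"),
    ("PARP1", "PIK3CA"),
    ("SLC6A3", "SLC6A4"),
]

# TF -> (printed overlap p-value from the source database's own background,
#        target genes).  The p-values are carried as context only; the
# package recomputes its own hypergeometric against an explicit universe.
TABLE3_REGULONS: dict[str, tuple[float, tuple[str, ...]]] = {
    "NFKB": (5.74e-05, ("EGFR", "ADORA1", "GSK3B", "OPRM1")),
    "SP1": (0.000317, ("EGFR", "OPRM1", "MAOB", "KDR")),
    "YY1": (3.80e-05, ("EGFR", "OPRM1", "PARP1")),
    "SP3": (7.25e-05, ("MAOB", "OPRM1", "KDR")),
    "SP4": (2.80e-05, ("MAOB", "KDR")),
    "YBX1": (0.00022, ("EGFR", "SLC6A4")),
    "ESR1": (0.00141, ("KDR", "EGFR")),
    "STAT1": (0.00172, ("OPRM1", "EGFR")),
    "STAT3": (0.00482, ("EGFR", "OPRM1")),
    "JUN": (0.0053, ("EGFR", "OPRM1")),
    "RELA": (0.0203, ("ADORA1", "EGFR")),
}

# Wiring-dependent topology statistics of the frozen realization (baseline
# column plus one column per removed hub), rounded to 3 decimals.  These pin
# the packaged fixture; statistics that depend only on the degree sequence
# are covered by closed-form identities instead.
FROZEN_PANEL: dict[str, dict[str, float]] = {
    "original": {"diameter": 3, "radius": 2,
                 "characteristic_path_length": 1.934,
                 "clustering_coefficient": 0.679,
                 "heterogeneity": 0.338, "centralization": 0.231},
    "OPRM1": {"diameter": 6, "radius": 3,
              "characteristic_path_length": 2.397,
              "clustering_coefficient": 0.636,
              "heterogeneity": 0.374, "centralization": 0.227},
    "EGFR": {"diameter": 5, "radius": 3,
             "characteristic_path_length": 2.244,
             "clustering_coefficient": 0.597,
             "heterogeneity": 0.406, "centralization": 0.212},
    "GSK3B": {"diameter": 4, "radius": 2,
              "characteristic_path_length": 2.115,
              "clustering_coefficient": 0.672,
              "heterogeneity": 0.393, "centralization": 0.311},
}

DRUGS = ["esketamine", "fluoxetine", "ketamine"]
PREDICTORS = ["SEA", "SwissTargetPrediction", "TargetNet"]

# Synthetic drug-specific consensus extras (outside the disease list) and
# per-predictor noise (dropped by the >=2-of-3 rule).
_DRUG_EXTRAS: dict[str, list[str]] = {
    "fluoxetine": ["HTR1A", "HTR2A", "HTR2C", "CHRM1"],
    "ketamine": ["GRIN1", "GRIN2B", "NTRK2"],
    "esketamine": ["GRIN2A", "MTOR", "AKT1"],
}
_DRUG_NOISE: dict[str, dict[str, list[str]]] = {
    "fluoxetine": {"SwissTargetPrediction": ["CYP2D6"], "SEA": ["ABCB1"],
                   "TargetNet": ["HRH1"]},
    "ketamine": {"SwissTargetPrediction": ["SIGMAR1"], "SEA": ["CHRNA7"],
                 "TargetNet": ["HCN1"]},
    "esketamine": {"SwissTargetPrediction": ["DRD2"], "SEA": ["CACNA1C"],
                   "TargetNet": ["KCNQ2"]},
}
_DISEASE_EXTRAS = ["BDNF", "IL6", "TNF", "COMT", "TPH2", "NR3C1", "FKBP5",
                   "CRHR1"]


def fixture_network() -> InteractionNetwork:
    """The frozen 14-node / 31-edge interaction network."""
    return InteractionNetwork.from_edges(FROZEN_EDGES)


def fixture_regulons() -> list[Regulon]:
    """The 11 curated TF regulons over the network genes."""
    return [Regulon(tf=tf, targets=set(targets),
                    modes={t: "Unknown" for t in targets})
            for tf, (_, targets) in TABLE3_REGULONS.items()]


def fixture_drug_predictions() -> list[DrugTargetSet]:
    """Synthetic per-predictor target lists for the three drugs.

    Every shared gene appears in all three predictors of every drug;
    drug-specific extras appear in exactly two predictors; one noise gene
    per predictor appears nowhere else, so the 2-of-3 consensus keeps the
    shared genes plus the extras and drops the noise.
    """
    out = []
    for drug in DRUGS:
        extras = _DRUG_EXTRAS[drug]
        for i, predictor in enumerate(PREDICTORS):
            genes = set(SHARED_GENES)
            # each extra is missing from exactly one predictor (round-robin)
            genes |= {g for j, g in enumerate(extras) if j % 3 != i}
            genes |= set(_DRUG_NOISE[drug].get(predictor, []))
            out.append(DrugTargetSet(drug=drug, predictor=predictor,
                                     genes=frozenset(genes)))
    return out


def fixture_disease_set() -> EvidenceGeneSet:
    """Synthetic disease evidence list: the shared genes plus MDD-associated
    genes that are not drug consensus targets."""
    return EvidenceGeneSet(
        source_name="disease_evidence",
        genes=frozenset(SHARED_GENES) | frozenset(_DISEASE_EXTRAS))


def packaged_fixtures(outdir: str | Path) -> Path:
    """Write all packaged fixtures as plain-text files under ``outdir``.

    Emits the node-metrics table, the frozen edge realization, the TF
    regulon table (TRRUST dialect), the 14-gene shared set, and the
    synthetic drug-prediction and disease-evidence inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "node_metrics.tsv", "w") as fh:
        fh.write("gene\tdegree\tbetweenness\tcloseness\n")
        for gene, (deg, bet, clo) in TABLE1_METRICS.items():
            fh.write(f"{gene}\t{deg}\t{bet}\t{clo}\n")

    fixture_network().to_tsv(outdir / "network_edges.tsv")

    with open(outdir / "tf_regulons.tsv", "w") as fh:
        for tf, (_, targets) in TABLE3_REGULONS.items():
            for t in targets:
                fh.write(f"{tf}\t{t}\tUnknown\t-\n")

    (outdir / "shared_genes.txt").write_text(
        "\n".join(sorted(SHARED_GENES)) + "\n")

    with open(outdir / "drug_targets.tsv", "w") as fh:
        fh.write("drug\tpredictor\tgene\n")
        for pred in fixture_drug_predictions():
            for g in sorted(pred.genes):
                fh.write(f"{pred.drug}\t{pred.predictor}\t{g}\n")

    (outdir / "disease_genes.txt").write_text(
        "\n".join(sorted(fixture_disease_set().genes)) + "\n")
    return outdir
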