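"""End-to-end orchestration: run the pipeline stages named in a config
mapping, write per-stage TSV/JSON outputs and a manifest, and collate a
final report.

A config is a plain mapping (usually loaded from YAML).  Each stage runs
only if its section is present, in the fixed order

    evidence -> consensus -> network -> topology -> mcode -> fragility
    -> enrichment -> tf

Cross-stage references (e.g. fragility needs a network) are validated
before anything executes.  Stage failures stop the run with the manifest
marking the failed stage; prior outputs are kept.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import (consensus_by_drug, disease_overlap, load_drug_targets,
                        overlap_to_frame)
from .enrichment import cluster_terms, enrich, load_gmt
from .errors import ValidationError
from .evidence import (load_gene_list, load_synonym_map,
                       multi_evidence_intersect, unify_identifiers)
from .fragility import fragility_analysis
from .graph_core import build_network, metric_panel, node_metrics, rank_hubs
from .mcode import find_complexes
from .tf_overlay import load_trrust, tf_coverage

logger = logging.getLogger(__name__)

STAGE_ORDER = ["evidence", "consensus", "network", "topology", "mcode",
               "fragility", "enrichment", "tf"]

__all__ = ["load_config", "validate_config", "run_pipeline", "make_report"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> list[str]:
    """Return the stages that will run; raise on broken cross-references."""
    stages = [s for s in STAGE_ORDER if s in cfg]
    if not stages:
        raise ValidationError("config names no pipeline stages")
    needs_network = [s for s in ("topology", "mcode", "fragility") if s in cfg]
    if needs_network and "network" not in cfg:
        raise ValidationError(
            f"stage(s) {needs_network} require a 'network' section")
    for stage in stages:
        section = cfg[stage] or {}
        for key in ("sources", "drug_targets", "edges", "annotation",
                    "universe", "trrust", "synonyms", "disease", "hits"):
            value = section.get(key)
            paths = value.values() if isinstance(value, dict) else [value]
            for p in paths:
                if isinstance(p, str) and not Path(p).exists():
                    raise ValidationError(
                        f"{stage}.{key}: file not found: {p}")
    return stages


def _read_genes(path: str) -> set[str]:
    return set(load_gene_list(path, source_name=Path(path).stem).genes)


def run_pipeline(cfg: dict, outdir: str | Path) -> Path:
    """Execute the configured stages and write outputs under ``outdir``."""
    stages = validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed", 0),
        "stages": {},
    }

    state: dict = {}
    for i, stage in enumerate(stages):
        try:
            _STAGE_RUNNERS[stage](cfg[stage] or {}, cfg, state, outdir)
        except Exception:
            manifest["stages"][stage] = "failed"
            for later in stages[i + 1:]:
                manifest["stages"][later] = "skipped"
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2))
            raise
        manifest["stages"][stage] = "completed"
        logger.info("stage %s completed", stage)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _run_evidence(section, cfg, state, outdir):
    sets = [load_gene_list(path, name)
            for name, path in section["sources"].items()]
    if section.get("synonyms"):
        sets = unify_identifiers(sets, load_synonym_map(section["synonyms"]))
    matrix = multi_evidence_intersect(sets, section.get("min_sources", 2))
    matrix.to_tsv(outdir / "evidence_retained.tsv")
    (outdir / "evidence_venn.json").write_text(json.dumps({
        "sources": matrix.sources,
        "min_sources": matrix.min_sources,
        "regions": matrix.venn,
        "n_retained": len(matrix.genes),
    }, indent=2))
    state["evidence_genes"] = matrix.genes
    state["evidence_union"] = set().union(*(s.genes for s in sets))


def _run_consensus(section, cfg, state, outdir):
    predictions = load_drug_targets(section["drug_targets"])
    consensus = consensus_by_drug(predictions,
                                  section.get("min_agreement", 2))
    if section.get("disease"):
        disease = _read_genes(section["disease"])
    elif "evidence_genes" in state:
        disease = state["evidence_genes"]
    else:
        raise ValidationError(
            "consensus needs a 'disease' file or an evidence stage")
    result = disease_overlap(consensus, disease,
                             section.get("policy", "all_drugs"))
    pd.DataFrame(
        [(d, len(t), ",".join(sorted(t))) for d, t in consensus.items()],
        columns=["drug", "n_targets", "targets"],
    ).to_csv(outdir / "consensus_targets.tsv", sep="\t", index=False)
    overlap_to_frame(result).to_csv(outdir / "shared_genes.tsv",
                                    sep="\t", index=False)
    (outdir / "overlap_summary.json").write_text(json.dumps({
        "policy": result.policy,
        "n_shared": len(result.shared),
        "shared": sorted(result.shared),
        "per_drug_shared": {d: sorted(s)
                            for d, s in result.per_drug_shared.items()},
    }, indent=2))
    state["shared_genes"] = result.shared


def _run_network(section, cfg, state, outdir):
    net = build_network(section["edges"], section.get("dialect", "tsv"))
    net.to_tsv(outdir / "network_edges.tsv")
    state["network"] = net


def _run_topology(section, cfg, state, outdir):
    net = state["network"]
    metrics = node_metrics(net)
    ranked = rank_hubs(metrics)
    ranked.round(3).to_csv(outdir / "node_metrics.tsv", sep="\t")
    panel = metric_panel(net)
    (outdir / "metric_panel.json").write_text(
        json.dumps(panel.to_dict(ndigits=3), indent=2))
    state["panel"] = panel
    state["hub_ranking"] = ranked


def _run_mcode(section, cfg, state, outdir):
    complexes = find_complexes(
        state["network"],
        node_score_cutoff=section.get("node_score_cutoff", 0.2),
        k_core=section.get("k_core", 2),
        haircut=section.get("haircut", True),
    )
    rows = [[i + 1, c.seed, c.n_nodes, c.n_edges, round(c.score, 3),
             ",".join(sorted(c.members))]
            for i, c in enumerate(complexes)]
    pd.DataFrame(rows, columns=["rank", "seed", "n_nodes", "n_edges",
                                "score", "members"]
                 ).to_csv(outdir / "mcode_complexes.tsv", sep="\t", index=False)
    state["complexes"] = complexes


def _run_fragility(section, cfg, state, outdir):
    report = fragility_analysis(state["network"], section["hubs"])
    report.to_frame(ndigits=3).to_csv(outdir / "fragility_panel.tsv", sep="\t")
    (outdir / "fragility_deltas.json").write_text(json.dumps(
        {g: {m: round(v, 6) for m, v in d.items()}
         for g, d in report.deltas.items()}, indent=2))
    state["fragility"] = report


def _run_enrichment(section, cfg, state, outdir):
    annotations = load_gmt(section["annotation"],
                           section.get("category", "default"))
    universe = _read_genes(section["universe"])
    if section.get("hits"):
        hits = _read_genes(section["hits"])
    elif "shared_genes" in state:
        hits = state["shared_genes"]
    else:
        raise ValidationError(
            "enrichment needs a 'hits' file or a consensus stage")
    rows = enrich(hits, annotations, universe,
                  min_hits=section.get("min_hits", 2))
    if not rows.empty:
        clusters = cluster_terms(rows, annotations,
                                 threshold=section.get("kappa_threshold", 0.3),
                                 domain=hits)
        cluster_of = {t: i + 1 for i, c in enumerate(clusters)
                      for t in c.members}
        rep = {c.representative for c in clusters}
        rows["cluster_id"] = rows["term_id"].map(cluster_of)
        rows["representative"] = rows["term_id"].isin(rep)
    rows.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    state["enrichment"] = rows


def _run_tf(section, cfg, state, outdir):
    regulons = load_trrust(section["trrust"])
    key = {g.strip().upper() for g in section["key_genes"]}
    if "network" in state:
        network_genes = state["network"].nodes
    else:
        network_genes = set().union(*(r.targets for r in regulons)) | key
    if section.get("universe"):
        universe = _read_genes(section["universe"])
    else:
        universe = network_genes | set().union(*(r.targets for r in regulons))
    coverage = tf_coverage(regulons, key, network_genes, universe)
    coverage.to_csv(outdir / "tf_coverage.tsv", sep="\t", index=False)
    state["tf_coverage"] = coverage


_STAGE_RUNNERS = {
    "evidence": _run_evidence,
    "consensus": _run_consensus,
    "network": _run_network,
    "topology": _run_topology,
    "mcode": _run_mcode,
    "fragility": _run_fragility,
    "enrichment": _run_enrichment,
    "tf": _run_tf,
}


def make_report(run_dir: str | Path) -> Path:
    """Collate stage outputs into report.json and a readable report.txt.

    Missing stage outputs are listed as absent rather than fatal, so partial
    runs still produce a report.
    """
    run_dir = Path(run_dir)
    report: dict = {"run_dir": str(run_dir), "sections": {}}
    lines: list[str] = ["netpharm run report", "=" * 19, ""]

    def section(name, filename, parser):
        path = run_dir / filename
        if not path.exists():
            report["sections"][name] = None
            lines.append(f"[{name}] absent")
            return
        report["sections"][name] = parser(path)

    def read_json(path):
        return json.loads(path.read_text())

    def read_tsv(path):
        return pd.read_csv(path, sep="\t").to_dict(orient="records")

    section("manifest", "manifest.json", read_json)
    section("evidence_venn", "evidence_venn.json", read_json)
    section("overlap", "overlap_summary.json", read_json)
    section("hub_ranking", "node_metrics.tsv", read_tsv)
    section("metric_panel", "metric_panel.json", read_json)
    section("mcode", "mcode_complexes.tsv", read_tsv)
    section("tf_coverage", "tf_coverage.tsv", read_tsv)

    frag = run_dir / "fragility_panel.tsv"
    if frag.exists():
        table = pd.read_csv(frag, sep="\t", index_col=0)
        report["sections"]["fragility"] = {
            metric: [row[c] for c in table.columns]
            for metric, row in table.iterrows()}
        lines.append("Fragility panel (rows: metric; cols: "
                     + ", ".join(table.columns) + ")")
        lines.append(table.to_string())
        lines.append("")
    else:
        report["sections"]["fragility"] = None
        lines.append("[fragility] absent")

    if report["sections"].get("hub_ranking"):
        lines.append("Hub ranking (degree, betweenness, closeness):")
        for row in report["sections"]["hub_ranking"][:5]:
            lines.append(f"  {row['gene']}: DG={row['degree']} "
                         f"BS={row['betweenness']} CS={row['closeness']}")
        lines.append("")

    (run_dir / "report.json").write_text(json.dumps(report, indent=2))
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return run_dir / "report.json"
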