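"""End-to-end orchestration: DE screening -> membership -> networks -> hubs.

The pipeline is driven by one declarative YAML config and writes every stage
output to disk (DE tables, membership table, per-category networks, hub
reports, axes) plus a machine-readable ``report.json``. Runs are
deterministic: the report contains no timestamps, and identical config +
seed produce byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import yaml

from . import __version__
from .cerna import (
    assemble,
    consensus_targets,
    export_network,
    load_evidence,
    network_summary,
)
from .diffexpr import (
    CATEGORY_LABELS,
    ExpressionDataset,
    build_membership,
    call_degs,
    intersect_datasets,
    run_de,
    venn_counts,
)
from .enrichment import AnnotationCollection, run_ora, write_ora_tsv
from .errors import ConfigError
from .gene_sets import GeneSet, read_gene_list
from .hubs import (
    CentralityConfig,
    compute_centralities,
    consensus_hubs,
    dedup_axes,
    extract_axes,
)
from .synthetic import write_axes_tsv

logger = logging.getLogger("cernakit.pipeline")

DEFAULT_THRESHOLDS = {
    "p_cut": 0.05,
    "lfc_cut": 1.0,
    "mirna_min_support": 3,
    "lncrna_min_support": 2,
    "k_top": 10,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config`` for the YAML
    schema)."""

    datasets: list  # dicts: label, expression, groups, platform[, transform]
    gene_lists: list  # dicts: path, category, provenance
    mirna_evidence: list  # TSV paths, miRNA->mRNA sources
    lncrna_evidence: list  # TSV paths, lncRNA->miRNA sources
    thresholds: dict = field(default_factory=dict)
    epc: dict = field(default_factory=dict)
    seed: int = 0
    require_lncrna_partner: bool = False
    annotations: str | None = None
    output_dir: str = "cernakit_out"

    def __post_init__(self):
        if len(self.datasets) < 2:
            raise ConfigError("need >= 2 datasets for the intersection stage")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds or {})
        self.thresholds = merged
        if not (0.0 <= self.thresholds["p_cut"] <= 1.0):
            raise ConfigError("p_cut must be in [0, 1]")
        if self.thresholds["lfc_cut"] < 0:
            raise ConfigError("lfc_cut must be >= 0")
        for key in ("mirna_min_support", "lncrna_min_support", "k_top"):
            if int(self.thresholds[key]) < 1:
                raise ConfigError(f"{key} must be >= 1")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    evidence = raw.get("evidence", {})
    return PipelineConfig(
        datasets=raw.get("datasets", []),
        gene_lists=raw.get("gene_lists", []),
        mirna_evidence=evidence.get("mirna", []),
        lncrna_evidence=evidence.get("lncrna", []),
        thresholds=raw.get("thresholds", {}),
        epc=raw.get("epc", {}),
        seed=int(raw.get("seed", 0)),
        require_lncrna_partner=bool(raw.get("require_lncrna_partner", False)),
        annotations=raw.get("annotations"),
        output_dir=raw.get("output_dir", "cernakit_out"),
    )


def _config_echo(config: PipelineConfig) -> dict:
    return {
        "datasets": config.datasets,
        "gene_lists": config.gene_lists,
        "evidence": {"mirna": config.mirna_evidence,
                     "lncrna": config.lncrna_evidence},
        "thresholds": config.thresholds,
        "epc": config.epc,
        "seed": config.seed,
        "require_lncrna_partner": config.require_lncrna_partner,
        "annotations": config.annotations,
    }


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute every stage and return the run report (also written to
    ``<outdir>/report.json``)."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
    }
    th = config.thresholds

    # stage 1: per-dataset differential expression
    degs_by_dataset: Dict[str, Dict[str, str]] = {}
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    de_counts = {}
    for entry in config.datasets:
        dataset = ExpressionDataset.from_tsv(
            entry["expression"], entry["groups"], entry["platform"],
            label=entry["label"])
        result = run_de(dataset, transform=entry.get("transform"))
        result.to_csv(de_dir / f"{entry['label']}_de.tsv", sep="\t")
        degs = call_degs(result, p_cut=th["p_cut"], lfc_cut=th["lfc_cut"])
        degs_by_dataset[entry["label"]] = degs
        de_counts[entry["label"]] = len(degs)
        logger.info("DE %s: %d genes in, %d DEGs out",
                    entry["label"], len(result), len(degs))

    # stage 2: intersection + membership
    common = intersect_datasets(degs_by_dataset)
    pcd_sets: List[GeneSet] = [
        read_gene_list(e["path"], e["category"], e.get("provenance", "file"))
        for e in config.gene_lists
    ]
    membership = build_membership(common, pcd_sets)
    membership.to_tsv(outdir / "membership.tsv")
    logger.info("membership: %d common DEGs, %d PCD-related rows",
                len(common), len(membership))
    report["de_counts"] = de_counts
    report["common_deg_count"] = len(common)
    report["membership"] = {
        "rows": len(membership),
        "category_counts": membership.category_counts(),
        "venn": {"+".join(sorted(k)): v for k, v in venn_counts(membership).items()},
    }

    # stage 3 (optional): enrichment per category
    if config.annotations:
        collection = AnnotationCollection.from_gmt(config.annotations)
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        for s in pcd_sets:
            label = CATEGORY_LABELS[s.category]
            query = GeneSet.from_symbols(
                name=label, category=s.category,
                raw_symbols=membership.genes_in_category(label))
            if len(query) == 0:
                continue
            result = run_ora(query, collection)
            write_ora_tsv(result, enr_dir / f"{label}.tsv")

    # stage 4: consensus voting + per-category assembly
    mirna_evidence = load_evidence(config.mirna_evidence)
    lncrna_evidence = load_evidence(config.lncrna_evidence)
    mirna_consensus = consensus_targets(mirna_evidence, "miRNA",
                                        int(th["mirna_min_support"]))
    lncrna_consensus = consensus_targets(lncrna_evidence, "lncRNA",
                                         int(th["lncrna_min_support"]))
    logger.info("consensus: %d miRNA->mRNA pairs, %d lncRNA->miRNA pairs",
                len(mirna_consensus), len(lncrna_consensus))

    net_dir = outdir / "networks"
    hub_dir = outdir / "hubs"
    hub_dir.mkdir(exist_ok=True)
    centrality_config = CentralityConfig(
        k_top=int(th["k_top"]),
        epc_realizations=int(config.epc.get("realizations", 1000)),
        epc_retention=float(config.epc.get("retention", 0.5)),
        seed=config.seed,
    )
    report["networks"] = {}
    all_axes = []
    for s in pcd_sets:
        label = CATEGORY_LABELS[s.category]
        mrnas = membership.genes_in_category(label)
        entry = {"mrna_inputs": len(mrnas)}
        if mrnas:
            net = assemble(mrnas, mirna_consensus, lncrna_consensus,
                           label=s.category,
                           require_lncrna_partner=config.require_lncrna_partner)
            export_network(net, net_dir, stem=s.category)
            entry["summary"] = network_summary(net)
            if net.nodes:
                # stage 5: hubs + axes
                centralities = compute_centralities(net, centrality_config)
                hubs = consensus_hubs(centralities)
                hubs.membership_frame().to_csv(
                    hub_dir / f"{s.category}_membership.tsv", sep="\t")
                _write_scores(centralities, hub_dir / f"{s.category}_scores.tsv")
                axes = extract_axes(net, hubs)
                all_axes.extend(axes)
                entry["hubs"] = [f"{n.kind}:{n.id}" for n in hubs.hubs]
                entry["axes"] = [list(a.triple) for a in axes]
                logger.info("network %s: %s; %d hubs, %d axes", s.category,
                            entry["summary"], len(hubs.hubs), len(axes))
            else:
                entry["hubs"], entry["axes"] = [], []
        else:
            entry["summary"] = {"lncRNAs": 0, "miRNAs": 0, "mRNAs": 0,
                                "nodes": 0, "edges": 0}
            entry["hubs"], entry["axes"] = [], []
        report["networks"][s.category] = entry

    # stage 6: axis dedup across networks
    write_axes_tsv(all_axes, outdir / "axes.tsv")
    unique = dedup_axes(all_axes)
    report["unique_axes"] = [
        {"lncRNA": a.lncrna, "miRNA": a.mirna, "mRNA": a.mrna,
         "networks": sorted(a.networks)}
        for a in unique
    ]
    report["unique_axis_count"] = len(unique)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _write_scores(centralities, path) -> None:
    import pandas as pd

    nodes = sorted({n for sc in centralities.scores.values() for n in sc})
    frame = pd.DataFrame(
        {alg: [centralities.scores[alg][n] for n in nodes]
         for alg in centralities.scores},
        index=[f"{n.kind}:{n.id}" for n in nodes],
    )
    frame.index.name = "node"
    frame.to_csv(path, sep="\t")
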