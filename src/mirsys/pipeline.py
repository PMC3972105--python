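"""End-to-end orchestration: simulate-or-load, then every analysis stage.

Stage order follows the study workflow: differential expression (SAM) ->
overlap with the curated disease list and Group 1/2 partition -> consensus
target filtering -> enrichment per group -> tripartite regulatory network
and IR hubs per group -> pooled co-expression network with topological
metrics and degree hubs -> hierarchical clustering -> cross-network hub
summary (novel hubs = hubs outside the curated list; common hubs = miRs
that are hubs in both network types).

Every intermediate is written as a plain file in the standard formats, so
each stage is independently inspectable and re-runnable; the machine-
readable run report is deterministic under a fixed seed (byte-identical
JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from . import coexpr, enrichment, hclust, overlap, regnet, sam, targets
from .io import (ExpressionDataset, GRAPHML_DIALECT, SIF_DIALECT,
                 canonical_mir, read_expression, read_gmt, read_target_table,
                 read_tf_table, write_network)
from .synth import SimConfig, SimulatedInputs, simulate, write_inputs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs: inputs (files or simulation) + knobs."""

    # either simulate ...
    sim: Optional[SimConfig] = None
    # ... or load from files
    expression: Optional[str] = None
    metadata: Optional[str] = None
    known_list: Optional[str] = None
    tf_table: Optional[str] = None
    target_table: Optional[str] = None
    annotations: Optional[str] = None

    sam_params: sam.SamParams = field(default_factory=sam.SamParams)
    background: Optional[int] = None     # overlap universe; default n_probes
    min_score: float = targets.DEFAULT_MIN_SCORE
    consensus: int = 3
    top_k: int = targets.DEFAULT_TOP_K
    alpha: float = 0.05
    top_n_terms: int = 20
    use_adjusted: bool = False
    ir_threshold: int = regnet.DEFAULT_IR_THRESHOLD
    r_min: float = coexpr.DEFAULT_R_MIN
    hub_fraction: float = coexpr.DEFAULT_HUB_FRACTION
    n_clusters: int = 6
    out_dir: str = "mirsys_out"
    seed: int = 0

    def __post_init__(self):
        if self.sim is None and self.expression is None:
            self.sim = SimConfig(seed=self.seed)
        if self.sim is not None:
            self.sim.seed = self.seed
        self.sam_params.seed = self.seed


@dataclass
class GroupResult:
    """Per-group (1 or 2) target/enrichment/regulatory-network outputs."""

    mirs: List[str]
    filtered_targets: pd.DataFrame
    unique_genes: int
    enrichment: pd.DataFrame
    network_mirs: List[str]
    hub_report: Optional[regnet.HubReport]

    @property
    def ir_hub_names(self) -> List[str]:
        if self.hub_report is None:
            return []
        return list(self.hub_report.rows["miR"])


@dataclass
class RunReport:
    """Machine-readable per-stage counts plus the novel-hub summary."""

    seed: int
    n_probes: int
    n_samples: int
    s0: float
    delta: float
    n_de: int
    n_known: int
    n_group1: int
    n_group2: int
    overlap_p: float
    n_ir_hubs: Dict[str, int]
    ir_hubs: Dict[str, List[str]]
    n_coexpr_nodes: int
    n_coexpr_edges: int
    coexpr_hub_cutoff: float
    coexpr_hubs: List[str]
    cluster_sizes: List[int]
    novel_hubs: List[str]
    common_hubs: List[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def common_hubs(ir_hubs: Iterable[str], coexpr_hubs: Iterable[str],
                known: Iterable[str]) -> Tuple[List[str], List[str]]:
    """(novel, common) hub sets across the two network types.

    novel = (IR hubs ∪ co-expression hubs) \\ known;
    common = IR hubs ∩ co-expression hubs.
    """
    ir_set, co_set, known_set = set(ir_hubs), set(coexpr_hubs), set(known)
    novel = sorted((ir_set | co_set) - known_set)
    common = sorted(ir_set & co_set)
    return novel, common


def _load_inputs(config: RunConfig, out: Path):
    if config.expression is not None:
        dataset = read_expression(config.expression, config.metadata)
        known = [canonical_mir(line) for line in
                 Path(config.known_list).read_text().splitlines()
                 if line.strip()]
        tf_table = read_tf_table(config.tf_table)
        target_table = read_target_table(config.target_table)
        annotations = read_gmt(config.annotations)
        return dataset, known, tf_table, target_table, annotations
    sim_bundle: SimulatedInputs = simulate(config.sim)
    write_inputs(sim_bundle, out / "inputs")
    return (sim_bundle.dataset, sim_bundle.known_list, sim_bundle.tf_table,
            sim_bundle.target_table, sim_bundle.annotations)


def _analyse_group(name: str, mirs: List[str], tf_table: pd.DataFrame,
                   target_table: pd.DataFrame, annotations, config: RunConfig,
                   out: Path) -> GroupResult:
    """Targets -> enrichment -> tripartite network for one miR group."""
    group_targets = target_table[target_table["miR"].isin(set(mirs))]
    if len(group_targets):
        filtered = targets.consensus_targets(group_targets, config.consensus)
        filtered = targets.filter_by_score(filtered, config.min_score)
        filtered = targets.top_k_targets(filtered, config.top_k)
    else:
        filtered = group_targets.copy()
    filtered.to_csv(out / f"targets_{name}.tsv", sep="\t", index=False)
    unique_genes = targets.unique_target_genes(mirs, filtered)

    background = set(target_table["gene"])
    for gs in annotations.values():
        background |= set(gs.genes)
    if unique_genes:
        rows = enrichment.enrich(unique_genes, annotations, background)
    else:
        rows = pd.DataFrame(columns=enrichment.ENRICHMENT_COLUMNS)
    rows.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    sig = enrichment.significant_terms(rows, config.alpha,
                                       config.use_adjusted)

    mir_to_genes = {m: targets.unique_target_genes([m], filtered)
                    for m in mirs}
    network_mirs = enrichment.mirs_for_top_terms(sig, annotations,
                                                 mir_to_genes,
                                                 config.top_n_terms)
    hub_report = None
    if network_mirs:
        net = regnet.build_tripartite(tf_table, filtered, network_mirs)
        hub_report = regnet.select_ir_hubs(net, config.ir_threshold)
        hub_report.rows.to_csv(out / f"regnet_{name}_hubs.tsv", sep="\t",
                               index=False)
        hub_report.tf_ranking.to_csv(out / f"regnet_{name}_tf_ranking.tsv",
                                     sep="\t", index=False)
        write_network(net.to_networkx(), out / f"regnet_{name}.sif",
                      SIF_DIALECT)
        write_network(net.to_networkx(), out / f"regnet_{name}.graphml",
                      GRAPHML_DIALECT)
    logger.info("group %s: %d miRs, %d unique targets, %d network miRs, "
                "%d IR hubs", name, len(mirs), len(unique_genes),
                len(network_mirs),
                0 if hub_report is None else len(hub_report.rows))
    return GroupResult(mirs=mirs, filtered_targets=filtered,
                       unique_genes=len(unique_genes), enrichment=rows,
                       network_mirs=network_mirs, hub_report=hub_report)


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline; writes every stage's output, returns report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, known, tf_table, target_table, annotations = _load_inputs(config,
                                                                       out)

    # differential expression
    result = sam.permutation_fdr(dataset, config.sam_params)
    de = sam.select_de(result)
    result.table.to_csv(out / "de_results.tsv", sep="\t",
                        index_label="miR")
    (out / "de_summary.json").write_text(json.dumps({
        "s0": result.s0, "delta": result.delta, "n_called": result.n_called,
        "exhaustive": result.exhaustive,
    }, indent=1, sort_keys=True))
    logger.info("SAM: %d/%d miRs called at FDR target %g (s0=%.4g)",
                len(de), len(dataset.probe_names),
                config.sam_params.fdr_target, result.s0)

    # overlap with the curated list
    background = config.background or len(dataset.probe_names)
    background = max(background, len(set(de) | set(known)))
    ov = overlap.overlap_significance(de, known, background)
    (out / "overlap.json").write_text(json.dumps(ov.to_dict(), indent=1,
                                                 sort_keys=True))
    (out / "group1.txt").write_text("\n".join(ov.group1) + "\n")
    (out / "group2.txt").write_text("\n".join(ov.group2) + "\n")

    groups = {
        "group1": _analyse_group("group1", ov.group1, tf_table, target_table,
                                 annotations, config, out),
        "group2": _analyse_group("group2", ov.group2, tf_table, target_table,
                                 annotations, config, out),
    }

    # co-expression network over the DE miRs, pooled samples
    coexpr_hub_names: List[str] = []
    cutoff = 0.0
    n_nodes = n_edges = 0
    if de:
        graph = coexpr.coexpression_graph(dataset, de, r_min=config.r_min)
        n_nodes, n_edges = graph.number_of_nodes(), graph.number_of_edges()
        if n_nodes:
            coexpr.annotate_graph(graph)
            coexpr.node_metrics(graph).to_csv(out / "coexpr_metrics.tsv",
                                              sep="\t", index_label="miR")
            coexpr.summarize_nodes(graph).to_csv(out / "coexpr_summary.tsv",
                                                 sep="\t",
                                                 index_label="metric")
            hubs = coexpr.select_degree_hubs(graph, config.hub_fraction)
            hubs.table.to_csv(out / "coexpr_hubs.tsv", sep="\t", index=False)
            write_network(graph, out / "coexpr.graphml", GRAPHML_DIALECT)
            coexpr_hub_names = hubs.names
            cutoff = hubs.cutoff
    logger.info("co-expression: %d nodes, %d edges, %d degree hubs",
                n_nodes, n_edges, len(coexpr_hub_names))

    # hierarchical clustering of the DE miRs
    cluster_sizes: List[int] = []
    if len(de) >= 2:
        k = min(config.n_clusters, len(de))
        assignment, _ = hclust.cluster_expression(dataset, k, de)
        frame = pd.DataFrame(sorted(assignment.items()),
                             columns=["miR", "cluster"])
        frame.to_csv(out / "clusters.tsv", sep="\t", index=False)
        cluster_sizes = [int(c) for c in
                         frame["cluster"].value_counts().sort_index()]

    ir_all = sorted(set(groups["group1"].ir_hub_names)
                    | set(groups["group2"].ir_hub_names))
    novel, common = common_hubs(ir_all, coexpr_hub_names, known)

    report = RunReport(
        seed=config.seed,
        n_probes=len(dataset.probe_names),
        n_samples=len(dataset.sample_names),
        s0=round(result.s0, 10), delta=round(result.delta, 10)
        if result.delta != float("inf") else -1.0,
        n_de=len(de), n_known=ov.n_known,
        n_group1=len(ov.group1), n_group2=len(ov.group2),
        overlap_p=round(ov.p_value, 12),
        n_ir_hubs={g: len(r.ir_hub_names) for g, r in groups.items()},
        ir_hubs={g: r.ir_hub_names for g, r in groups.items()},
        n_coexpr_nodes=n_nodes, n_coexpr_edges=n_edges,
        coexpr_hub_cutoff=round(cutoff, 10), coexpr_hubs=coexpr_hub_names,
        cluster_sizes=cluster_sizes,
        novel_hubs=novel, common_hubs=common,
    )
    (out / "run_report.json").write_text(report.to_json())
    return report
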