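"""Tripartite TF -> miR -> mRNA regulatory network and IR hub scoring.

The network has three strict layers: transcription factors on top, miRs in
the middle, target mRNAs at the bottom, with edges only across adjacent
layers.  Each miR's importance as an intermediate regulator is scored as

    IR = m * n

where m is its in-degree (number of distinct regulating TFs) and n its
out-degree (number of retained high-confidence targets, capped by the
upstream top-k filter).  Hub miRs are those with IR at or above a threshold
(default 70, boundary inclusive).  TFs are ranked by the number of miRs
they regulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import networkx as nx
import pandas as pd

DEFAULT_IR_THRESHOLD = 70


class LayerViolationError(ValueError):
    """A name appeared in two layers of one network instance."""


@dataclass
class TripartiteNetwork:
    """Three-layer directed network with per-miR (m, n, IR) statistics."""

    tf_edges: List[Tuple[str, str]]      # (TF, miR), deduplicated
    target_edges: List[Tuple[str, str]]  # (miR, gene)
    mirs: Tuple[str, ...]
    stats: pd.DataFrame                  # index miR; columns m, n, ir

    @property
    def tfs(self) -> List[str]:
        return sorted({tf for tf, _ in self.tf_edges})

    @property
    def genes(self) -> List[str]:
        return sorted({g for _, g in self.target_edges})

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf in self.tfs:
            g.add_node(tf, layer="TF")
        for mir in self.mirs:
            g.add_node(mir, layer="miR",
                       m=int(self.stats.loc[mir, "m"]),
                       n=int(self.stats.loc[mir, "n"]),
                       ir=int(self.stats.loc[mir, "ir"]))
        for gene in self.genes:
            g.add_node(gene, layer="gene")
        for tf, mir in self.tf_edges:
            g.add_edge(tf, mir, interaction="regulates")
        for mir, gene in self.target_edges:
            g.add_edge(mir, gene, interaction="targets")
        return g


@dataclass
class HubReport:
    """IR hubs at a threshold, plus the TF out-degree ranking."""

    rows: pd.DataFrame        # miR, m, n, ir — ir desc, name asc; all >= threshold
    threshold: int
    tf_ranking: pd.DataFrame  # TF, out_degree — desc, name asc


def ir_score(m: int, n: int) -> int:
    """Intermediate-regulation score: in-degree times out-degree."""
    if m < 0 or n < 0:
        raise ValueError("degrees must be non-negative")
    return int(m) * int(n)


def build_tripartite(tf_table: pd.DataFrame, filtered_targets: pd.DataFrame,
                     mir_subset: Iterable[str]) -> TripartiteNetwork:
    """Assemble the three-layer network for the given miRs.

    ``filtered_targets`` should already have consensus, score and top-k
    filters applied.  Duplicate TF->miR records collapse to one edge (m
    counts distinct regulators).  miRs with no recorded TF are retained
    with m = 0 (hence IR = 0).  A name occurring in two layers raises
    :class:`LayerViolationError`.
    """
    mirs = tuple(sorted(set(mir_subset)))
    mir_set = set(mirs)
    tf_edges = sorted({(tf, mir) for tf, mir in
                       zip(tf_table["TF"], tf_table["miR"]) if mir in mir_set})
    target_edges = sorted({(mir, gene) for mir, gene in
                           zip(filtered_targets["miR"],
                               filtered_targets["gene"]) if mir in mir_set})
    tfs = {tf for tf, _ in tf_edges}
    genes = {g for _, g in target_edges}
    for a, b, what in ((tfs, mir_set, "TF/miR"), (tfs, genes, "TF/gene"),
                       (mir_set, genes, "miR/gene")):
        shared = a & b
        if shared:
            raise LayerViolationError(
                f"names present in both {what} layers: {sorted(shared)}"
            )
    m_counts = {mir: 0 for mir in mirs}
    for _, mir in tf_edges:
        m_counts[mir] += 1
    n_counts = {mir: 0 for mir in mirs}
    for mir, _ in target_edges:
        n_counts[mir] += 1
    stats = pd.DataFrame({
        "m": [m_counts[m] for m in mirs],
        "n": [n_counts[m] for m in mirs],
    }, index=list(mirs))
    stats["ir"] = stats["m"] * stats["n"]
    return TripartiteNetwork(tf_edges, target_edges, mirs, stats)


def tf_outdegree_ranking(network: TripartiteNetwork) -> pd.DataFrame:
    """TFs sorted by number of regulated miRs descending, then name."""
    counts: dict = {}
    for tf, _ in network.tf_edges:
        counts[tf] = counts.get(tf, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["TF", "out_degree"])


def select_ir_hubs(network: TripartiteNetwork,
                   threshold: int = DEFAULT_IR_THRESHOLD) -> HubReport:
    """miRs with IR >= threshold, ranked by IR descending then name."""
    stats = network.stats
    hubs = stats[stats["ir"] >= threshold].copy()
    hubs = hubs.sort_values(["ir"], ascending=False, kind="stable")
    hubs = hubs.loc[sorted(hubs.index,
                           key=lambda m: (-hubs.loc[m, "ir"], m))]
    rows = hubs.reset_index(names="miR")[["miR", "m", "n", "ir"]]
    return HubReport(rows=rows, threshold=threshold,
                     tf_ranking=tf_outdegree_ranking(network))
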