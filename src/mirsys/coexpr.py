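"""miR-miR Pearson co-expression network and topological hub analysis.

Pearson correlations are computed over all samples pooled (disease and
control together) with pairwise-complete observations; a pair is connected
when r exceeds the threshold (default 0.9, strict and signed — strongly
anti-correlated pairs do not form edges unless the absolute-value mode is
requested).  Node statistics follow the conventions of classic network-
analysis services: betweenness is the unnormalized sum over unordered node
pairs of the fraction of shortest paths through the node (endpoints
excluded, unreachable pairs skipped); eccentricity is the maximum finite
shortest-path length (0 for an isolated node); the clustering coefficient
is 2 * e_n / (k_n * (k_n - 1)), defined as 0 for degree < 2.  Degree hubs
are the nodes whose degree strictly exceeds a fraction (default 0.8) of
the maximum degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.9
DEFAULT_HUB_FRACTION = 0.8

METRIC_COLUMNS = ["degree", "betweenness", "eccentricity", "clustering"]

MIN_COMMON_SAMPLES = 3  # pairs with fewer complete observations get NaN


def pearson_matrix(dataset: ExpressionDataset) -> pd.DataFrame:
    """Symmetric probe-by-probe Pearson correlation over pooled samples.

    Missing values are handled pairwise-complete; pairs with fewer than
    three common observations, and any pair involving a zero-variance
    probe, are NaN (and thus never become edges).  Diagonal is 1.
    """
    corr = dataset.values.T.corr(method="pearson",
                                 min_periods=MIN_COMMON_SAMPLES)
    zero_var = dataset.values.std(axis=1, ddof=0) == 0
    if zero_var.any():
        logger.warning("%d zero-variance probes: correlations undefined",
                       int(zero_var.sum()))
    np.fill_diagonal(corr.values, 1.0)
    return corr


def threshold_edges(corr: pd.DataFrame, r_min: float = DEFAULT_R_MIN,
                    keep_isolated: bool = False,
                    use_absolute: bool = False) -> nx.Graph:
    """Undirected graph with an edge where r > r_min (strict).

    The signed convention is the default (r = -0.95 is not an edge);
    ``use_absolute`` switches to |r| > r_min.  Nodes without any edge are
    dropped unless ``keep_isolated`` is set.
    """
    if not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix must be square and labeled")
    g = nx.Graph()
    names = list(corr.index)
    if keep_isolated:
        g.add_nodes_from(names)
    vals = corr.to_numpy()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = vals[i, j]
            if not np.isfinite(r):
                continue
            if (abs(r) if use_absolute else r) > r_min:
                g.add_edge(names[i], names[j], weight=float(r),
                           interaction="coexpressed")
    return g


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness, eccentricity, clustering coefficient."""
    nodes = sorted(graph.nodes)
    degree = {v: graph.degree(v) for v in nodes}
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    clustering = nx.clustering(graph)
    eccentricity = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            eccentricity[next(iter(comp))] = 0
        else:
            eccentricity.update(nx.eccentricity(sub))
    frame = pd.DataFrame({
        "degree": [degree[v] for v in nodes],
        "betweenness": [betweenness[v] for v in nodes],
        "eccentricity": [eccentricity[v] for v in nodes],
        "clustering": [clustering[v] for v in nodes],
    }, index=nodes)
    return frame


def summarize_nodes(graph: nx.Graph) -> pd.DataFrame:
    """Avg / SD / Min / Max of each metric over nodes (population SD)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot summarize an empty graph")
    metrics = node_metrics(graph)
    return pd.DataFrame({
        "avg": metrics.mean(),
        "sd": metrics.std(ddof=0),
        "min": metrics.min(),
        "max": metrics.max(),
    })


@dataclass
class DegreeHubs:
    """Top-connectivity nodes under the fractional degree cutoff."""

    cutoff: float            # fraction * max degree; hubs strictly exceed it
    fraction: float
    table: pd.DataFrame      # miR, degree — degree desc, name asc

    @property
    def names(self) -> List[str]:
        return list(self.table["miR"])


def select_degree_hubs(graph: nx.Graph,
                       fraction: float = DEFAULT_HUB_FRACTION) -> DegreeHubs:
    """Nodes whose degree strictly exceeds fraction * max degree."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    degrees = dict(graph.degree())
    cutoff = fraction * max(degrees.values())
    hubs = [(v, d) for v, d in degrees.items() if d > cutoff]
    hubs.sort(key=lambda vd: (-vd[1], vd[0]))
    return DegreeHubs(cutoff=float(cutoff), fraction=fraction,
                      table=pd.DataFrame(hubs, columns=["miR", "degree"]))


def coexpression_graph(dataset: ExpressionDataset, mirs=None,
                       r_min: float = DEFAULT_R_MIN,
                       keep_isolated: bool = False,
                       use_absolute: bool = False) -> nx.Graph:
    """Convenience: correlation + thresholding, optionally on a miR subset."""
    ds = dataset.subset_probes(mirs) if mirs is not None else dataset
    return threshold_edges(pearson_matrix(ds), r_min=r_min,
                           keep_isolated=keep_isolated,
                           use_absolute=use_absolute)


def annotate_graph(graph: nx.Graph) -> nx.Graph:
    """Attach the four node metrics as GraphML-exportable attributes."""
    metrics = node_metrics(graph)
    for v in graph.nodes:
        graph.nodes[v]["degree"] = int(metrics.loc[v, "degree"])
        graph.nodes[v]["betweenness"] = float(metrics.loc[v, "betweenness"])
        graph.nodes[v]["eccentricity"] = int(metrics.loc[v, "eccentricity"])
        graph.nodes[v]["clustering"] = float(metrics.loc[v, "clustering"])
    return graph
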