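"""Agglomerative hierarchical clustering with correlation distance (UPGMA).

Pairwise distance between expression profiles is 1 - r (Pearson), ranging
over [0, 2].  Average linkage merges, at every step, the pair of clusters
whose unweighted mean of all cross-pair leaf distances is smallest; the
running inter-cluster distances are maintained with the Lance-Williams
average update, which is algebraically identical to re-averaging over all
cross pairs.  A cluster is identified by its lexicographically smallest
leaf name, and distance ties are broken by the smallest (sorted) pair of
cluster ids, making merge order fully deterministic.  Cutting at k undoes
the last k - 1 merges; cluster ids in the cut are assigned by decreasing
size, then by smallest member name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ExpressionDataset


@dataclass(frozen=True)
class Merge:
    left: str      # cluster id (its smallest leaf name); left < right
    right: str
    height: float
    size: int      # leaves in the merged cluster


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering: |leaves| - 1 merges."""

    leaf_names: Tuple[str, ...]
    merges: List[Merge]

    @property
    def heights(self) -> List[float]:
        return [m.height for m in self.merges]


def correlation_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation, in [0, 2]; undefined for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(1.0 - r, 0.0, 2.0))


def correlation_distance_matrix(dataset: ExpressionDataset) -> pd.DataFrame:
    """Probe-by-probe correlation distance matrix (1 - r, zero diagonal)."""
    corr = dataset.values.T.corr(method="pearson")
    d = 1.0 - corr
    np.fill_diagonal(d.values, 0.0)
    return d


def average_linkage(dist_matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA over a symmetric, zero-diagonal labeled distance matrix."""
    labels = list(dist_matrix.index)
    if not dist_matrix.index.equals(dist_matrix.columns):
        raise ValueError("distance matrix must have matching row/column labels")
    d = dist_matrix.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, equal_nan=False):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two leaves")

    d = d.copy()
    np.fill_diagonal(d, np.inf)
    active = {i: (labels[i], 1) for i in range(n)}  # row -> (id, size)
    merges: List[Merge] = []
    for _ in range(n - 1):
        # smallest distance; ties by the sorted (id, id) pair
        height = float(np.min(d))
        ties = np.argwhere(d == height)
        best = None
        for ai, bi in ties:
            if bi <= ai:
                continue
            pair = tuple(sorted((active[ai][0], active[bi][0])))
            if best is None or pair < best[0]:
                best = (pair, int(ai), int(bi))
        pair, ai, bi = best
        id_a, size_a = active[ai]
        id_b, size_b = active[bi]
        new_size = size_a + size_b
        merges.append(Merge(left=pair[0], right=pair[1],
                            height=float(height), size=new_size))
        # Lance-Williams average update into row ai
        for ci in active:
            if ci in (ai, bi):
                continue
            d[ai, ci] = d[ci, ai] = (size_a * d[ai, ci]
                                     + size_b * d[bi, ci]) / new_size
        d[bi, :] = np.inf
        d[:, bi] = np.inf
        active[ai] = (min(id_a, id_b), new_size)
        del active[bi]
    return Dendrogram(leaf_names=tuple(labels), merges=merges)


def cut_clusters(dendrogram: Dendrogram, k: int) -> Dict[str, int]:
    """Partition into k clusters by undoing the last k - 1 merges.

    Returns leaf -> cluster id, with ids 1..k assigned by decreasing
    cluster size, then by smallest member name.
    """
    n = len(dendrogram.leaf_names)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    members: Dict[str, set] = {name: {name} for name in dendrogram.leaf_names}
    for merge in dendrogram.merges[: n - k]:
        merged = members.pop(merge.left) | members.pop(merge.right)
        members[min(merge.left, merge.right)] = merged
    clusters = sorted(members.values(), key=lambda c: (-len(c), min(c)))
    assignment: Dict[str, int] = {}
    for cid, cluster in enumerate(clusters, start=1):
        for leaf in cluster:
            assignment[leaf] = cid
    return assignment


def cluster_expression(dataset: ExpressionDataset, k: int,
                       mirs=None) -> Tuple[Dict[str, int], Dendrogram]:
    """Cluster (a subset of) the expression probes into k groups."""
    ds = dataset.subset_probes(mirs) if mirs is not None else dataset
    dend = average_linkage(correlation_distance_matrix(ds))
    return cut_clusters(dend, k), dend
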