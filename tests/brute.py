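"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (plain loops, explicit
enumeration) and deliberately shares no code with the package, so it can
serve as an independent reference for the implementation's results.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


# ---------------------------------------------------------------------------
# graph metrics by explicit enumeration
# ---------------------------------------------------------------------------

def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def enumerate_shortest_paths(adj, s, t):
    """All shortest s->t paths, found by DFS along distance-decreasing edges."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(u, path):
        if u == t:
            paths.append(path)
            return
        for v in adj[u]:
            if v in dist_t and dist_t[v] == dist_t[u] - 1:
                walk(v, path + [v])

    walk(s, [s])
    return paths


def brute_metrics(nodes, edges):
    """degree, betweenness, eccentricity, clustering for a simple graph."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    degree = {v: len(adj[v]) for v in nodes}

    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / len(paths)

    eccentricity = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        finite = [d for u, d in dist.items() if u != v]
        eccentricity[v] = max(finite) if finite else 0

    clustering = {}
    for v in nodes:
        k = degree[v]
        if k < 2:
            clustering[v] = 0.0
            continue
        e = sum(1 for a, b in itertools.combinations(adj[v], 2)
                if b in adj[a])
        clustering[v] = 2.0 * e / (k * (k - 1))

    return degree, betweenness, eccentricity, clustering


# ---------------------------------------------------------------------------
# hypergeometric upper tail by exhaustive draw enumeration
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(N, K, n, k_min):
    """P(X >= k_min) by enumerating all C(N, n) draws from the urn."""
    population = [1] * K + [0] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k_min:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# UPGMA by re-averaging over all cross leaf pairs at every step
# ---------------------------------------------------------------------------

def upgma_heights(labels, dist):
    """Merge heights computed from the original leaf distances each step.

    ``dist`` maps frozenset({a, b}) -> distance.  Inter-cluster distance is
    recomputed from scratch as the mean over all cross leaf pairs, with the
    same tie rule as the implementation (smallest sorted pair of min-leaf
    cluster ids).
    """
    clusters = [frozenset([l]) for l in labels]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            total = sum(dist[frozenset([x, y])] for x in a for y in b)
            mean = total / (len(a) * len(b))
            key = (mean, tuple(sorted((min(a), min(b)))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (height, _), a, b = best
        heights.append(height)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights


# ---------------------------------------------------------------------------
# two-class SAM statistic by plain arithmetic
# ---------------------------------------------------------------------------

def sam_d(disease, control, s0):
    n1, n2 = len(disease), len(control)
    m1 = sum(disease) / n1
    m2 = sum(control) / n2
    ss1 = sum((x - m1) ** 2 for x in disease)
    ss2 = sum((x - m2) ** 2 for x in control)
    s = math.sqrt((1 / n1 + 1 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return (m1 - m2) / (s + s0), m1 - m2, s
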