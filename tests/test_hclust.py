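"""Correlation distance, UPGMA merges and dendrogram cutting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from brute import upgma_heights
from conftest import make_dataset
from mirsys.hclust import (Dendrogram, average_linkage, correlation_distance,
                           cut_clusters, cluster_expression)


def dist_frame(matrix, names):
    return pd.DataFrame(matrix, index=names, columns=names, dtype=float)


@pytest.mark.parametrize("x,y,expected", [
    ([1, 2, 3], [3, 5, 7], 0.0),     # y = 2x + 1
    ([1, 2, 3], [-1, -2, -3], 2.0),  # y = -x
    ([1, 2, 3], [1, 3, 2], 0.5),     # r = 0.5
])
def test_correlation_distance_values(x, y, expected):
    assert correlation_distance(x, y) == pytest.approx(expected)


def test_correlation_distance_zero_variance_rejected():
    with pytest.raises(ValueError):
        correlation_distance([1, 1, 1], [1, 2, 3])


def test_correlation_distance_short_vectors_rejected():
    with pytest.raises(ValueError):
        correlation_distance([1, 2], [3, 4])


def test_upgma_hand_example():
    # d(A,B)=1, d(A,C)=4, d(B,C)=6: first merge {A,B} at 1,
    # then {AB},{C} at mean(4,6)=5
    m = [[0, 1, 4], [1, 0, 6], [4, 6, 0]]
    dend = average_linkage(dist_frame(m, ["A", "B", "C"]))
    assert len(dend.merges) == 2
    assert dend.merges[0].left == "A" and dend.merges[0].right == "B"
    assert dend.merges[0].height == pytest.approx(1.0)
    assert dend.merges[1].height == pytest.approx(5.0)


def test_upgma_all_equal_distances_tie_rule():
    m = np.ones((4, 4)) - np.eye(4)
    dend = average_linkage(dist_frame(m, ["d", "c", "b", "a"]))
    # ties resolved by lexicographic cluster-id pairs: (a,b), then (a,c), (a,d)
    assert (dend.merges[0].left, dend.merges[0].right) == ("a", "b")
    assert (dend.merges[1].left, dend.merges[1].right) == ("a", "c")
    assert (dend.merges[2].left, dend.merges[2].right) == ("a", "d")


def test_upgma_heights_match_scipy_average_linkage():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = 8
        cond = rng.uniform(0.1, 2.0, size=n * (n - 1) // 2)
        square = squareform(cond)
        names = [f"L{i}" for i in range(n)]
        dend = average_linkage(dist_frame(square, names))
        z = hierarchy.linkage(cond, method="average")
        np.testing.assert_allclose(dend.heights, z[:, 2], rtol=1e-10)


def test_upgma_heights_match_cross_pair_oracle():
    rng = np.random.default_rng(1)
    n = 7
    names = [f"L{i}" for i in range(n)]
    square = squareform(rng.uniform(0.1, 2.0, size=n * (n - 1) // 2))
    dend = average_linkage(dist_frame(square, names))
    dist = {frozenset([names[i], names[j]]): square[i, j]
            for i in range(n) for j in range(i + 1, n)}
    np.testing.assert_allclose(dend.heights, upgma_heights(names, dist))


def test_upgma_invariant_to_leaf_order():
    rng = np.random.default_rng(2)
    n = 6
    names = [f"L{i}" for i in range(n)]
    square = squareform(rng.uniform(0.1, 2.0, size=n * (n - 1) // 2))
    frame = dist_frame(square, names)
    ref = average_linkage(frame)
    ref_cut = cut_clusters(ref, 3)
    for perm in itertools.islice(itertools.permutations(range(n)), 1, 12, 3):
        shuffled = frame.iloc[list(perm), list(perm)]
        dend = average_linkage(shuffled)
        np.testing.assert_allclose(sorted(dend.heights), sorted(ref.heights))
        cut = cut_clusters(dend, 3)
        # identical partition up to relabeling
        groups_ref = {}
        for leaf, cid in ref_cut.items():
            groups_ref.setdefault(cid, set()).add(leaf)
        groups = {}
        for leaf, cid in cut.items():
            groups.setdefault(cid, set()).add(leaf)
        assert set(map(frozenset, groups.values())) == \
            set(map(frozenset, groups_ref.values()))


def test_non_symmetric_matrix_rejected():
    m = [[0, 1], [2, 0]]
    with pytest.raises(ValueError, match="symmetric"):
        average_linkage(dist_frame(m, ["a", "b"]))


def test_cut_extremes_and_hierarchy():
    rng = np.random.default_rng(3)
    n = 9
    names = [f"L{i}" for i in range(n)]
    square = squareform(rng.uniform(0.1, 2.0, size=n * (n - 1) // 2))
    dend = average_linkage(dist_frame(square, names))
    assert set(cut_clusters(dend, 1).values()) == {1}
    singletons = cut_clusters(dend, n)
    assert len(set(singletons.values())) == n
    with pytest.raises(ValueError):
        cut_clusters(dend, 0)
    with pytest.raises(ValueError):
        cut_clusters(dend, n + 1)
    # refinement: the k-cut only merges clusters of the (k+1)-cut
    for k in range(2, n):
        coarse = cut_clusters(dend, k)
        fine = cut_clusters(dend, k + 1)
        mapping = {}
        for leaf in names:
            mapping.setdefault(fine[leaf], set()).add(coarse[leaf])
        assert all(len(v) == 1 for v in mapping.values())


def test_cluster_ids_by_decreasing_size():
    m = [[0.0, 0.1, 0.9, 0.9],
         [0.1, 0.0, 0.9, 0.9],
         [0.9, 0.9, 0.0, 0.8],
         [0.9, 0.9, 0.8, 0.0]]
    dend = average_linkage(dist_frame(m, ["a", "b", "c", "d"]))
    cut = cut_clusters(dend, 3)
    assert cut["a"] == cut["b"] == 1  # size-2 cluster gets id 1
    assert len({cut["c"], cut["d"]}) == 2


def test_planted_three_block_recovery():
    rng = np.random.default_rng(4)
    blocks = [3, 4, 5]
    names, truth = [], {}
    for b, size in enumerate(blocks):
        for i in range(size):
            name = f"B{b}_L{i}"
            names.append(name)
            truth[name] = b
    n = len(names)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = truth[names[i]] == truth[names[j]]
            base = 0.1 if same else 1.5
            m[i, j] = m[j, i] = base + rng.uniform(0, 0.05)
    cut = cut_clusters(average_linkage(dist_frame(m, names)), 3)
    for b in range(3):
        ids = {cut[nm] for nm in names if truth[nm] == b}
        assert len(ids) == 1
    assert len({cut[nm] for nm in names}) == 3


def test_cluster_expression_on_correlated_rows():
    rng = np.random.default_rng(5)
    f1, f2 = rng.normal(size=20), rng.normal(size=20)
    rows = [f1 + 0.05 * rng.normal(size=20) for _ in range(3)]
    rows += [f2 + 0.05 * rng.normal(size=20) for _ in range(3)]
    ds = make_dataset(np.array(rows))
    assignment, dend = cluster_expression(ds, 2)
    a = {assignment[p] for p in ds.probe_names[:3]}
    b = {assignment[p] for p in ds.probe_names[3:]}
    assert len(a) == 1 and len(b) == 1 and a != b
    assert len(dend.merges) == 5
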