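"""Neighbour-joining correctness: additivity, closed forms, invariance."""

import numpy as np
import pytest

from sbs.phylo import neighbor_joining, tree_bipartitions
from sbs.phylo.distance import DistanceMatrix


def _edge_lengths(tree):
    return {
        frozenset(leaf.name for leaf in n.tips()) or frozenset([n.name]): n.length
        for n in tree.traverse() if n.length is not None
    }


def test_four_taxon_additive_matrix_reconstructed_exactly():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> path-sum distances
    labels = list("ABCD")
    d = np.array(
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 7, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(labels, d))
    assert tree_bipartitions(tree) == {frozenset("CD")}
    tip_len = {leaf.name: leaf.length for leaf in tree.tips()}
    assert tip_len == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
    internal = [n.length for n in tree.non_tips(include_self=False)]
    assert internal == [pytest.approx(1.0)]


def test_three_taxon_closed_form():
    labels = list("ABC")
    d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(labels, d))
    tip_len = {leaf.name: leaf.length for leaf in tree.tips()}
    assert tip_len["A"] == pytest.approx((5 + 9 - 8) / 2)
    assert tip_len["B"] == pytest.approx((5 + 8 - 9) / 2)
    assert tip_len["C"] == pytest.approx((9 + 8 - 5) / 2)


@pytest.mark.parametrize("seed", range(50))
def test_nj_reconstructs_random_additive_trees(seed):
    """On an additive matrix from a random binary tree, NJ recovers the
    exact topology and branch lengths."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    # independent additive-matrix oracle: grow a tree as an explicit node
    # set with parent pointers, then distances = path sums
    parent = {}
    blen = {}
    active = list(range(n))
    next_id = n
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a], parent[b] = next_id, next_id
        blen[a] = round(float(rng.uniform(0.1, 1.0)), 3)
        blen[b] = round(float(rng.uniform(0.1, 1.0)), 3)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = next_id
    for x in active:
        parent[x] = root
        blen[x] = round(float(rng.uniform(0.1, 1.0)), 3)

    def path_to_root(x):
        out = {}
        acc = 0.0
        while x in parent:
            out[x] = acc
            acc += blen[x]
            x = parent[x]
        out[x] = acc
        return out

    d = np.zeros((n, n))
    paths = [path_to_root(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            # distance = combined path to the lowest common ancestor,
            # i.e. the minimum over shared ancestors
            common = min(
                paths[i][k] + paths[j][k]
                for k in set(paths[i]) & set(paths[j])
            )
            d[i, j] = d[j, i] = common

    labels = [f"t{i}" for i in range(n)]
    tree = neighbor_joining(DistanceMatrix(labels, d))
    # reconstructed tree must reproduce every pairwise distance exactly
    tip = {leaf.name: leaf for leaf in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            got = tip[labels[i]].distance(tip[labels[j]])
            assert got == pytest.approx(d[i, j], abs=1e-9)


def test_taxon_order_invariance():
    rng = np.random.default_rng(7)
    n = 7
    base = rng.uniform(0.5, 2.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"t{i}" for i in range(n)]
    t1 = neighbor_joining(DistanceMatrix(labels, d))
    perm = rng.permutation(n)
    t2 = neighbor_joining(
        DistanceMatrix([labels[p] for p in perm], d[np.ix_(perm, perm)])
    )
    assert tree_bipartitions(t1) == tree_bipartitions(t2)
    tips1 = {leaf.name: leaf for leaf in t1.tips()}
    tips2 = {leaf.name: leaf for leaf in t2.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            assert tips1[a].distance(tips1[b]) == pytest.approx(
                tips2[a].distance(tips2[b]), abs=1e-9
            )


def test_matches_scikit_bio_nj_topology():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    rng = np.random.default_rng(5)
    n = 8
    base = rng.uniform(0.2, 2.0, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"t{i}" for i in range(n)]
    mine = neighbor_joining(DistanceMatrix(labels, d))
    theirs = sknj(SkDM(d, ids=labels))
    assert tree_bipartitions(mine) == tree_bipartitions(theirs)


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b", "c"], np.array([[0, 1], [1, 0]], float))
    bad = np.array([[0, 1, 2], [1, 0, -1], [2, -1, 0]], dtype=float)
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b", "c"], bad)
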