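"""Neighbour-joining on a distance matrix.

Standard Saitou–Nei agglomeration with the rate-corrected Q criterion,
two-point branch-length formulas, deterministic tie-breaking (lowest index
pair in the current matrix) and negative branch-length estimates clamped
to zero (the clamped deficit is recorded on the tree).  Trees are
scikit-bio ``TreeNode`` objects (unrooted; the root is a trifurcation).
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .distance import DistanceMatrix


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour-joining needs at least three taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # lowest flat index wins ties
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(float(li))
        nodes[j].length = clamp(float(lj))
        parent.append(nodes[i])
        parent.append(nodes[j])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # final trifurcation from the three-point closed form
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode()
    for node, ln in zip((a, b, c), (la, lb, lc)):
        node.length = clamp(float(ln))
        root.append(node)
    root.clamped_negative_length = clamped
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions of an unrooted tree, each canonicalised
    as the side not containing the lexicographically smallest taxon."""
    taxa = frozenset(leaf.name for leaf in tree.tips())
    anchor = min(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        out.add(side)
    return out
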