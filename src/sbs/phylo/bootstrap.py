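"""Bootstrap supports and majority-rule consensus for NJ trees."""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
from skbio import TreeNode

from ..msa import Alignment
from .distance import distance_matrix
from .nj import neighbor_joining, tree_bipartitions
from .ratemodel import RateModel


def bootstrap_tree(
    records: list[tuple[str, str]],
    model: RateModel,
    n_reps: int = 1000,
    seed: int = 0,
    consensus_rule: str = "extended",
) -> tuple[TreeNode, TreeNode, int]:
    """Column-resampling bootstrap around the full-data NJ tree.

    Returns ``(tree, consensus, n_used)``: the full-data NJ tree with
    percentage supports attached to its internal edges (``node.support``,
    mirrored into ``node.name`` for Newick export), the majority-rule
    consensus tree of the replicates (extended by default), and the number
    of replicates actually used.  Replicates containing a pair with no
    comparable sites are dropped, counted and warned about.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(distance_matrix(records, model))
    aln = Alignment(list(records))
    rng = np.random.default_rng(seed)
    counts: Counter[frozenset[str]] = Counter()
    used = 0
    dropped = 0
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            dm = distance_matrix(rep.records, model)
        except ValueError:
            dropped += 1
            continue
        counts.update(tree_bipartitions(neighbor_joining(dm)))
        used += 1
    if dropped:
        warnings.warn(
            f"{dropped} bootstrap replicate(s) dropped (incomparable pair)"
        )
    if used == 0:
        raise ValueError("all bootstrap replicates were dropped")

    taxa = frozenset(r for r, _ in records)
    anchor = min(taxa)
    for node in full.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        key = taxa - side if anchor in side else side
        support = 100.0 * counts.get(key, 0) / used
        node.support = support
        node.name = f"{support:g}"

    consensus = majority_consensus(
        counts, used, sorted(taxa), extended=(consensus_rule == "extended")
    )
    return full, consensus, used


def _compatible(a: frozenset, b: frozenset) -> bool:
    inter = a & b
    return not inter or inter == a or inter == b


def majority_consensus(
    counts: Counter,
    n_reps: int,
    taxa: list[str],
    extended: bool = True,
) -> TreeNode:
    """Build a consensus tree from bipartition counts.

    Plain majority rule keeps splits occurring in more than half the
    replicates; the extended rule then greedily adds the remaining splits
    in decreasing frequency order when compatible with everything kept.
    Splits are expressed as the side not containing the first taxon, so
    the consensus is rooted (arbitrarily) at that taxon's side.
    """
    ordered = sorted(
        counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
    )
    kept: list[tuple[frozenset, float]] = []
    for split, c in ordered:
        freq = c / n_reps
        if freq <= 0.5 and not extended:
            continue
        if freq <= 0.5 and extended and any(
            not _compatible(split, s) for s, _ in kept
        ):
            continue
        if freq > 0.5 or extended:
            if all(_compatible(split, s) for s, _ in kept):
                kept.append((split, freq))

    # laminar family -> tree by containment
    kept.sort(key=lambda sf: len(sf[0]))
    nodes: list[tuple[frozenset, TreeNode]] = []
    root = TreeNode()
    for split, freq in kept:
        node = TreeNode(name=f"{100.0 * freq:g}")
        node.support = 100.0 * freq
        nodes.append((split, node))
    # attach each split node to the smallest strictly-containing split
    for i, (split, node) in enumerate(nodes):
        parent = root
        best = None
        for osplit, onode in nodes[i + 1:]:
            if split < osplit and (best is None or len(osplit) < len(best)):
                best, parent = osplit, onode
        parent.append(node)
    for taxon in taxa:
        best = None
        parent = root
        for split, node in nodes:
            if taxon in split and (best is None or len(split) < len(best)):
                best, parent = split, node
        parent.append(TreeNode(name=taxon))
    return root
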