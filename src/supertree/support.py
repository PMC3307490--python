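"""Supertree support (rQS per node) and inter-tree topological distance.

The reduced qualitative support index scores every internal supertree node
against each source tree after pruning both to their shared taxa: +1 when the
node's induced bipartition occurs in the source, -1 when the source contains
an incompatible bipartition, 0 when the node collapses on the shared taxa or
the source is compatible but unresolved.  A node's rQS is
(support - conflict) / (support + conflict) over the informative sources.

Topological distance between two trees is the normalized partition metric:
the number of bipartitions found in exactly one tree divided by the maximum
possible disagreement, 2(n - 3), for n shared leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from ._tree_utils import (
    clade_leafsets,
    leaf_labels,
    restrict_to_labels,
    splits_conflict,
    unrooted_bipartitions,
)
from .sources import SourceTreeRecord


@dataclass
class NodeSupport:
    """Per-node source-tree tallies and the resulting rQS value."""

    node_id: int
    clade: frozenset
    n_support: int
    n_conflict: int
    n_equivocal: int

    @property
    def rqs(self) -> Optional[float]:
        informative = self.n_support + self.n_conflict
        if informative == 0:
            return None
        return (self.n_support - self.n_conflict) / informative


def rqs_per_node(
    supertree: dendropy.Tree, sources: Sequence[SourceTreeRecord]
) -> list[NodeSupport]:
    """Score every internal supertree node (root excluded) against the sources."""
    universe = frozenset(leaf_labels(supertree))
    sets = clade_leafsets(supertree)
    nodes = [
        (node, sets[node])
        for node in supertree.preorder_internal_node_iter()
        if node is not supertree.seed_node and len(sets[node]) >= 2
    ]

    # precompute each source's bipartitions over its shared taxa
    prepared = []
    for rec in sources:
        shared = rec.taxa & universe
        if len(shared) < 4:
            prepared.append((shared, None))
            continue
        pruned = (
            rec.tree
            if rec.taxa == shared
            else restrict_to_labels(rec.tree, shared)
        )
        prepared.append((shared, unrooted_bipartitions(pruned)))

    out = []
    for node_id, (node, clade) in enumerate(nodes, start=1):
        n_sup = n_con = n_eq = 0
        for shared, splits in prepared:
            if splits is None:
                n_eq += 1
                continue
            side1 = clade & shared
            side2 = shared - clade
            if len(side1) < 2 or len(side2) < 2:
                n_eq += 1
                continue
            split = frozenset([side1, side2])
            if split in splits:
                n_sup += 1
            elif any(splits_conflict(split, s) for s in splits):
                n_con += 1
            else:
                n_eq += 1
        out.append(
            NodeSupport(
                node_id=node_id, clade=clade,
                n_support=n_sup, n_conflict=n_con, n_equivocal=n_eq,
            )
        )
    return out


def mean_rqs(supports: Sequence[NodeSupport]) -> tuple:
    """Mean rQS and its standard error over nodes with a defined value."""
    values = [s.rqs for s in supports if s.rqs is not None]
    if not values:
        return None, None
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def partition_metric(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Normalized partition metric in [0, 1] on the shared leaves."""
    shared = frozenset(leaf_labels(t1)) & frozenset(leaf_labels(t2))
    n = len(shared)
    if n < 4:
        raise ValueError("need at least 4 shared leaves")
    p1 = t1 if frozenset(leaf_labels(t1)) == shared else restrict_to_labels(t1, shared)
    p2 = t2 if frozenset(leaf_labels(t2)) == shared else restrict_to_labels(t2, shared)
    s1 = unrooted_bipartitions(p1)
    s2 = unrooted_bipartitions(p2)
    return len(s1 ^ s2) / (2 * (n - 3))


def resolution(tree: dendropy.Tree) -> float:
    """Fraction of resolved internal nodes relative to a fully bifurcating
    rooted tree: (internal nodes - 1) / (n - 2) for n leaves."""
    n = sum(1 for _ in tree.leaf_node_iter())
    if n < 3:
        raise ValueError("need at least 3 leaves")
    internal = sum(1 for _ in tree.preorder_internal_node_iter())
    return (internal - 1) / (n - 2)
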