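"""Shared low-level helpers on dendropy trees.

All public modules pass around :class:`dendropy.Tree` objects; the helpers here
centralize the label-set / bipartition bookkeeping that several of them need.
Leaf labels are the canonical species identifiers throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

__all__ = [
    "leaf_labels",
    "clade_leafsets",
    "internal_clades",
    "unrooted_bipartitions",
    "normalize_bipartition",
    "splits_conflict",
    "restrict_to_labels",
    "tree_from_clades",
    "canonical_topology_id",
    "annotate_ages_from_edges",
    "apply_edge_lengths_from_ages",
    "parse_tree",
]


def parse_tree(source: str, schema: str = "newick") -> dendropy.Tree:
    """Parse a single tree from a string or file path (Newick or NEXUS)."""
    import os

    if os.path.exists(source):
        return dendropy.Tree.get(path=source, schema=schema)
    return dendropy.Tree.get(data=source, schema=schema)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def clade_leafsets(tree: dendropy.Tree) -> dict:
    """Map every node to the frozenset of leaf labels it subtends (postorder)."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= out[ch]
            out[node] = frozenset(acc)
    return out


def internal_clades(
    tree: dendropy.Tree, include_root: bool = False, include_trivial: bool = False
) -> list[frozenset]:
    """Leaf-label sets of internal nodes, root excluded by default."""
    sets = clade_leafsets(tree)
    out = []
    for node, labels in sets.items():
        if node.is_leaf():
            continue
        if node is tree.seed_node and not include_root:
            continue
        if len(labels) < 2 and not include_trivial:
            continue
        out.append(labels)
    return out


def normalize_bipartition(side: Iterable[str], universe: frozenset) -> frozenset:
    """Represent the unrooted split {side | universe-side} canonically.

    Returned as a frozenset of the two frozenset sides, so orientation does not
    matter and splits over different leaf sets never compare equal by accident.
    """
    a = frozenset(side)
    b = frozenset(universe) - a
    return frozenset([a, b])


def unrooted_bipartitions(tree: dendropy.Tree, nontrivial: bool = True) -> set:
    """Set of unrooted bipartitions induced by the tree's internal edges."""
    universe = frozenset(leaf_labels(tree))
    out = set()
    for labels in internal_clades(tree, include_root=False):
        other = universe - labels
        if nontrivial and (len(labels) < 2 or len(other) < 2):
            continue
        out.add(frozenset([labels, other]))
    return out


def splits_conflict(split_a, split_b) -> bool:
    """Two unrooted bipartitions (over the same leaf set) are incompatible iff
    all four pairwise side intersections are non-empty."""
    a1, a2 = tuple(split_a)
    b1, b2 = tuple(split_b)
    return all(
        len(x & y) > 0 for x in (a1, a2) for y in (b1, b2)
    )


def restrict_to_labels(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Copy of *tree* pruned to the given leaf labels; unifurcations suppressed."""
    keep = set(labels)
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    return sub


def tree_from_clades(
    clades: Iterable[frozenset], taxa: Sequence[str], rooted: bool = True
) -> dendropy.Tree:
    """Assemble a rooted tree whose internal nodes are exactly *clades*.

    The clades must be pairwise nested or disjoint (as produced by a strict
    consensus or by decoding a single tree's matrix representation); a
    ValueError is raised otherwise.
    """
    taxa = list(taxa)
    universe = frozenset(taxa)
    uniq = {frozenset(c) for c in clades if 1 < len(c) < len(universe)}
    for c in uniq:
        if not c <= universe:
            raise ValueError(f"clade {sorted(c)} not within the taxon set")
    ordered = sorted(uniq, key=len, reverse=True)
    # verify nesting
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a & b and not (b <= a):
                raise ValueError("clades are not compatible (neither nested nor disjoint)")

    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = rooted
    node_of = {universe: tree.seed_node}
    for c in ordered:
        parent_set = min(
            (p for p in node_of if c < p), key=len
        )
        node = dendropy.Node()
        node_of[parent_set].add_child(node)
        node_of[c] = node
    for label in taxa:
        parent_set = min((p for p in node_of if label in p), key=len)
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        node_of[parent_set].add_child(leaf)
    return tree


def canonical_topology_id(tree: dendropy.Tree) -> str:
    """Rotation-invariant string identifying the rooted topology."""

    def rec(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(rec(c) for c in node.child_nodes())) + ")"

    return rec(tree.seed_node)


def annotate_ages_from_edges(tree: dendropy.Tree, tol: float = 1e-6) -> None:
    """Set ``node.age`` from edge lengths, leaves at 0 (tree must be ultrametric
    to within *tol* of the maximum root-to-tip distance)."""
    depths = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        depths[node] = (depths[node.parent_node] + el) if node.parent_node else 0.0
    leaf_depths = [depths[lf] for lf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if height <= 0:
        raise ValueError("tree has zero depth")
    if max(leaf_depths) - min(leaf_depths) > tol * max(height, 1.0):
        raise ValueError("tree is not ultrametric; cannot assign ages")
    for node in tree.preorder_node_iter():
        node.age = height - depths[node]
    for lf in tree.leaf_node_iter():
        lf.age = 0.0


def apply_edge_lengths_from_ages(tree: dendropy.Tree) -> None:
    """Set edge lengths from ``node.age`` attributes (parent age - node age)."""
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
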