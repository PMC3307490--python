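"""A rooted ultrametric tree with absolute node ages and confidence intervals.

``DatedTree`` wraps a rooted :class:`dendropy.Tree` whose nodes carry an
``age`` attribute in Ma before present (leaves at 0), optional 95% CI bounds
(``ci_low``/``ci_high``) and a provenance flag (``age_origin``: ``genetic``,
``fossil-override`` or ``interpolated``).  Edge lengths are kept consistent
with the ages (parent age minus child age), so the wrapped tree can be handed
to any branch-length consumer.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy
import pandas as pd

from ._tree_utils import (
    annotate_ages_from_edges,
    apply_edge_lengths_from_ages,
    clade_leafsets,
    leaf_labels,
)

GENETIC = "genetic"
FOSSIL_OVERRIDE = "fossil-override"
INTERPOLATED = "interpolated"


class DatedTree:
    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self.tree = tree
        for lf in tree.leaf_node_iter():
            lf.age = 0.0
        if validate:
            self.validate()
        apply_edge_lengths_from_ages(tree)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_ultrametric(cls, tree: dendropy.Tree) -> "DatedTree":
        """Adopt a tree whose edge lengths already encode an ultrametric clock."""
        annotate_ages_from_edges(tree)
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def from_newick(cls, source: str) -> "DatedTree":
        import os

        if os.path.exists(source):
            t = dendropy.Tree.get(path=source, schema="newick")
        else:
            t = dendropy.Tree.get(data=source, schema="newick")
        return cls.from_ultrametric(t)

    # -- basic accessors ----------------------------------------------------

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def leaf_labels(self) -> list:
        return leaf_labels(self.tree)

    def internal_nodes(self) -> Iterator[dendropy.Node]:
        return self.tree.preorder_internal_node_iter()

    def clades(self) -> dict:
        return clade_leafsets(self.tree)

    def branching_times(self) -> list:
        """Internal-node ages, one entry per child beyond the first for
        polytomies, sorted oldest first."""
        times = []
        for node in self.internal_nodes():
            times.extend([node.age] * (len(node.child_nodes()) - 1))
        return sorted(times, reverse=True)

    def is_binary(self) -> bool:
        return all(len(n.child_nodes()) == 2 for n in self.internal_nodes())

    def total_branch_length(self) -> float:
        return sum(
            n.edge.length for n in self.tree.preorder_node_iter()
            if n.parent_node is not None
        )

    def copy(self) -> "DatedTree":
        cl = self.tree.clone(depth=1)
        return DatedTree(cl, validate=False)

    # -- consistency --------------------------------------------------------

    def validate(self, tol: float = 1e-9) -> None:
        for node in self.tree.preorder_node_iter():
            age = getattr(node, "age", None)
            if age is None:
                raise ValueError("every node needs an age")
            if node.parent_node is not None and age > node.parent_node.age + tol:
                raise ValueError("child older than its parent")
            lo = getattr(node, "ci_low", None)
            hi = getattr(node, "ci_high", None)
            if lo is not None and hi is not None and not (lo - tol <= age <= hi + tol):
                raise ValueError("age outside its CI")
        for lf in self.tree.leaf_node_iter():
            if abs(lf.age) > tol:
                raise ValueError("leaves must sit at age 0")

    def refresh_branch_lengths(self) -> None:
        apply_edge_lengths_from_ages(self.tree)

    # -- reporting ----------------------------------------------------------

    def ages_frame(self) -> pd.DataFrame:
        """Per-internal-node table: id, age, CI bounds, origin flag, clade size."""
        sets = self.clades()
        rows = []
        for i, node in enumerate(self.internal_nodes(), start=1):
            rows.append(
                {
                    "node_id": i,
                    "age": node.age,
                    "ci_low": getattr(node, "ci_low", None),
                    "ci_high": getattr(node, "ci_high", None),
                    "age_origin": getattr(node, "age_origin", None),
                    "n_species": len(sets[node]),
                }
            )
        return pd.DataFrame(rows)

    def _tree_with_ages(self, attr: str) -> dendropy.Tree:
        cl = self.tree.clone(depth=1)
        ages = {}
        for node in cl.preorder_node_iter():
            a = getattr(node, attr, None)
            ages[node] = node.age if (a is None or node.is_leaf()) else a
        # enforce monotonicity so the CI trees remain valid clocks
        for node in cl.preorder_node_iter():
            if node.parent_node is not None:
                ages[node] = min(ages[node], ages[node.parent_node])
            node.age = ages[node]
        apply_edge_lengths_from_ages(cl)
        return cl

    def write_nexus(self, path: str) -> None:
        """Write three stored trees: best ages and the CI bound renderings."""
        best = self.tree.clone(depth=1)
        apply_edge_lengths_from_ages(best)
        low = self._tree_with_ages("ci_low")
        high = self._tree_with_ages("ci_high")
        tl = dendropy.TreeList(
            [best, low, high], taxon_namespace=best.taxon_namespace
        )
        tl[0].label, tl[1].label, tl[2].label = "best", "ci_low", "ci_high"
        tl.write(path=path, schema="nexus", suppress_rooting=False)
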