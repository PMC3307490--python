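"""Phylogenetic diversity, evolutionary distinctiveness and EDGE priorities.

PD of a taxon set is the summed branch length of the minimal subtree
connecting it (optionally including the clade's stem branch).  Species-level
PD is reported as the terminal branch length — the species' unshared share of
the tree.  Fair-proportion ED divides every branch equally among its leaf
descendants, so the per-species ED values sum exactly to the tree length.
EDGE combines distinctiveness with a Red List weight:
``EDGE = ln(1 + ED) + GE·ln 2`` with GE = 0..4 for LC, NT, VU, EN, CR; Data
Deficient species score 0 and share the bottom rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .datedtree import DatedTree

GE_BY_CATEGORY = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}
DATA_DEFICIENT = "DD"


def pd_clade(tree: DatedTree, taxa: Iterable[str], include_stem: bool = False) -> float:
    """Summed branch length of the minimal subtree connecting *taxa*; with
    ``include_stem``, the branch subtending the connecting clade is added."""
    target = set(taxa)
    if not target:
        raise ValueError("taxa must be non-empty")
    leaves = set(tree.leaf_labels())
    missing = target - leaves
    if missing:
        raise ValueError(f"taxa not on the tree: {sorted(missing)}")

    sets = tree.clades()
    # MRCA = smallest clade containing all targets
    mrca = tree.tree.seed_node
    changed = True
    while changed:
        changed = False
        for ch in mrca.child_nodes():
            if target <= sets[ch]:
                mrca = ch
                changed = True
                break

    total = 0.0
    stack = list(mrca.child_nodes())
    while stack:
        node = stack.pop()
        if sets[node] & target:
            total += node.edge.length or 0.0
            stack.extend(node.child_nodes())
    if include_stem and mrca.parent_node is not None:
        total += mrca.edge.length or 0.0
    return total


def ed_fair_proportion(
    tree: DatedTree,
    include_root_stem: bool = False,
    root_stem_age: Optional[float] = None,
) -> dict:
    """Fair-proportion evolutionary distinctiveness per species (Ma).

    Each branch's length is divided by its number of leaf descendants and
    credited to each of them.  With ``include_root_stem``, a stem branch from
    the root back to *root_stem_age* is shared equally among all species.
    """
    sets = tree.clades()
    n_total = tree.n_leaves
    ed = {label: 0.0 for label in tree.leaf_labels()}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        share = length / len(sets[node])
        for sp in sets[node]:
            ed[sp] += share
    if include_root_stem:
        if root_stem_age is None or root_stem_age < tree.root_age:
            raise ValueError("root_stem_age must be given and at least the root age")
        stem_share = (root_stem_age - tree.root_age) / n_total
        for sp in ed:
            ed[sp] += stem_share
    return ed


def edge_score(ed: float, category: str) -> float:
    """EDGE = ln(1 + ED) + GE·ln 2; Data Deficient species score 0."""
    if ed < 0:
        raise ValueError("ED must be non-negative")
    if category == DATA_DEFICIENT:
        return 0.0
    if category not in GE_BY_CATEGORY:
        raise ValueError(f"unknown Red List category {category!r}")
    return math.log1p(ed) + GE_BY_CATEGORY[category] * math.log(2.0)


@dataclass
class ConservationScore:
    species: str
    pd_terminal: float
    ed: float
    category: str
    edge: float

    @property
    def ge(self) -> Optional[int]:
        return GE_BY_CATEGORY.get(self.category)


def conservation_scores(
    tree: DatedTree,
    categories: dict,
    include_root_stem: bool = False,
    root_stem_age: Optional[float] = None,
) -> list[ConservationScore]:
    """Per-species PD (terminal branch), ED and EDGE from a dated tree and a
    species -> Red List category map (missing species default to DD)."""
    ed = ed_fair_proportion(tree, include_root_stem, root_stem_age)
    terminal = {
        lf.taxon.label: (lf.edge.length or 0.0) for lf in tree.tree.leaf_node_iter()
    }
    out = []
    for sp in tree.leaf_labels():
        cat = categories.get(sp, DATA_DEFICIENT)
        out.append(
            ConservationScore(
                species=sp, pd_terminal=terminal[sp], ed=ed[sp],
                category=cat, edge=edge_score(ed[sp], cat),
            )
        )
    return out


def rank_table(scores: list) -> pd.DataFrame:
    """Ranked table of the scores, descending, ties sharing the best rank
    (1, 2, 2, 4 ...), mirroring published priority lists."""
    df = pd.DataFrame(
        {
            "species": [s.species for s in scores],
            "pd": [s.pd_terminal for s in scores],
            "ed": [s.ed for s in scores],
            "category": [s.category for s in scores],
            "edge": [s.edge for s in scores],
        }
    )
    for col in ("pd", "ed", "edge"):
        df[f"{col}_rank"] = df[col].rank(method="min", ascending=False).astype(int)
    return df.sort_values("edge_rank").reset_index(drop=True)
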