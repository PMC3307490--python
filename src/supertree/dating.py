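"""Divergence-time estimation from gene-tree relative node heights.

Each gene tree with branch lengths defines relative node heights: a node's
depth is its mean path length to its descendant leaves, normalized by the
root's depth.  Scaling by one or more fossil-anchored calibration points
turns the relative heights into absolute age estimates; every (gene x
calibration) combination yields one estimate per node, weighted by the
bootstrap support of that node on the gene tree.  Per node the estimates are
combined by a bootstrap-weighted mean (or, alternatively, the median), the
youngest fossil age overrides a younger genetic value, and the pooled
estimate distribution provides 95% CIs.  Nodes with no genetic estimate are
interpolated from clade sizes under a pure-birth model, and any negative
branch implied by the combined ages is clamped to zero length.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._tree_utils import clade_leafsets, leaf_labels
from .datedtree import DatedTree, FOSSIL_OVERRIDE, GENETIC, INTERPOLATED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationPoint:
    """A clade anchor: the taxa identifying a node, its calibration age in Ma,
    and optional hard bounds (for range calibrations, the midpoint is the
    calibration and the extremes the bounds)."""

    clade: frozenset
    calibration_age: float
    min_age: Optional[float] = None
    max_age: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "clade", frozenset(self.clade))
        if self.min_age is not None and self.min_age > self.calibration_age:
            raise ValueError("min_age must not exceed the calibration age")
        if self.max_age is not None and self.max_age < self.calibration_age:
            raise ValueError("max_age must not be below the calibration age")

    @classmethod
    def from_range(cls, clade, low: float, high: float) -> "CalibrationPoint":
        """Range calibration: midpoint as the age, extremes as constraints."""
        return cls(clade=frozenset(clade), calibration_age=(low + high) / 2.0,
                   min_age=low, max_age=high)

    def clamp(self, value: float) -> float:
        if self.min_age is not None:
            value = max(value, self.min_age)
        if self.max_age is not None:
            value = min(value, self.max_age)
        return value


@dataclass
class GeneEstimate:
    gene: str
    estimate: float
    weight: float  # bootstrap support in [0, 100]


@dataclass
class GeneEstimateSet:
    """All per-gene absolute age estimates gathered for one target node."""

    node_id: int
    entries: list = field(default_factory=list)


def read_calibrations_csv(path: str) -> list[CalibrationPoint]:
    """Read semicolon-separated calibration rows: clade_taxa;age;min;max
    (clade taxa comma-separated; empty min/max mean unbounded)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=";"):
            if not row or row[0].startswith("#"):
                continue
            taxa = frozenset(t.strip() for t in row[0].split(",") if t.strip())
            age = float(row[1])
            lo = float(row[2]) if len(row) > 2 and row[2].strip() else None
            hi = float(row[3]) if len(row) > 3 and row[3].strip() else None
            out.append(CalibrationPoint(taxa, age, lo, hi))
    return out


# ---------------------------------------------------------------------------
# relative heights and per-gene calibration
# ---------------------------------------------------------------------------

def relative_heights(gene_tree: dendropy.Tree) -> dict:
    """Node -> height relative to the root in [0, 1].

    A node's depth is the mean path length from the node to its descendant
    leaves; heights are depths normalized by the root depth.  Exact clock
    heights for ultrametric input.
    """
    stats = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            stats[node] = (1, 0.0)
        else:
            count = total = 0.0
            for ch in node.child_nodes():
                el = ch.edge.length or 0.0
                if el < 0:
                    raise ValueError("negative branch length")
                c, s = stats[ch]
                count += c
                total += s + c * el
            stats[node] = (count, total)
    root_c, root_s = stats[gene_tree.seed_node]
    root_depth = root_s / root_c
    if root_depth <= 0:
        raise ValueError("zero root depth")
    return {node: (s / c) / root_depth for node, (c, s) in stats.items()}


def _find_calibration_node(gene_tree: dendropy.Tree, clade: frozenset, sets=None):
    """The gene-tree node whose leaf set equals clade restricted to the gene's
    taxa (None if the restriction is trivial or not monophyletic there)."""
    sets = sets or clade_leafsets(gene_tree)
    taxa = sets[gene_tree.seed_node]
    target = clade & taxa
    if len(target) < 2:
        return None
    # smallest clade containing the restricted target = its MRCA
    best = None
    for node, labels in sets.items():
        if target <= labels and (best is None or len(labels) < len(sets[best])):
            best = node
    if best is None or sets[best] != target:
        return None
    return best


def calibrate_gene(
    heights: dict,
    calibrations: Sequence[CalibrationPoint],
    gene_tree: dendropy.Tree,
) -> dict:
    """Absolute age estimates per gene-tree node, pooled over calibrations.

    Each calibration whose clade maps to a node of the gene tree contributes
    one scaled estimate set; estimates at calibration nodes are clamped to the
    calibration's hard bounds before pooling.
    """
    sets = clade_leafsets(gene_tree)
    cal_nodes = {}
    for cal in calibrations:
        node = _find_calibration_node(gene_tree, cal.clade, sets)
        if node is None:
            logger.debug("calibration %s absent from gene tree; skipped", sorted(cal.clade)[:3])
            continue
        cal_nodes[cal] = node

    estimates: dict = {n: [] for n in heights if not n.is_leaf()}
    for cal, cal_node in cal_nodes.items():
        rel = heights[cal_node]
        if rel <= 0:
            continue
        scale = cal.calibration_age / rel
        for node in estimates:
            est = heights[node] * scale
            for c2, n2 in cal_nodes.items():
                if n2 is node:
                    est = c2.clamp(est)
            estimates[node].append(est)
    return estimates


# ---------------------------------------------------------------------------
# combination, correction, interpolation
# ---------------------------------------------------------------------------

def combine_estimates(
    node_estimates: GeneEstimateSet,
    fossil_min: Optional[float] = None,
    mode: str = "weighted-mean",
) -> tuple:
    """Combine one node's pooled estimates into (age, ci_low, ci_high, flag).

    The central value is the bootstrap-weighted mean (default) or the median;
    if a fossil minimum exists and exceeds it, the fossil age wins
    (``fossil-override``).  The CI is the 2.5th/97.5th percentile of the
    pooled distribution (genetic estimates plus the fossil age when present).
    """
    if mode not in ("weighted-mean", "median"):
        raise ValueError("mode must be 'weighted-mean' or 'median'")
    values = np.array([e.estimate for e in node_estimates.entries], dtype=float)
    weights = np.array([e.weight for e in node_estimates.entries], dtype=float)
    if values.size == 0:
        if fossil_min is None:
            return None, None, None, None
        return fossil_min, fossil_min, fossil_min, FOSSIL_OVERRIDE

    if mode == "weighted-mean" and weights.sum() > 0:
        central = float(np.average(values, weights=weights))
    elif mode == "weighted-mean":
        central = float(values.mean())
    else:
        central = float(np.median(values))

    pooled = values if fossil_min is None else np.append(values, fossil_min)
    ci_low, ci_high = (float(x) for x in np.percentile(pooled, [2.5, 97.5]))

    if fossil_min is not None and fossil_min > central:
        age, flag = fossil_min, FOSSIL_OVERRIDE
    else:
        age, flag = central, GENETIC
    ci_low = min(ci_low, age)
    ci_high = max(ci_high, age)
    return age, ci_low, ci_high, flag


def correct_negative_branches(dated: DatedTree) -> DatedTree:
    """Clamp, in pre-order, any child older than its parent to the parent's
    age (zero-length branch); idempotent."""
    for node in dated.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None or node.is_leaf():
            continue
        if node.age > parent.age:
            node.age = parent.age
            lo = getattr(node, "ci_low", None)
            hi = getattr(node, "ci_high", None)
            if lo is not None:
                node.ci_low = min(lo, node.age)
            if hi is not None:
                node.ci_high = max(hi, node.age) if hi >= node.age else node.age
    dated.refresh_branch_lengths()
    return dated


def interpolate_missing(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign ages to undated internal nodes from relative clade sizes under a
    pure-birth model: a node subtending k species, below its nearest dated
    ancestor of age T subtending m species, gets age T * ln(k) / ln(m).

    Works top-down so newly dated nodes serve as ancestors further down; the
    root must already be dated.
    """
    if getattr(tree.seed_node, "age", None) is None:
        raise ValueError("the root must be dated before interpolation")
    sets = clade_leafsets(tree)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.age = 0.0
            continue
        if getattr(node, "age", None) is not None:
            continue
        parent = node.parent_node
        T = parent.age
        m = len(sets[parent])
        k = len(sets[node])
        if m < 2:
            raise ValueError("dated ancestor subtends fewer than 2 species")
        node.age = T if k >= m else T * np.log(k) / np.log(m)
        node.age_origin = INTERPOLATED
    return tree


# ---------------------------------------------------------------------------
# orchestration: date a supertree from gene trees
# ---------------------------------------------------------------------------

def _node_weight(node: dendropy.Node, default: float) -> float:
    label = node.label
    if label not in (None, ""):
        try:
            return float(label)
        except ValueError:
            pass
    return default


def date_tree(
    supertree: dendropy.Tree,
    gene_trees: Sequence[tuple],
    calibrations: Sequence[CalibrationPoint],
    mode: str = "weighted-mean",
) -> DatedTree:
    """Date a (rooted) supertree topology from gene trees and calibrations.

    *gene_trees* is a sequence of ``(gene_name, tree)`` pairs where each tree
    is rooted, has branch lengths, and (optionally) bootstrap supports as
    internal node labels.  For every internal supertree node, each gene tree
    in which the node's clade (restricted to the gene's taxa) is monophyletic
    contributes its calibrated estimates, weighted by that gene node's
    bootstrap.  Calibrations whose clade matches a supertree node also act as
    fossil ages there (youngest-fossil override).  Undated nodes are
    interpolated, negative branches corrected.
    """
    universe = frozenset(leaf_labels(supertree))
    super_sets = clade_leafsets(supertree)

    # per-gene: relative heights -> absolute estimates, plus clade lookup
    prepared = []
    for gene_name, gtree in gene_trees:
        heights = relative_heights(gtree)
        per_node = calibrate_gene(heights, calibrations, gtree)
        gsets = clade_leafsets(gtree)
        sup_values = [
            _node_weight(n, -1.0) for n in gtree.preorder_internal_node_iter()
        ]
        have = [v for v in sup_values if v >= 0]
        default_w = float(np.mean(have)) if have else 1.0
        by_clade = {}
        for node, ests in per_node.items():
            by_clade[gsets[node]] = (ests, _node_weight(node, default_w))
        gene_taxa = frozenset(gsets[gtree.seed_node])
        prepared.append((gene_name, gene_taxa, by_clade))

    # fossil ages at supertree nodes
    fossil_at = {}
    for cal in calibrations:
        for node, clade in super_sets.items():
            if node.is_leaf():
                continue
            if clade == (cal.clade & universe) and len(clade) >= 2:
                fossil_at[node] = (
                    min(fossil_at[node], cal.calibration_age)
                    if node in fossil_at else cal.calibration_age
                )

    internal = [n for n in supertree.preorder_internal_node_iter()]
    for node_id, node in enumerate(internal, start=1):
        clade = super_sets[node]
        pool = GeneEstimateSet(node_id=node_id)
        for gene_name, gene_taxa, by_clade in prepared:
            target = clade & gene_taxa
            if len(target) < 2:
                continue
            hit = by_clade.get(frozenset(target))
            if hit is None:
                continue
            ests, weight = hit
            for est in ests:
                pool.entries.append(GeneEstimate(gene=gene_name, estimate=est, weight=weight))
        age, lo, hi, flag = combine_estimates(pool, fossil_at.get(node), mode=mode)
        node.age = age
        if age is not None:
            node.ci_low, node.ci_high, node.age_origin = lo, hi, flag

    interpolate_missing(supertree)
    dated = DatedTree(supertree, validate=False)
    correct_negative_branches(dated)
    dated.validate()
    return dated
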