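"""Weighted parsimony search over MRP matrices via a parsimony ratchet.

The weighted parsimony length of a tree is the sum over characters of the
character's weight times the minimum number of state changes needed on that
topology (missing entries are free).  Lengths are computed by a two-state
Sankoff dynamic program, which is exact on multifurcating trees as well.

The search roots every candidate tree at the fictional outgroup taxon, so the
space of unrooted topologies over the full taxon set maps one-to-one onto
rooted binary topologies over the real species.  Hill climbing uses rooted
nearest-neighbour-interchange (NNI) moves by default (subtree pruning and
regrafting, SPR, is available); the ratchet alternates hill climbs under
randomly perturbed and original character weights to escape local optima, and
all distinct topologies tying the best score are retained, up to a cap.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._tree_utils import internal_clades, leaf_labels, tree_from_clades
from .mrp import MISSING, MRPMatrix

_INF = np.int32(1_000_000)
_REL_TOL = 1e-9

#: search effort used in the original analysis (available via SearchConfig)
PAPER_N_BATCHES = 50
PAPER_ITERATIONS_PER_BATCH = 200
PAPER_MAX_TREES = 10_500


@dataclass
class SearchConfig:
    """Ratchet configuration.  Defaults are desk-scale; the original analysis
    used ``n_batches=50, iterations_per_batch=200, max_trees=10500``."""

    n_batches: int = 5
    iterations_per_batch: int = 50
    perturbation_fraction: float = 0.25
    max_trees: int = PAPER_MAX_TREES
    swap_move: str = "NNI"
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_batches, self.iterations_per_batch, self.max_trees) < 1:
            raise ValueError("counts must be positive")
        if not (0.0 < self.perturbation_fraction < 1.0):
            raise ValueError("perturbation_fraction must lie in (0, 1)")
        if self.swap_move not in ("NNI", "SPR"):
            raise ValueError("swap_move must be 'NNI' or 'SPR'")


@dataclass
class SearchResult:
    """All equally most-parsimonious trees found, their shared score, the
    strict consensus, and the per-batch best-score trace."""

    mp_trees: list
    score: float
    consensus: dendropy.Tree
    trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal mutable tree structure (rooted at the outgroup attachment point)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "taxon", "parent")

    def __init__(self, taxon=None):
        self.children = []
        self.taxon = taxon
        self.parent = None

    def add(self, child):
        child.parent = self
        self.children.append(child)


def _postorder(root):
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    out.reverse()
    return out


def _copy(root):
    new = _Node(root.taxon)
    for c in root.children:
        new.add(_copy(c))
    return new


def _canonical(node) -> str:
    if node.taxon is not None:
        return str(node.taxon)
    return "(" + ",".join(sorted(_canonical(c) for c in node.children)) + ")"


def _random_rooted(taxon_ids: Sequence[int], rng: random.Random) -> _Node:
    """Random binary rooted tree by sequential random joins."""
    lineages = [_Node(t) for t in taxon_ids]
    rng.shuffle(lineages)
    while len(lineages) > 1:
        i = rng.randrange(len(lineages))
        a = lineages.pop(i)
        j = rng.randrange(len(lineages))
        b = lineages.pop(j)
        n = _Node()
        n.add(a)
        n.add(b)
        lineages.append(n)
    return lineages[0]


def _insert_subtree_everywhere(root, sub):
    """Yield fresh trees with a copy of *sub* joined onto every edge of a copy
    of *root* (including the edge above the root)."""
    n_positions = len(_postorder(root))
    for i in range(n_positions):
        new_root = _copy(root)
        target = _postorder(new_root)[i]
        joint = _Node()
        graft = _copy(sub)
        parent = target.parent
        if parent is None:
            joint.add(target)
            joint.add(graft)
            yield joint
        else:
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            joint.add(target)
            joint.add(graft)
            yield new_root


def _stepwise_addition(scorer: "_Scorer", taxon_ids, rng: random.Random):
    """Greedy stepwise-addition starting tree (random addition order)."""
    order = list(taxon_ids)
    rng.shuffle(order)
    root = _Node()
    root.add(_Node(order[0]))
    root.add(_Node(order[1]))
    for tid in order[2:]:
        best_tree, best_score = None, None
        for cand in _insert_subtree_everywhere(root, _Node(tid)):
            s = scorer.score(cand)
            if best_score is None or s < best_score - _REL_TOL:
                best_tree, best_score = cand, s
        root = best_tree
    return root


def _resolve_polytomies(root, rng: random.Random):
    for node in _postorder(root):
        while len(node.children) > 2:
            i = rng.randrange(len(node.children))
            a = node.children.pop(i)
            j = rng.randrange(len(node.children))
            b = node.children.pop(j)
            n = _Node()
            n.add(a)
            n.add(b)
            node.add(n)
            node.children[-1].parent = node
    return root


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _leaf_costs(codes: np.ndarray):
    """Per-taxon Sankoff leaf costs (cost-of-state-0, cost-of-state-1)."""
    c0 = np.where(codes == 1, _INF, 0).astype(np.int32)
    c1 = np.where(codes == 0, _INF, 0).astype(np.int32)
    return c0, c1


class _Scorer:
    """Vectorized two-state Sankoff over all characters at once."""

    def __init__(self, matrix: MRPMatrix):
        codes, weights = matrix.to_arrays()
        self.taxa = list(matrix.taxa)
        self.index = {t: i for i, t in enumerate(self.taxa)}
        self.og_index = self.index[matrix.outgroup]
        self.c0, self.c1 = _leaf_costs(codes)
        self.weights = weights

    def min_steps(self, root, extra_leaf: Optional[int] = None) -> np.ndarray:
        """Per-character minimum state changes of the rooted structure; if
        *extra_leaf* is given, that taxon joins at the root (outgroup)."""
        costs = {}
        for node in _postorder(root):
            if node.taxon is not None:
                costs[id(node)] = (self.c0[node.taxon], self.c1[node.taxon])
            else:
                a0 = np.zeros_like(self.weights, dtype=np.int32)
                a1 = np.zeros_like(a0)
                for ch in node.children:
                    b0, b1 = costs.pop(id(ch))
                    a0 = a0 + np.minimum(b0, b1 + 1)
                    a1 = a1 + np.minimum(b1, b0 + 1)
                costs[id(node)] = (a0, a1)
        r0, r1 = costs[id(root)]
        if extra_leaf is not None:
            e0, e1 = self.c0[extra_leaf], self.c1[extra_leaf]
            r0 = r0 + np.minimum(e0, e1 + 1)
            r1 = r1 + np.minimum(e1, e0 + 1)
        return np.minimum(r0, r1)

    def score(self, root, weights: Optional[np.ndarray] = None) -> float:
        w = self.weights if weights is None else weights
        return float(np.dot(w, self.min_steps(root, extra_leaf=self.og_index)))


def weighted_length(tree: dendropy.Tree, matrix: MRPMatrix) -> float:
    """Weighted parsimony length of *tree* (leaves = matrix taxa, outgroup
    included) under the matrix, with ``?`` treated as missing."""
    labels = leaf_labels(tree)
    if set(labels) != set(matrix.taxa):
        raise ValueError("tree leaf set must equal the matrix taxon set")
    scorer = _Scorer(matrix)
    index = scorer.index

    def build(dnode):
        if dnode.is_leaf():
            return _Node(index[dnode.taxon.label])
        n = _Node()
        for c in dnode.child_nodes():
            n.add(build(c))
        return n

    root = build(tree.seed_node)
    return float(np.dot(scorer.weights, scorer.min_steps(root)))


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------

def _nni_moves(root):
    """Yield (u, ui, v, vi) rooted-NNI moves: swap child *vi* of internal node
    *v* with *v*'s sibling (child *ui* of parent *u*)."""
    for u in _postorder(root):
        if u.taxon is not None or len(u.children) != 2:
            continue
        for k, v in enumerate(u.children):
            if v.taxon is not None:
                continue
            ui = 1 - k
            for vi in range(len(v.children)):
                yield u, ui, v, vi


def _apply_nni(u, ui, v, vi):
    s, c = u.children[ui], v.children[vi]
    u.children[ui], v.children[vi] = c, s
    c.parent, s.parent = u, v


def _detach_copy(root, prune):
    """Copy of the tree with the *prune* subtree removed (unary node
    suppressed), plus a copy of the pruned subtree."""
    mapping = {}

    def rec(node):
        new = _Node(node.taxon)
        mapping[id(node)] = new
        for c in node.children:
            new.add(rec(c))
        return new

    new_root = rec(root)
    p = mapping[id(prune)]
    par = p.parent
    par.children.remove(p)
    p.parent = None
    if len(par.children) == 1:
        only = par.children[0]
        if par.parent is None:
            only.parent = None
            new_root = only
        else:
            gp = par.parent
            gp.children[gp.children.index(par)] = only
            only.parent = gp
    return new_root, p


def _spr_neighbors(root):
    """All SPR rearrangements as fresh trees: prune every non-root subtree and
    regraft it on every edge of what remains."""
    nodes = _postorder(root)
    for prune in nodes:
        if prune is root:
            continue
        remaining, sub = _detach_copy(root, prune)
        if remaining.taxon is None and not remaining.children:
            continue
        yield from _insert_subtree_everywhere(remaining, sub)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _hill_climb(root, scorer: _Scorer, weights, swap_move: str, max_passes: int = 200):
    best = float(np.dot(weights, scorer.min_steps(root, extra_leaf=scorer.og_index)))
    for _ in range(max_passes):
        improved = False
        if swap_move == "NNI":
            best_move = None
            for move in _nni_moves(root):
                _apply_nni(*move)
                s = float(np.dot(weights, scorer.min_steps(root, extra_leaf=scorer.og_index)))
                _apply_nni(*move)
                if s < best * (1 - _REL_TOL) - _REL_TOL:
                    best, best_move = s, move
            if best_move is not None:
                _apply_nni(*best_move)
                improved = True
        else:
            best_tree = None
            for cand in _spr_neighbors(root):
                s = float(np.dot(weights, scorer.min_steps(cand, extra_leaf=scorer.og_index)))
                if s < best * (1 - _REL_TOL) - _REL_TOL:
                    best, best_tree = s, cand
            if best_tree is not None:
                root = best_tree
                improved = True
        if not improved:
            break
    return root, best


def _polish(root, scorer: _Scorer, weights, max_rounds: int = 25):
    """Alternate NNI climbing with single SPR sweeps until neither improves
    (the conventional heuristic search that follows the ratchet phase)."""
    root, best = _hill_climb(root, scorer, weights, "NNI")
    for _ in range(max_rounds):
        improved_tree = None
        for cand in _spr_neighbors(root):
            s = float(np.dot(weights, scorer.min_steps(cand, extra_leaf=scorer.og_index)))
            if s < best * (1 - _REL_TOL) - _REL_TOL:
                best, improved_tree = s, cand
        if improved_tree is None:
            break
        root, best = _hill_climb(improved_tree, scorer, weights, "NNI")
    return root, best


def _tie_closure(root, score, scorer, max_trees, max_expansions=200):
    """Breadth-first collection of equal-score NNI neighbours (the MP plateau)."""
    tol = abs(score) * _REL_TOL + _REL_TOL
    found = {_canonical(root): _copy(root)}
    queue = [root]
    expansions = 0
    while queue and len(found) < max_trees and expansions < max_expansions:
        cur = queue.pop(0)
        expansions += 1
        for move in _nni_moves(cur):
            _apply_nni(*move)
            s = scorer.score(cur)
            key = _canonical(cur)
            if abs(s - score) <= tol and key not in found:
                found[key] = _copy(cur)
                queue.append(found[key])
                if len(found) >= max_trees:
                    _apply_nni(*move)
                    break
            _apply_nni(*move)
    return list(found.values())


def _struct_to_dendropy(root, taxa, tns=None) -> dendropy.Tree:
    if tns is None:
        tns = dendropy.TaxonNamespace(sorted(set(taxa[i] for i in _leaf_ids(root))))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def attach(parent, node):
        if node.taxon is not None:
            parent.add_child(dendropy.Node(taxon=tns.get_taxon(taxa[node.taxon])))
        else:
            n = dendropy.Node()
            parent.add_child(n)
            for c in node.children:
                attach(n, c)

    for c in root.children:
        attach(tree.seed_node, c)
    if root.taxon is not None:  # degenerate single-leaf case
        tree.seed_node.taxon = tns.get_taxon(taxa[root.taxon])
    return tree


def _leaf_ids(root):
    return [n.taxon for n in _postorder(root) if n.taxon is not None]


def _dendropy_to_struct(tree: dendropy.Tree, index: dict, drop: Optional[str] = None):
    def build(dnode):
        if dnode.is_leaf():
            label = dnode.taxon.label
            if label == drop:
                return None
            return _Node(index[label])
        n = _Node()
        for c in dnode.child_nodes():
            sub = build(c)
            if sub is not None:
                n.add(sub)
        if not n.children:
            return None
        if len(n.children) == 1:
            only = n.children[0]
            only.parent = None
            return only
        return n

    return build(tree.seed_node)


def ratchet_search(
    matrix: MRPMatrix,
    config: Optional[SearchConfig] = None,
    start_tree: Optional[dendropy.Tree] = None,
) -> SearchResult:
    """Parsimony-ratchet search for all equally most-parsimonious trees.

    Returns topologies over the real species only (the fictional outgroup,
    which participates in the search, is pruned; trees are rooted at its
    attachment point).  Deterministic for a fixed ``config.rng_seed``.
    """
    config = config or SearchConfig()
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    scorer = _Scorer(matrix)
    rng = random.Random(config.rng_seed)
    nprng = np.random.default_rng(config.rng_seed)

    real_ids = [i for i, t in enumerate(matrix.taxa) if t != matrix.outgroup]
    if start_tree is not None:
        current = _dendropy_to_struct(start_tree, scorer.index, drop=matrix.outgroup)
        _resolve_polytomies(current, rng)
    else:
        current = _stepwise_addition(scorer, real_ids, rng)

    current, score = _hill_climb(current, scorer, scorer.weights, config.swap_move)
    best_score = score
    best = {_canonical(current): _copy(current)}
    trace = []

    nchar = matrix.n_characters
    n_perturb = max(1, int(round(config.perturbation_fraction * nchar)))
    tol = lambda s: abs(s) * _REL_TOL + _REL_TOL  # noqa: E731

    for batch in range(config.n_batches):
        if batch > 0 and start_tree is None:
            # random-addition-sequence restart
            current = _stepwise_addition(scorer, real_ids, rng)
        for _ in range(config.iterations_per_batch):
            perturbed = scorer.weights.copy()
            idx = nprng.choice(nchar, size=n_perturb, replace=False)
            perturbed[idx] *= 2.0
            current, _s = _hill_climb(current, scorer, perturbed, config.swap_move)
            current, score = _hill_climb(current, scorer, scorer.weights, config.swap_move)
            if score < best_score - tol(best_score):
                best_score = score
                best = {_canonical(current): _copy(current)}
            elif abs(score - best_score) <= tol(best_score):
                key = _canonical(current)
                if key not in best and len(best) < config.max_trees:
                    best[key] = _copy(current)
        # conventional heuristic search from the ratchet's incumbent
        current, score = _polish(_copy(next(iter(best.values()))), scorer, scorer.weights)
        if score < best_score - tol(best_score):
            best_score = score
            best = {_canonical(current): _copy(current)}
        trace.append(best_score)
        current = _copy(next(iter(best.values())))

    # sweep the equal-score plateau around every incumbent
    plateau = {}
    for t in list(best.values()):
        for x in _tie_closure(t, best_score, scorer, config.max_trees):
            plateau.setdefault(_canonical(x), x)
        if len(plateau) >= config.max_trees:
            break
    if len(plateau) > config.max_trees:
        plateau = dict(list(plateau.items())[: config.max_trees])

    tns = dendropy.TaxonNamespace(sorted(matrix.taxa[i] for i in real_ids))
    mp_trees = [
        _struct_to_dendropy(t, matrix.taxa, tns) for t in plateau.values()
    ]
    consensus = strict_consensus(mp_trees)
    return SearchResult(mp_trees=mp_trees, score=best_score, consensus=consensus, trace=trace)


def strict_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Rooted strict consensus: exactly the clades present in every input tree."""
    if not trees:
        raise ValueError("need at least one tree")
    leafsets = [frozenset(leaf_labels(t)) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("trees must share one leaf set")
    common = set(internal_clades(trees[0]))
    for t in trees[1:]:
        common &= set(internal_clades(t))
    return tree_from_clades(common, sorted(leafsets[0]), rooted=True)
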