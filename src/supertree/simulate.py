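"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator produces a true dated birth–death tree and derives from it the
heterogeneous evidence the pipeline ingests: literature-style source trees
(small taxon subsamples with local topological error and no support values,
mostly unrooted), gene trees (clock-like branch lengths with lognormal rate
noise per branch and per gene, missing taxa, bootstrap supports), a
less-resolved taxonomy tree used as the search seed, fossil-style calibration
points with bounded error, and Red List threat categories.  Every generator
is deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from ._tree_utils import apply_edge_lengths_from_ages, leaf_labels, restrict_to_labels
from .datedtree import DatedTree
from .dating import CalibrationPoint
from .sources import LITERATURE_CATEGORIES, MOLECULAR_GENE_CATEGORY, SourceTreeRecord

#: default Red List composition of the simulated fauna
THREAT_PROBS = {"LC": 0.50, "NT": 0.10, "VU": 0.15, "EN": 0.10, "CR": 0.05, "DD": 0.10}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe the standard recovery scenario: a 40-species pure-birth
    truth, 30 small literature trees each perturbed by one NNI move, six
    clock-like genes with lognormal rate noise, and one exact calibration at
    the root.
    """

    n_species: int = 40
    birth_rate: float = 0.2
    death_rate: float = 0.0
    n_literature_trees: int = 30
    literature_taxon_fraction: float = 0.4
    literature_rooted_fraction: float = 0.12  # most literature trees are unrooted
    nni_perturbations: int = 1
    n_genes: int = 6
    gene_taxon_fraction: float = 0.75
    gene_rate_sigma: float = 0.5  # lognormal spread of per-gene mean rates
    rate_noise_sigma: float = 0.2  # lognormal per-branch rate noise
    bootstrap_true: tuple = (8.0, 2.0)  # Beta params, scaled to [50, 100]
    bootstrap_perturbed: tuple = (2.0, 2.0)  # Beta params, scaled to [0, 70]
    n_calibrations: int = 1
    calibration_error_sigma: float = 0.0
    calibration_range_fraction: float = 0.0  # e.g. 0.10 emits a +/-10% range
    seed_collapse_fraction: float = 0.5  # taxonomy tree resolution loss
    rng_seed: int = 0

    def __post_init__(self):
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        for frac in (self.literature_taxon_fraction, self.gene_taxon_fraction):
            if not (0.0 < frac <= 1.0):
                raise ValueError("taxon fractions must lie in (0, 1]")


def _species_labels(n: int) -> list:
    return [f"sp{i + 1:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# true tree
# ---------------------------------------------------------------------------

def _yule_tree(n: int, birth_rate: float, rng: random.Random) -> DatedTree:
    """Pure-birth tree conditioned on n extant tips: internode intervals
    g_k ~ Exp(k*lambda) (k = 2..n) with ERM topology by random joins."""
    labels = _species_labels(n)
    tns = dendropy.TaxonNamespace(labels)
    lineages = [dendropy.Node(taxon=tns.get_taxon(lb)) for lb in labels]
    for lf in lineages:
        lf.age = 0.0
    rng.shuffle(lineages)
    # g_n is the most recent interval; build joins from the present backwards
    intervals = [rng.expovariate(k * birth_rate) for k in range(2, n + 1)]
    age = 0.0
    for g in reversed(intervals):  # g_n first
        age += g
        i = rng.randrange(len(lineages))
        a = lineages.pop(i)
        j = rng.randrange(len(lineages))
        b = lineages.pop(j)
        node = dendropy.Node()
        node.age = age
        node.add_child(a)
        node.add_child(b)
        lineages.append(node)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = lineages[0]
    tree.seed_node = root
    apply_edge_lengths_from_ages(tree)
    return DatedTree(tree)


def _birth_death_forward(n: int, birth: float, death: float, rng: random.Random,
                         max_tries: int = 1000) -> DatedTree:
    """Forward birth–death simulation, retried until exactly n lineages are
    extant when the n-th is born; extinct lineages pruned."""
    labels = _species_labels(n)
    for _ in range(max_tries):
        # each lineage: (birth_time, parent_idx); events forward in time
        nodes = [{"t0": 0.0, "parent": None, "t1": None, "children": []}]
        alive = [0]
        t = 0.0
        ok = False
        while alive:
            k = len(alive)
            if k == n:
                ok = True
                break
            t += rng.expovariate(k * (birth + death))
            idx = alive[rng.randrange(k)]
            if rng.random() < birth / (birth + death):
                for _c in range(2):
                    nodes.append({"t0": t, "parent": idx, "t1": None, "children": []})
                    nodes[idx]["children"].append(len(nodes) - 1)
                nodes[idx]["t1"] = t
                alive.remove(idx)
                alive.extend([len(nodes) - 2, len(nodes) - 1])
            else:
                nodes[idx]["t1"] = t
                alive.remove(idx)
        if not ok:
            continue
        present = t
        for idx in alive:
            nodes[idx]["t1"] = present

        # build, keeping only lineages with extant descendants
        def extant(idx):
            nd = nodes[idx]
            if not nd["children"]:
                return idx in alive
            return any(extant(c) for c in nd["children"])

        tns = dendropy.TaxonNamespace(labels)
        counter = [0]

        def build(idx):
            nd = nodes[idx]
            kids = [c for c in nd["children"] if extant(c)]
            if not kids:
                leaf = dendropy.Node(taxon=tns.get_taxon(labels[counter[0]]))
                counter[0] += 1
                leaf.age = 0.0
                return leaf
            if len(kids) == 1:
                return build(kids[0])
            node = dendropy.Node()
            node.age = present - nd["t1"]
            for c in kids:
                node.add_child(build(c))
            return node

        root = build(0)
        if root.is_leaf() or sum(1 for _ in root.leaf_iter()) != n:
            continue
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = True
        tree.seed_node = root
        apply_edge_lengths_from_ages(tree)
        return DatedTree(tree)
    raise RuntimeError(f"birth-death simulation failed to reach n={n} after {max_tries} tries")


def simulate_bd_tree(config: ScenarioConfig, rng: Optional[random.Random] = None) -> DatedTree:
    """True dated tree conditioned on ``config.n_species`` extant leaves."""
    rng = rng or random.Random(config.rng_seed)
    if config.death_rate == 0.0:
        return _yule_tree(config.n_species, config.birth_rate, rng)
    return _birth_death_forward(
        config.n_species, config.birth_rate, config.death_rate, rng
    )


# ---------------------------------------------------------------------------
# derived evidence
# ---------------------------------------------------------------------------

def _random_nni(tree: dendropy.Tree, rng: random.Random) -> None:
    """One random NNI move in place (no-op when no eligible edge exists)."""
    candidates = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        if node.parent_node is not None and len(node.child_nodes()) >= 2:
            candidates.append(node)
    if not candidates:
        return
    v = candidates[rng.randrange(len(candidates))]
    u = v.parent_node
    sibs = [c for c in u.child_nodes() if c is not v]
    s = sibs[rng.randrange(len(sibs))]
    c = v.child_nodes()[rng.randrange(len(v.child_nodes()))]
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)


def _subsample(true_tree: DatedTree, fraction: float, rng: random.Random,
               minimum: int = 4) -> dendropy.Tree:
    labels = true_tree.leaf_labels()
    k = max(minimum, int(round(fraction * len(labels))))
    chosen = rng.sample(labels, min(k, len(labels)))
    return restrict_to_labels(true_tree.tree, chosen)


def _strip(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node.edge.length = None
        if not node.is_leaf():
            node.label = None


def make_literature_trees(
    true_tree: DatedTree, config: ScenarioConfig, rng: Optional[random.Random] = None
) -> list[SourceTreeRecord]:
    """Literature-style records: taxon subsamples, k random NNI errors, no
    supports, mostly unrooted, random data category."""
    rng = rng or random.Random(config.rng_seed + 1)
    records = []
    for i in range(config.n_literature_trees):
        sub = _subsample(true_tree, config.literature_taxon_fraction, rng)
        for _ in range(config.nni_perturbations):
            _random_nni(sub, rng)
        _strip(sub)
        records.append(
            SourceTreeRecord(
                tree=sub,
                rooted=(rng.random() < config.literature_rooted_fraction),
                publication_id=f"lit{i + 1:03d}",
                data_category=LITERATURE_CATEGORIES[rng.randrange(len(LITERATURE_CATEGORIES))],
                permutation_count=1,
            )
        )
    return records


def _beta_scaled(rng: random.Random, params: tuple, lo: float, hi: float) -> float:
    return lo + (hi - lo) * rng.betavariate(*params)


def make_gene_trees(
    true_tree: DatedTree, config: ScenarioConfig, rng: Optional[random.Random] = None
) -> list[tuple]:
    """Gene trees as ``(gene_name, tree)`` pairs: taxon subsamples of the true
    topology with branch lengths = true durations x per-branch lognormal rate
    noise x a per-gene rate, and bootstrap supports as internal node labels
    (high Beta regime on true clades).  Rooted."""
    rng = rng or random.Random(config.rng_seed + 2)
    out = []
    for g in range(config.n_genes):
        sub = _subsample(true_tree, config.gene_taxon_fraction, rng)
        gene_rate = rng.lognormvariate(0.0, config.gene_rate_sigma)
        for node in sub.preorder_node_iter():
            if node.parent_node is None:
                node.edge.length = None
                continue
            duration = node.edge.length or 0.0
            noise = (
                rng.lognormvariate(0.0, config.rate_noise_sigma)
                if config.rate_noise_sigma > 0 else 1.0
            )
            node.edge.length = duration * gene_rate * noise
        for node in sub.preorder_internal_node_iter():
            if node is sub.seed_node:
                node.label = None
                continue
            node.label = f"{_beta_scaled(rng, config.bootstrap_true, 50.0, 100.0):.1f}"
        sub.is_rooted = True
        out.append((f"gene{g + 1:02d}", sub))
    return out


def make_seed_taxonomy_tree(
    true_tree: DatedTree, config: ScenarioConfig, rng: Optional[random.Random] = None
) -> SourceTreeRecord:
    """A less-resolved rooted taxonomy tree over all species: the true
    topology with a fraction of internal nodes collapsed into polytomies."""
    rng = rng or random.Random(config.rng_seed + 3)
    copy = restrict_to_labels(true_tree.tree, true_tree.leaf_labels())
    for node in list(copy.preorder_internal_node_iter()):
        if node is copy.seed_node or node.parent_node is None:
            continue
        if rng.random() < config.seed_collapse_fraction:
            parent = node.parent_node
            for ch in list(node.child_nodes()):
                node.remove_child(ch)
                parent.add_child(ch)
            parent.remove_child(node)
    _strip(copy)
    copy.is_rooted = True
    return SourceTreeRecord(
        tree=copy, rooted=True, publication_id="TAXONOMY",
        data_category="taxonomy", permutation_count=1,
    )


def make_calibrations(
    true_tree: DatedTree, config: ScenarioConfig, rng: Optional[random.Random] = None
) -> list[CalibrationPoint]:
    """Calibration points at sampled nodes (the root first), with lognormal
    age error and optionally a symmetric range whose midpoint is the
    calibration age."""
    rng = rng or random.Random(config.rng_seed + 4)
    sets = true_tree.clades()
    internal = [n for n in true_tree.internal_nodes()]
    if config.n_calibrations > len(internal):
        raise ValueError("more calibrations than internal nodes")
    chosen = [true_tree.tree.seed_node]
    others = [n for n in internal if n is not true_tree.tree.seed_node]
    rng.shuffle(others)
    chosen.extend(others[: config.n_calibrations - 1])

    out = []
    for node in chosen[: config.n_calibrations]:
        age = node.age
        if config.calibration_error_sigma > 0:
            age *= rng.lognormvariate(0.0, config.calibration_error_sigma)
        if config.calibration_range_fraction > 0:
            half = config.calibration_range_fraction * age
            out.append(CalibrationPoint.from_range(sets[node], age - half, age + half))
        else:
            out.append(CalibrationPoint(clade=sets[node], calibration_age=age))
    return out


def make_threat_categories(
    species: Sequence[str], rng: Optional[random.Random] = None,
    probs: Optional[dict] = None,
) -> dict:
    """Random Red List categories with a realistic composition."""
    rng = rng or random.Random(0)
    probs = probs or THREAT_PROBS
    cats = list(probs)
    weights = [probs[c] for c in cats]
    return {sp: rng.choices(cats, weights=weights)[0] for sp in species}


@dataclass
class Scenario:
    """One fully generated scenario: truth plus every derived input."""

    config: ScenarioConfig
    true_tree: DatedTree
    literature: list
    gene_trees: list
    seed_tree: SourceTreeRecord
    calibrations: list
    threat_categories: dict = field(default_factory=dict)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate every input from one seed (byte-identical per seed)."""
    rng = random.Random(config.rng_seed)
    true_tree = simulate_bd_tree(config, rng)
    literature = make_literature_trees(true_tree, config, random.Random(config.rng_seed + 1))
    gene_trees = make_gene_trees(true_tree, config, random.Random(config.rng_seed + 2))
    seed_tree = make_seed_taxonomy_tree(true_tree, config, random.Random(config.rng_seed + 3))
    calibrations = make_calibrations(true_tree, config, random.Random(config.rng_seed + 4))
    categories = make_threat_categories(
        true_tree.leaf_labels(), random.Random(config.rng_seed + 5)
    )
    return Scenario(
        config=config, true_tree=true_tree, literature=literature,
        gene_trees=gene_trees, seed_tree=seed_tree,
        calibrations=calibrations, threat_categories=categories,
    )
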