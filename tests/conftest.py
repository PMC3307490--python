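"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms: parsimony
lengths come from exhaustive enumeration of internal state assignments, and
tree-space minima from exhaustive topology enumeration.
"""

from __future__ import annotations

import itertools
import random

import dendropy
import pytest

from supertree import TaxonRegistry


# ---------------------------------------------------------------------------
# registries and small trees
# ---------------------------------------------------------------------------

@pytest.fixture
def registry() -> TaxonRegistry:
    return TaxonRegistry(
        valid_names={"A", "B", "C", "D", "E", "Canis lupus", "X"},
        synonym_map={"Asyn": "A", "Bsyn": "B", "OUT": "DELETE"},
        type_species_map={"Canidae": "Canis lupus"},
    )


def tree_of(newick: str, rooted: bool = True) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = rooted
    return t


@pytest.fixture
def tree_factory():
    return tree_of


# ---------------------------------------------------------------------------
# parsimony oracle: exhaustive internal-state enumeration
# ---------------------------------------------------------------------------

def brute_force_steps(tree: dendropy.Tree, states: dict) -> int:
    """Minimum state changes for one binary character by enumerating every
    assignment of {0,1} to internal nodes and unscored leaves."""
    nodes = list(tree.preorder_node_iter())
    fixed = {}
    free = []
    for node in nodes:
        if node.is_leaf() and node.taxon.label in states:
            fixed[node] = states[node.taxon.label]
        else:
            free.append(node)
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        changes = sum(
            1
            for node in nodes
            if node.parent_node is not None
            and assign[node] != assign[node.parent_node]
        )
        if best is None or changes < best:
            best = changes
    return best


@pytest.fixture
def parsimony_oracle():
    return brute_force_steps


# ---------------------------------------------------------------------------
# exhaustive rooted-topology enumeration (tuples), plus conversion
# ---------------------------------------------------------------------------

def _insert_everywhere(tree, leaf):
    yield (tree, leaf)  # above the current root
    if isinstance(tree, tuple):
        a, b = tree
        for sub in _insert_everywhere(a, leaf):
            yield (sub, b)
        for sub in _insert_everywhere(b, leaf):
            yield (a, sub)


def rooted_topologies(labels):
    """Every rooted binary topology over the labels, as nested 2-tuples
    ((2n-3)!! of them)."""
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    for smaller in rooted_topologies(labels[:-1]):
        yield from _insert_everywhere(smaller, labels[-1])


def tuples_to_newick(tree) -> str:
    if isinstance(tree, tuple):
        return "(" + ",".join(tuples_to_newick(c) for c in tree) + ")"
    return str(tree)


@pytest.fixture
def topology_enumerator():
    return rooted_topologies


def feliform_backbone():
    """Dated backbone rebuilt from the published node ages and clade sizes:
    Prionodontidae crown 10.9 Ma (2 sp), Felidae split 52.9 Ma (42 sp above),
    Feliformia crown 53.2 Ma (121 sp), Carnivora crown 64.9 Ma (286 sp); the
    Carnivora stem reaches back to 89.6 Ma (handled as a root stem)."""
    from supertree import DatedTree
    from supertree._tree_utils import apply_edge_lengths_from_ages

    labels = (
        ["Prionodon linsang", "Prionodon pardicolor", "Nandinia binotata"]
        + [f"felid{i}" for i in range(40)]
        + [f"felif{i}" for i in range(78)]
        + [f"canif{i}" for i in range(165)]
    )
    tns = dendropy.TaxonNamespace(labels)

    def polytomy(names, age):
        node = dendropy.Node()
        node.age = age
        for nm in names:
            leaf = dendropy.Node(taxon=tns.get_taxon(nm))
            leaf.age = 0.0
            node.add_child(leaf)
        return node

    prion = polytomy(["Prionodon linsang", "Prionodon pardicolor"], 10.9)
    split = dendropy.Node()
    split.age = 52.9
    split.add_child(prion)
    split.add_child(polytomy([f"felid{i}" for i in range(40)], 16.3))
    felif = dendropy.Node()
    felif.age = 53.2
    nandinia = dendropy.Node(taxon=tns.get_taxon("Nandinia binotata"))
    nandinia.age = 0.0
    felif.add_child(nandinia)
    felif.add_child(split)
    felif.add_child(polytomy([f"felif{i}" for i in range(78)], 30.0))
    root = dendropy.Node()
    root.age = 64.9
    root.add_child(felif)
    root.add_child(polytomy([f"canif{i}" for i in range(165)], 61.2))

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    tree.seed_node = root
    apply_edge_lengths_from_ages(tree)
    return DatedTree(tree)


def random_rooted_tuples(labels, rng: random.Random):
    """Random rooted binary topology by sequential random joins."""
    lineages = list(labels)
    rng.shuffle(lineages)
    while len(lineages) > 1:
        a = lineages.pop(rng.randrange(len(lineages)))
        b = lineages.pop(rng.randrange(len(lineages)))
        lineages.append((a, b))
    return lineages[0]
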