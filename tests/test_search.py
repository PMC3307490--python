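"""Weighted parsimony lengths and the ratchet search, against exhaustive oracles."""

import random

import dendropy
import pytest

from supertree import (
    MRPCharacter,
    MRPMatrix,
    SearchConfig,
    ratchet_search,
    strict_consensus,
    weighted_length,
)
from supertree._tree_utils import canonical_topology_id
from supertree.mrp import matrix_from_records
from supertree.sources import SourceTreeRecord

from conftest import (
    brute_force_steps,
    random_rooted_tuples,
    rooted_topologies,
    tree_of,
    tuples_to_newick,
)


def random_character(taxa, rng, score_outgroup=None):
    while True:
        states = {}
        for t in taxa:
            r = rng.random()
            if r < 0.2:
                continue  # missing
            states[t] = 1 if r < 0.6 else 0
        ones = sum(1 for v in states.values() if v == 1)
        zeros = sum(1 for v in states.values() if v == 0)
        if ones >= 2 and zeros >= 1:
            break
    if score_outgroup is not None:
        states[score_outgroup] = 0
    return MRPCharacter(states, weight=rng.choice([0.5, 1.0, 2.0, 3.5]))


class TestWeightedLength:
    def test_compatible_character_costs_one_step(self):
        m = MRPMatrix(
            taxa=["A", "B", "C", "D", "OG"], outgroup="OG",
            characters=[MRPCharacter({"A": 1, "B": 1, "C": 0, "D": 0}, weight=2.0)],
        )
        assert weighted_length(tree_of("((A,B),(C,D),OG);"), m) == pytest.approx(2.0)

    def test_incompatible_character_costs_two_steps(self):
        m = MRPMatrix(
            taxa=["A", "B", "C", "D", "OG"], outgroup="OG",
            characters=[MRPCharacter({"A": 1, "B": 1, "C": 0, "D": 0}, weight=2.0)],
        )
        assert weighted_length(tree_of("((A,C),(B,D),OG);"), m) == pytest.approx(4.0)

    def test_leaf_mismatch_rejected(self):
        m = MRPMatrix(
            taxa=["A", "B", "C", "OG"], outgroup="OG",
            characters=[MRPCharacter({"A": 1, "B": 1, "C": 0})],
        )
        with pytest.raises(ValueError):
            weighted_length(tree_of("((A,B),(C,D),OG);"), m)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 7)  # + outgroup: at most 8 taxa
        taxa = [f"t{i}" for i in range(n)]
        chars = [
            random_character(taxa, rng, score_outgroup="OG" if rng.random() < 0.5 else None)
            for _ in range(rng.randint(1, 6))
        ]
        m = MRPMatrix(taxa=taxa + ["OG"], outgroup="OG", characters=chars)
        tpl = random_rooted_tuples(taxa + ["OG"], rng)
        tree = tree_of(tuples_to_newick(tpl) + ";")
        expected = sum(c.weight * brute_force_steps(tree, c.states) for c in chars)
        assert weighted_length(tree, m) == pytest.approx(expected)


class TestRatchetSearch:
    def _config(self, seed=0, batches=2, iters=10):
        return SearchConfig(n_batches=batches, iterations_per_batch=iters, rng_seed=seed)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_single_source_tree(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 12)
        labels = [f"t{i}" for i in range(n)]
        newick = tuples_to_newick(random_rooted_tuples(labels, rng)) + ";"
        rec = SourceTreeRecord(tree=tree_of(newick), rooted=True,
                               publication_id="p", data_category="karyotype")
        matrix = matrix_from_records([rec])
        result = ratchet_search(matrix, self._config(seed))
        assert result.score == pytest.approx(sum(c.weight for c in matrix.characters))
        assert canonical_topology_id(result.consensus) == canonical_topology_id(rec.tree)

    def test_recovers_thirty_taxon_tree(self):
        rng = random.Random(99)
        labels = [f"t{i}" for i in range(30)]
        newick = tuples_to_newick(random_rooted_tuples(labels, rng)) + ";"
        rec = SourceTreeRecord(tree=tree_of(newick), rooted=True,
                               publication_id="p", data_category="karyotype")
        matrix = matrix_from_records([rec])
        result = ratchet_search(matrix, self._config(99, batches=3, iters=15))
        assert result.score == pytest.approx(matrix.n_characters)
        assert canonical_topology_id(result.consensus) == canonical_topology_id(rec.tree)

    def test_score_equals_exhaustive_minimum(self):
        rng = random.Random(7)
        taxa = [f"t{i}" for i in range(6)]
        chars = [
            random_character(taxa, rng, score_outgroup="OG" if rng.random() < 0.5 else None)
            for _ in range(20)
        ]
        matrix = MRPMatrix(taxa=taxa + ["OG"], outgroup="OG", characters=chars)

        # oracle: every unrooted 7-taxon topology = every rooted 6-taxon
        # topology with the outgroup attached at the root (945 trees)
        best = None
        count = 0
        for tpl in rooted_topologies(taxa):
            count += 1
            tree = tree_of("(" + tuples_to_newick(tpl) + ",OG);")
            s = weighted_length(tree, matrix)
            best = s if best is None else min(best, s)
        assert count == 945

        result = ratchet_search(matrix, self._config(7, batches=3, iters=20))
        assert result.score == pytest.approx(best)

    def test_conflicting_characters_collapse_consensus(self):
        matrix = MRPMatrix(
            taxa=["A", "B", "C", "D", "OG"], outgroup="OG",
            characters=[
                MRPCharacter({"A": 1, "B": 1, "C": 0, "D": 0}),
                MRPCharacter({"A": 1, "C": 1, "B": 0, "D": 0}),
            ],
        )
        result = ratchet_search(matrix, self._config(1))
        # enumeration over the 3 quartet topologies gives a minimum of 3 steps
        assert result.score == pytest.approx(3.0)
        assert len(result.mp_trees) >= 2
        assert canonical_topology_id(result.consensus) == "(A,B,C,D)"

    def test_weight_scaling_scales_score_not_trees(self):
        rng = random.Random(3)
        taxa = [f"t{i}" for i in range(6)]
        chars = [random_character(taxa, rng) for _ in range(10)]
        m1 = MRPMatrix(taxa=taxa + ["OG"], outgroup="OG", characters=chars)
        r1 = ratchet_search(m1, self._config(3))
        scaled = [
            MRPCharacter(c.states, weight=c.weight * 7.0) for c in chars
        ]
        m2 = MRPMatrix(taxa=taxa + ["OG"], outgroup="OG", characters=scaled)
        r2 = ratchet_search(m2, self._config(3))
        assert r2.score == pytest.approx(7.0 * r1.score)
        assert (
            {canonical_topology_id(t) for t in r2.mp_trees}
            == {canonical_topology_id(t) for t in r1.mp_trees}
        )

    def test_trace_is_monotone_non_increasing(self):
        rng = random.Random(11)
        taxa = [f"t{i}" for i in range(8)]
        chars = [random_character(taxa, rng) for _ in range(15)]
        matrix = MRPMatrix(taxa=taxa + ["OG"], outgroup="OG", characters=chars)
        result = ratchet_search(matrix, self._config(11, batches=4, iters=10))
        assert all(a >= b - 1e-9 for a, b in zip(result.trace, result.trace[1:]))

    def test_deterministic_per_seed(self):
        rng = random.Random(5)
        taxa = [f"t{i}" for i in range(7)]
        chars = [random_character(taxa, rng) for _ in range(12)]
        matrix = MRPMatrix(taxa=taxa + ["OG"], outgroup="OG", characters=chars)
        r1 = ratchet_search(matrix, self._config(5))
        r2 = ratchet_search(matrix, self._config(5))
        assert r1.score == r2.score
        assert (
            [canonical_topology_id(t) for t in r1.mp_trees]
            == [canonical_topology_id(t) for t in r2.mp_trees]
        )


class TestStrictConsensus:
    def test_single_tree_is_its_own_consensus(self):
        t = tree_of("((A,B),(C,D));")
        assert canonical_topology_id(strict_consensus([t])) == canonical_topology_id(t)

    def test_shared_clade_survives(self):
        t1 = tree_of("((A,B),C,D);")
        t2 = tree_of("((A,B),(C,D));")
        assert canonical_topology_id(strict_consensus([t1, t2])) == "((A,B),C,D)"

    def test_all_quartets_collapse_to_star(self):
        trees = [tree_of(s) for s in
                 ("((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));")]
        assert canonical_topology_id(strict_consensus(trees)) == "(A,B,C,D)"

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            strict_consensus([tree_of("((A,B),C);"), tree_of("((A,B),D);")])
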