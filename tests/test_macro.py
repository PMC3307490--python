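"""LTT curves, gamma, segmented regression, binned rates, shifts, ERM."""

import math
import random

import numpy as np
import pytest

import supertree as st
from supertree._tree_utils import apply_edge_lengths_from_ages, canonical_topology_id

from conftest import tree_of


def dated_of(newick: str) -> st.DatedTree:
    return st.DatedTree.from_newick(newick)


def dated_from_ages(newick: str, ages: list) -> st.DatedTree:
    t = tree_of(newick)
    internal = list(t.preorder_internal_node_iter())
    for node, age in zip(internal, ages):
        node.age = age
    for lf in t.leaf_node_iter():
        lf.age = 0.0
    apply_edge_lengths_from_ages(t)
    return st.DatedTree(t)


class TestLTT:
    def test_cherry(self):
        curve = st.ltt(dated_of("(A:5,B:5);"))
        assert curve.event_times == [5.0] and curve.lineage_counts == [2]

    def test_balanced_four_leaf(self):
        curve = st.ltt(dated_from_ages("((A,B),(C,D));", [10.0, 4.0, 2.0]))
        assert curve.event_times == [10.0, 4.0, 2.0]
        assert curve.lineage_counts == [2, 3, 4]

    def test_polytomy_multiplicity(self):
        curve = st.ltt(dated_from_ages("((A,B,C),D);", [9.0, 3.0]))
        assert curve.event_times == [9.0, 3.0, 3.0]
        assert curve.lineage_counts == [2, 3, 4]

    def test_final_count_equals_leaf_count(self):
        tree = st.simulate_bd_tree(st.ScenarioConfig(n_species=25, rng_seed=2))
        curve = st.ltt(tree)
        assert curve.lineage_counts[-1] == 25
        assert curve.lineage_counts == sorted(curve.lineage_counts)


class TestGamma:
    def test_three_leaf_closed_form(self):
        # g_2 = g_3 = 1: gamma = (2 - 2.5) / (5 * sqrt(1/12))
        result = st.gamma_stat(dated_of("((A:1,B:1):1,C:2);"))
        expected = (2 - 2.5) / (5 * math.sqrt(1 / 12))
        assert result.gamma == pytest.approx(expected, abs=1e-9)
        assert result.n == 3

    def test_weighted_intervals_sum_to_total_path_time(self):
        tree = st.simulate_bd_tree(st.ScenarioConfig(n_species=20, rng_seed=7))
        result = st.gamma_stat(tree)
        total = sum(k * g for k, g in zip(range(2, result.n + 1),
                                          result.internode_intervals))
        assert total == pytest.approx(tree.total_branch_length())

    def test_polytomies_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            st.gamma_stat(dated_from_ages("((A,B,C),D);", [9.0, 3.0]))

    def test_yule_null_is_centred(self):
        gammas = [
            st.gamma_stat(
                st.simulate_bd_tree(st.ScenarioConfig(n_species=30, rng_seed=s))
            ).gamma
            for s in range(100)
        ]
        assert abs(float(np.mean(gammas))) < 0.25


class TestSegmentedFit:
    def test_pure_exponential_needs_no_breakpoint(self):
        rate = 0.2
        times = np.linspace(50, 1, 60)
        counts = 2 * np.exp(rate * (50 - times))
        curve = st.LTTCurve(list(times), list(counts))
        fit = st.segmented_fit(curve)
        assert fit.n_breakpoints == 0
        assert fit.slopes[0] == pytest.approx(rate, abs=1e-9)

    def test_two_phase_curve_recovers_breakpoint_and_slopes(self):
        s1, s2, bp = 0.1, 0.3, 20.0
        times = np.linspace(50, 0.25, 200)

        def lncount(t):
            x = 50 - t  # elapsed since the first event
            return s1 * min(x, 50 - bp) + s2 * max(0.0, x - (50 - bp)) + math.log(2)

        counts = [math.exp(lncount(t)) for t in times]
        fit = st.segmented_fit(st.LTTCurve(list(times), counts))
        assert fit.n_breakpoints == 1
        assert fit.breakpoints[0] == pytest.approx(bp, abs=0.3)
        assert fit.slopes[0] == pytest.approx(s1, abs=1e-3)
        assert fit.slopes[1] == pytest.approx(s2, abs=1e-3)

    def test_chosen_aic_never_worse_than_zero_breakpoints(self):
        tree = st.simulate_bd_tree(st.ScenarioConfig(n_species=40, rng_seed=9))
        fit = st.segmented_fit(st.ltt(tree))
        assert fit.aic[fit.n_breakpoints] <= fit.aic[0] + 1e-9


class TestBinnedRates:
    def test_bin_without_events_is_zero(self):
        rates = st.binned_rates(dated_of("(A:1.0,B:1.0);"), width=0.25)
        assert rates.rates[0] == 0.0 and not rates.zero_exposure[0]

    def test_exposure_arithmetic(self):
        # two lineages throughout [0.25, 0.5) with the branching event at the
        # bin's lower edge: exposure 2 x 0.25, rate 1/0.5 = 2 per Ma
        dated = dated_from_ages("((A,B),C);", [1.0, 0.25])
        rates = st.binned_rates(dated, width=0.25)
        b = 1  # bin [0.25, 0.5)
        assert rates.events[b] == 1
        assert rates.exposure[b] == pytest.approx(0.5)
        assert rates.rates[b] == pytest.approx(2.0)

    def test_constant_rate_yule_scatter(self):
        tree = st.simulate_bd_tree(
            st.ScenarioConfig(n_species=200, birth_rate=0.2, rng_seed=4)
        )
        rates = st.binned_rates(tree, width=0.25)
        mask = rates.exposure > 5.0  # well-populated bins only
        pooled = rates.events[mask].sum() / rates.exposure[mask].sum()
        assert pooled == pytest.approx(0.2, rel=0.25)

    def test_ln_diff_alternative_estimator(self):
        tree = st.simulate_bd_tree(st.ScenarioConfig(n_species=50, rng_seed=6))
        rates = st.binned_rates(tree, width=1.0, method="ln-diff")
        assert np.all(np.isfinite(rates.rates))


class TestSlowinskiGuyer:
    from hypothesis import given, settings
    from hypothesis import strategies as hs

    @given(r=hs.integers(1, 500), s=hs.integers(2, 500))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_and_range_property(self, r, s):
        p = st.slowinski_guyer(r, s)
        assert p == st.slowinski_guyer(s, r)
        assert 0.0 < p <= 1.0

    @pytest.mark.parametrize(
        "r,s,expected",
        [(8, 122, 16 / 129), (2, 33, 4 / 34), (1, 120, 2 / 120), (1, 9, 2 / 9)],
    )
    def test_closed_form(self, r, s, expected):
        assert st.slowinski_guyer(r, s) == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = random.Random(0)
        for _ in range(50):
            r, s = rng.randint(1, 200), rng.randint(2, 200)
            p = st.slowinski_guyer(r, s)
            assert p == st.slowinski_guyer(s, r)
            assert 0.0 < p <= 1.0

    def test_balanced_split_caps_at_one(self):
        assert st.slowinski_guyer(10, 10) == 1.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            st.slowinski_guyer(1, 1)


class TestLagPercent:
    @pytest.mark.parametrize(
        "crown,origin,expected",
        [(64.9, 89.6, 27.6), (5.3, 27.0, 80.4), (16.3, 52.9, 69.2)],
    )
    def test_printed_family_values(self, crown, origin, expected):
        assert st.lag_percent(crown, origin) == pytest.approx(expected, abs=0.05)

    def test_zero_when_crown_equals_origin(self):
        assert st.lag_percent(12.0, 12.0) == 0.0

    def test_crown_older_than_origin_rejected(self):
        with pytest.raises(ValueError):
            st.lag_percent(30.0, 20.0)


class TestERMResolution:
    def test_binary_tree_unchanged(self):
        dated = dated_from_ages("((A,B),(C,D));", [10.0, 4.0, 2.0])
        out = st.resolve_polytomies_erm(dated, rng_seed=1)
        assert canonical_topology_id(out.tree) == canonical_topology_id(dated.tree)

    def test_trifurcation_resolutions_uniform(self):
        counts = {}
        for seed in range(3000):
            dated = dated_from_ages("((A,B,C),D);", [9.0, 3.0])
            out = st.resolve_polytomies_erm(dated, rng_seed=seed)
            counts[canonical_topology_id(out.tree)] = (
                counts.get(canonical_topology_id(out.tree), 0) + 1
            )
        assert len(counts) == 3
        for c in counts.values():
            assert c / 3000 == pytest.approx(1 / 3, abs=0.05)

    def test_leaf_count_and_ages_preserved(self):
        dated = dated_from_ages("((A,B,C,D,E),(F,G));", [9.0, 3.0, 1.0])
        out = st.resolve_polytomies_erm(dated, rng_seed=3)
        assert out.n_leaves == dated.n_leaves
        assert out.is_binary()
        out.validate()

    def test_deterministic_per_seed(self):
        dated = dated_from_ages("((A,B,C,D,E),(F,G));", [9.0, 3.0, 1.0])
        a = st.resolve_polytomies_erm(dated, rng_seed=5)
        b = st.resolve_polytomies_erm(dated, rng_seed=5)
        assert canonical_topology_id(a.tree) == canonical_topology_id(b.tree)


class TestFamilyCorrelations:
    def test_perfectly_collinear(self):
        table = {
            "crown_age": [1.0, 2.0, 3.0, 4.0],
            "origin_age": [2.0, 4.0, 6.0, 8.0],
            "lag_percent": [50.0, 50.0, 50.0, 50.0],
            "n_species": [10, 20, 30, 40],
        }
        out = st.family_correlations(table)
        assert out["crown_age"][0] == pytest.approx(1.0)
        assert out["crown_age"][1] < 1e-6
        assert math.isnan(out["lag_percent"][0])  # zero variance

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            st.family_correlations({"crown_age": [1], "origin_age": [1],
                                    "lag_percent": [1], "n_species": [1]})


def test_shift_tests_cover_bifurcating_nodes():
    dated = dated_from_ages("(((A,B),C),(D,E));", [10.0, 6.0, 2.0, 4.0])
    tests = st.shift_tests(dated)
    sizes = {t.clade_sizes for t in tests}
    assert (2, 3) in sizes and (1, 2) in sizes
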