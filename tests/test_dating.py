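"""Relative-height dating: calibration, combination, correction, interpolation."""

import math
import random

import numpy as np
import pytest

import supertree as st
from supertree.datedtree import FOSSIL_OVERRIDE, GENETIC
from supertree.dating import GeneEstimate, GeneEstimateSet, _find_calibration_node

from conftest import tree_of


class TestRelativeHeights:
    def test_ultrametric_gives_exact_clock_heights(self):
        t = tree_of("((A:5,B:5):5,(C:2,D:2):8);")
        heights = st.relative_heights(t)
        by_val = sorted(round(v, 6) for v in heights.values())
        assert by_val == [0.0, 0.0, 0.0, 0.0, 0.2, 0.5, 1.0]

    def test_root_is_one_and_leaves_zero(self):
        t = tree_of("((A:1,B:1):1,C:2);")
        heights = st.relative_heights(t)
        assert heights[t.seed_node] == pytest.approx(1.0)
        assert all(heights[lf] == 0.0 for lf in t.leaf_node_iter())

    def test_mean_path_on_non_ultrametric_tree(self):
        t = tree_of("((A:1,B:3):2,C:4);")
        heights = st.relative_heights(t)
        internal = [n for n in t.preorder_internal_node_iter() if n is not t.seed_node]
        assert heights[internal[0]] == pytest.approx(0.5)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            st.relative_heights(tree_of("((A:0,B:0):0,C:0);"))


class TestCalibrateGene:
    def test_single_root_calibration_scales_heights(self):
        t = tree_of("((A:5,B:5):5,C:10);")
        cal = st.CalibrationPoint(clade=frozenset({"A", "B", "C"}), calibration_age=10.0)
        estimates = st.calibrate_gene(st.relative_heights(t), [cal], t)
        ab = _find_calibration_node(t, frozenset({"A", "B"}))
        assert estimates[ab] == [pytest.approx(5.0)]

    def test_internal_calibration_proportional_scaling(self):
        # node at relative height 0.6 calibrated to 6 -> node at 0.3 gets 3
        t = tree_of("(((A:3,B:3):3,C:6):4,D:10);")
        cal = st.CalibrationPoint(clade=frozenset({"A", "B", "C"}), calibration_age=6.0)
        estimates = st.calibrate_gene(st.relative_heights(t), [cal], t)
        ab = _find_calibration_node(t, frozenset({"A", "B"}))
        assert estimates[ab] == [pytest.approx(3.0)]

    def test_two_calibrations_pool_two_estimates(self):
        t = tree_of("((A:5,B:5):5,C:10);")
        cals = [
            st.CalibrationPoint(frozenset({"A", "B", "C"}), 10.0),
            st.CalibrationPoint(frozenset({"A", "B", "C"}), 12.0),
        ]
        estimates = st.calibrate_gene(st.relative_heights(t), cals, t)
        ab = _find_calibration_node(t, frozenset({"A", "B"}))
        assert sorted(estimates[ab]) == [pytest.approx(5.0), pytest.approx(6.0)]

    def test_absent_calibration_skipped(self):
        t = tree_of("((A:5,B:5):5,C:10);")
        cal = st.CalibrationPoint(frozenset({"X", "Y"}), 42.0)
        estimates = st.calibrate_gene(st.relative_heights(t), [cal], t)
        assert all(v == [] for v in estimates.values())

    def test_bounds_clamp_at_calibration_node(self):
        t = tree_of("((A:5,B:5):5,C:10);")
        cals = [
            st.CalibrationPoint(frozenset({"A", "B", "C"}), 10.0),
            st.CalibrationPoint(frozenset({"A", "B"}), 7.0, min_age=6.5, max_age=8.0),
        ]
        estimates = st.calibrate_gene(st.relative_heights(t), cals, t)
        ab = _find_calibration_node(t, frozenset({"A", "B"}))
        # root scale gives 5.0 at AB, clamped up to the 6.5 floor
        assert min(estimates[ab]) >= 6.5


class TestCombineEstimates:
    def _pool(self, pairs):
        return GeneEstimateSet(
            node_id=1, entries=[GeneEstimate("g", e, w) for e, w in pairs]
        )

    def test_single_estimate(self):
        age, lo, hi, flag = st.combine_estimates(self._pool([(10.0, 100.0)]))
        assert age == 10.0 and flag == GENETIC and lo <= age <= hi

    def test_fossil_override(self):
        age, _, hi, flag = st.combine_estimates(self._pool([(10.0, 100.0)]), fossil_min=12.0)
        assert age == 12.0 and flag == FOSSIL_OVERRIDE and hi >= 12.0

    def test_bootstrap_weighted_mean(self):
        age, *_ = st.combine_estimates(self._pool([(4.0, 50.0), (6.0, 150.0)]))
        assert age == pytest.approx(5.5)

    def test_median_mode(self):
        age, *_ = st.combine_estimates(
            self._pool([(1.0, 1.0), (2.0, 1.0), (9.0, 1.0)]), mode="median"
        )
        assert age == pytest.approx(2.0)

    def test_nothing_to_combine(self):
        assert st.combine_estimates(self._pool([])) == (None, None, None, None)


class TestNegativeBranchCorrection:
    def _dated(self, ages):
        t = tree_of("(((A,B),C),D);")
        internal = list(t.preorder_internal_node_iter())
        for node, age in zip(internal, ages):
            node.age = age
        for lf in t.leaf_node_iter():
            lf.age = 0.0
        return st.DatedTree(t, validate=False)

    def test_child_clamped_to_parent(self):
        dated = st.correct_negative_branches(self._dated([10.0, 12.0, 3.0]))
        ages = [n.age for n in dated.internal_nodes()]
        assert ages == [10.0, 10.0, 3.0]

    def test_cascading_clamp(self):
        dated = st.correct_negative_branches(self._dated([10.0, 12.0, 11.0]))
        ages = [n.age for n in dated.internal_nodes()]
        assert ages == [10.0, 10.0, 10.0]

    def test_idempotent_on_valid_tree(self):
        dated = self._dated([10.0, 6.0, 3.0])
        once = st.correct_negative_branches(dated)
        again = st.correct_negative_branches(once)
        assert [n.age for n in again.internal_nodes()] == [10.0, 6.0, 3.0]


class TestInterpolation:
    def test_pure_birth_log_clade_size_formula(self):
        t = tree_of("(((a,b),(c,d)),((e,f),(g,h)));")
        t.seed_node.age = 10.0
        for n in t.preorder_node_iter():
            if n is not t.seed_node and not n.is_leaf():
                n.age = None
        st.interpolate_missing(t)
        half = t.seed_node.child_nodes()[0]
        assert half.age == pytest.approx(10 * math.log(4) / math.log(8))
        cherry = half.child_nodes()[0]
        # ancestor is the newly dated half-node (m = 4, k = 2)
        assert cherry.age == pytest.approx(half.age * math.log(2) / math.log(4))

    def test_cherry_under_root(self):
        t = tree_of("((a,b),c,d,e,f,g,h);")
        t.seed_node.age = 10.0
        for n in t.preorder_node_iter():
            if n is not t.seed_node and not n.is_leaf():
                n.age = None
        st.interpolate_missing(t)
        cherry = next(
            n for n in t.preorder_internal_node_iter() if n is not t.seed_node
        )
        assert cherry.age == pytest.approx(10 * math.log(2) / math.log(8))

    def test_undated_root_rejected(self):
        t = tree_of("((a,b),c);")
        t.seed_node.age = None
        with pytest.raises(ValueError):
            st.interpolate_missing(t)


class TestDateTreeRecovery:
    def _scenario(self, sigma, seed, n_genes, fraction=1.0):
        cfg = st.ScenarioConfig(
            n_species=40, rate_noise_sigma=sigma, gene_taxon_fraction=fraction,
            n_genes=n_genes, rng_seed=seed,
        )
        truth = st.simulate_bd_tree(cfg)
        genes = st.make_gene_trees(truth, cfg, random.Random(seed + 100))
        cals = st.make_calibrations(truth, cfg, random.Random(seed + 200))
        topo = truth.tree.clone(depth=1)
        for n in topo.preorder_node_iter():
            n.age = None
        return truth, st.date_tree(topo, genes, cals)

    def test_exact_recovery_with_clocklike_genes(self):
        truth, dated = self._scenario(sigma=0.0, seed=3, n_genes=6)
        true_ages = {c: n.age for n, c in truth.clades().items() if not n.is_leaf()}
        for node, clade in dated.clades().items():
            if not node.is_leaf():
                assert node.age == pytest.approx(true_ages[clade], abs=1e-9)

    def test_noisy_genes_small_error_and_good_coverage(self):
        truth, dated = self._scenario(sigma=0.2, seed=11, n_genes=8, fraction=0.9)
        true_ages = {c: n.age for n, c in truth.clades().items() if not n.is_leaf()}
        rel_err, covered, total = [], 0, 0
        for node, clade in dated.clades().items():
            if node.is_leaf():
                continue
            ta = true_ages[clade]
            total += 1
            rel_err.append(abs(node.age - ta) / ta)
            lo = getattr(node, "ci_low", None)
            hi = getattr(node, "ci_high", None)
            if lo is not None and hi is not None and lo <= ta <= hi:
                covered += 1
        assert float(np.median(rel_err)) < 0.10
        assert covered / total >= 0.90

    def test_output_is_ultrametric_with_leaves_at_zero(self):
        _, dated = self._scenario(sigma=0.2, seed=5, n_genes=4, fraction=0.7)
        dated.validate()  # parent >= child, leaves at 0, CIs bracket ages


def test_calibration_range_midpoint_and_bounds():
    cal = st.CalibrationPoint.from_range({"A", "B"}, 86.5, 105.7)
    assert cal.calibration_age == pytest.approx(96.1)
    assert cal.min_age == 86.5 and cal.max_age == 105.7


def test_calibration_csv_round_trip(tmp_path):
    path = tmp_path / "cals.csv"
    path.write_text("A,B,C;10.0;9.0;11.0\nA,B;5.0;;\n")
    cals = st.dating.read_calibrations_csv(str(path))
    assert cals[0].clade == frozenset({"A", "B", "C"})
    assert cals[0].min_age == 9.0 and cals[0].max_age == 11.0
    assert cals[1].min_age is None and cals[1].max_age is None
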