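"""Enrichment-tree induction: preprocessing, splitting, growth, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiprofiler.errors import DataError
from ppiprofiler.fixtures import PlantedRuleSpec, make_labeled_table
from ppiprofiler.tree import (
    EnrichmentTree,
    LabeledTable,
    best_split,
    grow_tree,
    kfold_consensus,
    preprocess,
)


def exhaustive_best_split(values, labels, min_count=1):
    """Independent brute-force oracle over every midpoint threshold."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    n = len(values)
    n_pos = labels.sum()
    if n_pos == 0:
        return None
    distinct = np.unique(values)
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2
        sel = values >= thr
        n_sel = int(sel.sum())
        if n_sel < min_count or n - n_sel < min_count:
            continue
        ef = (labels[sel].sum() / n_sel) / (n_pos / n)
        key = (ef, n_sel, -thr)
        if best is None or key > best[0]:
            best = (key, thr, ef, n_sel)
    if best is None or best[2] <= 1.0:
        return None
    return best[1], best[2], best[3]


class TestBestSplit:
    def test_simple_separable_example(self):
        s = best_split(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert s.threshold == 2.5
        assert s.ef == pytest.approx(2.0)

    def test_all_positive_no_split(self):
        assert best_split(np.array([1.0, 2, 3]), np.array([1, 1, 1])) is None

    def test_all_values_identical_no_split(self):
        assert best_split(np.array([5.0, 5, 5, 5]), np.array([0, 1, 0, 1])) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        values = rng.choice([0.5, 1.5, 2.5, 3.5, 4.5], size=n) + rng.normal(0, 1, n)
        labels = rng.integers(0, 2, size=n)
        got = best_split(values, labels)
        want = exhaustive_best_split(values, labels)
        if want is None:
            assert got is None
        else:
            assert got.threshold == pytest.approx(want[0])
            assert got.ef == pytest.approx(want[1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        values = np.round(rng.uniform(0, 10, n), 1)  # ties likely
        labels = (rng.random(n) < 0.3).astype(int)
        got = best_split(values, labels, min_count=2)
        want = exhaustive_best_split(values, labels, min_count=2)
        if want is None:
            assert got is None
        else:
            assert got.threshold == pytest.approx(want[0])
            assert got.ef == pytest.approx(want[1])


class TestPreprocess:
    def make_table(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        informative = y * 2.0 + rng.normal(0, 0.5, n)
        X = pd.DataFrame({
            "const": np.ones(n),
            "inf": informative,
            "inf_copy": informative * 3 + 1,     # |r| = 1 with inf
            "noise": rng.normal(0, 1, n),        # no class separation
        })
        return LabeledTable(X, y)

    def test_stages_partition_columns(self):
        table, rep = preprocess(self.make_table())
        assert rep.dropped_zero_variance == ["const"]
        assert rep.dropped_correlated == {"inf_copy": "inf"}
        assert "noise" in rep.dropped_ttest
        assert rep.kept == ["inf"]
        assert set(rep.kept) | set(rep.dropped_zero_variance) \
            | set(rep.dropped_correlated) | set(rep.dropped_ttest) == \
            set(self.make_table().X.columns)

    def test_correlated_group_keeps_most_separating(self):
        rng = np.random.default_rng(2)
        y = np.array([0] * 30 + [1] * 30)
        strong = y * 3.0 + rng.normal(0, 0.3, 60)
        weak = strong + rng.normal(0, 0.5, 60)  # r > 0.9 with strong, noisier
        table = LabeledTable(pd.DataFrame({"weak": weak, "strong": strong}), y)
        _, rep = preprocess(table)
        assert rep.kept == ["strong"]

    def test_non_numeric_column_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "s": ["x", "y"]})
        with pytest.raises(DataError, match="'s'"):
            preprocess(LabeledTable(X, np.array([0, 1])))


class TestGrowTree:
    def test_four_observations_single_leaf(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        tree = grow_tree(LabeledTable(X, np.array([0, 0, 1, 1])), min_leaf=5)
        assert tree.root.is_leaf

    def test_perfectly_separable_depth_one(self):
        x = np.arange(20, dtype=float)
        y = (x >= 10).astype(int)
        tree = grow_tree(LabeledTable(pd.DataFrame({"x": x}), y), min_leaf=5)
        assert tree.depth() == 1
        assert tree.root.descriptor == "x"
        assert tree.root.threshold == pytest.approx(9.5)
        assert tree.root.pass_child.label == 1
        assert tree.root.fail_child.label == 0

    def test_planted_or_rule_recovered_without_noise(self):
        table = make_labeled_table(PlantedRuleSpec(noise=0.0, seed=7))
        tree = grow_tree(table)
        assert tree.root.descriptor == "X"
        assert abs(tree.root.threshold - 10.0) < 0.3
        fail = tree.root.fail_child
        assert not fail.is_leaf and fail.descriptor == "Y"
        assert abs(fail.threshold - 4.0) < 0.15
        pred = tree.predict(table.X)
        assert (pred == table.y).all()

    def test_no_leaf_below_min_leaf(self):
        table = make_labeled_table(PlantedRuleSpec(n=300, noise=0.05, seed=3))
        tree = grow_tree(table, min_leaf=5)

        def check(node):
            if node.is_leaf:
                assert node.n_obs >= 5 or node is tree.root
            else:
                check(node.pass_child)
                check(node.fail_child)

        check(tree.root)

    def test_sklearn_style_wrapper(self):
        table = make_labeled_table(PlantedRuleSpec(noise=0.0, seed=1))
        clf = EnrichmentTree(min_leaf=5, max_depth=3).fit(table.X, table.y)
        assert (clf.predict(table.X) == table.y).all()


class TestKfoldConsensus:
    def test_consensus_equals_single_fit_on_clean_planted_rule(self):
        table = make_labeled_table(PlantedRuleSpec(noise=0.0, seed=2))
        single = grow_tree(table)
        res = kfold_consensus(table, k=20, seed=4)
        assert res.tree.root.descriptor == single.root.descriptor
        assert abs(res.tree.root.threshold - single.root.threshold) < 0.3
        assert (res.tree.predict(table.X) == table.y).all()

    def test_consensus_root_descriptor_stable_across_folds(self):
        table = make_labeled_table(PlantedRuleSpec(noise=0.0, seed=6))
        res = kfold_consensus(table, k=20, seed=1)
        roots = res.per_fold[res.per_fold.path == ""]["descriptor"]
        assert len(roots) == 20
        assert (roots == "X").sum() >= 18

    def test_per_fold_report_exposes_minority_choices(self):
        table = make_labeled_table(PlantedRuleSpec(noise=0.05, seed=9))
        res = kfold_consensus(table, k=10, seed=0)
        assert set(res.per_fold.columns) == {"fold", "path", "descriptor", "threshold"}
        assert res.per_fold.fold.nunique() == 10

    def test_k_larger_than_n_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.array([0] * 5 + [1] * 5)
        with pytest.raises(DataError):
            kfold_consensus(LabeledTable(X, y), k=11)

    def test_row_permutation_invariance_of_structure(self):
        table = make_labeled_table(PlantedRuleSpec(n=400, noise=0.0, seed=5))
        tree_a = grow_tree(table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        table_b = table.subset(perm)
        tree_b = grow_tree(table_b)
        assert tree_a.root.descriptor == tree_b.root.descriptor
        assert tree_a.root.threshold == pytest.approx(tree_b.root.threshold)
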