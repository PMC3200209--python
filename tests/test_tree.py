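"""TSPC rule, tree growing, cost-complexity pruning and CV selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pcilos import registry, tree
from pcilos.tree import PrognosticTree, TreeNode
from tests.conftest import make_cohort, make_record


class TestTspcClassify:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            (dict(heart_failure="current", age=45), "very_high"),
            (dict(heart_failure="past", age=45), "very_high"),
            (dict(age=72, sex="male"), "low"),
            (dict(age=72, sex="female"), "moderate"),
            (dict(age=50, dialysis=1), "high"),
            (dict(age=50, creatinine_gt_2_5=1), "high"),
            (dict(age=50), "very_low"),
            (dict(age=70, sex="male"), "low"),  # tie at 70 goes to older branch
            (dict(age=72, sex="male", dialysis=1), "low"),  # renal not asked when >=70
        ],
    )
    def test_rule(self, overrides, expected):
        cohort = make_cohort([make_record(**overrides)])
        assert tree.tspc_classify(cohort)[0] == expected

    def test_total_partition_over_covariate_grid(self):
        records = [
            make_record(heart_failure=hf, age=age, sex=sex, dialysis=int(renal))
            for hf, age, sex, renal in itertools.product(
                ["none", "past", "current"], [45.0, 70.0, 85.0], ["male", "female"], [0, 1]
            )
        ]
        cats = tree.tspc_classify(make_cohort(records))
        assert not pd.isna(np.asarray(cats)).any()
        assert set(np.asarray(cats)) == {"very_low", "low", "moderate", "high", "very_high"}

    def test_current_only_mode(self):
        cohort = make_cohort([make_record(heart_failure="past", age=45)])
        assert tree.tspc_classify(cohort, hf_mode="current")[0] == "very_low"


class TestGrowTree:
    def test_constant_outcome_gives_single_leaf(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100)})
        t = tree.grow_tree(X, np.zeros(100), min_leaf=5)
        assert t.root.is_leaf

    def test_perfect_binary_separator(self):
        X = pd.DataFrame({"a": [0.0] * 50 + [1.0] * 50})
        y = np.array([0] * 50 + [1] * 50)
        t = tree.grow_tree(X, y, min_leaf=5)
        assert t.n_leaves == 2
        assert t.root.feature == "a" and t.root.threshold == 0.5
        assert t.root.left.rate == 0.0 and t.root.right.rate == 1.0

    def test_never_splits_pure_node(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=2000), "b": rng.integers(0, 2, 2000)})
        y = (X["b"].to_numpy() == 1).astype(int)  # 'a' is pure noise
        t = tree.grow_tree(X, y, min_leaf=10)

        def walk(node):
            if node.is_leaf:
                return
            assert 0 < node.n_events < node.n  # split nodes are impure
            walk(node.left)
            walk(node.right)

        walk(t.root)

    def test_planted_two_covariate_tree_recovered(self, rng):
        n = 20_000
        x0 = rng.integers(0, 2, n).astype(float)
        x1 = rng.uniform(0, 1, n)
        rate = np.where(x0 == 0, 0.05, np.where(x1 < 0.4, 0.2, 0.5))
        y = (rng.random(n) < rate).astype(int)
        t = tree.grow_tree(pd.DataFrame({"x0": x0, "x1": x1}), y, min_leaf=100, max_depth=2)
        assert t.root.feature == "x0"
        assert t.root.right.feature == "x1"
        assert abs(t.root.right.threshold - 0.4) < 0.02

    def test_root_split_matches_exhaustive_oracle(self, rng):
        n = 1500
        X = pd.DataFrame({"a": rng.normal(size=n).round(1), "b": rng.integers(0, 4, n).astype(float)})
        y = (rng.random(n) < 0.1 + 0.15 * (X["b"] > 1)).astype(int)
        t = tree.grow_tree(X, y, min_leaf=20, max_depth=1)

        def gini_cost(e, n_):
            return 2.0 * e * (n_ - e) / n_ if n_ else 0.0

        best = None
        for col in X.columns:  # exhaustive split search, independent code path
            vals = np.sort(X[col].unique())
            for lo, hi in zip(vals, vals[1:]):
                thr = (lo + hi) / 2
                right = X[col].to_numpy() >= thr
                if right.sum() < 20 or (~right).sum() < 20:
                    continue
                delta = gini_cost(y.sum(), n) - gini_cost(y[right].sum(), right.sum()) - gini_cost(
                    y[~right].sum(), (~right).sum()
                )
                if best is None or delta > best[0] + 1e-12:
                    best = (delta, col, thr)
        assert t.root.feature == best[1]
        assert t.root.threshold == pytest.approx(best[2])

    def test_sklearn_agrees_on_root_split(self, rng):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        n = 5000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = (rng.random(n) < 0.2 + 0.3 * (X["a"] > 0.5)).astype(int)
        ours = tree.grow_tree(X, y, min_leaf=50, max_depth=1)
        ref = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", max_depth=1, min_samples_leaf=50, random_state=0
        ).fit(X, y)
        assert X.columns[ref.tree_.feature[0]] == ours.root.feature
        assert ref.tree_.threshold[0] == pytest.approx(ours.root.threshold, abs=1e-9)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            tree.grow_tree(pd.DataFrame({"a": []}), np.array([]))


class TestPruneCcp:
    def _manual_tree(self, c_events=1):
        # root (16, 5+c) -- x0 --> left (8, 5) -- x1 --> A(4, 1), B(4, 4)
        #                          right: leaf C(8, c_events)
        a = TreeNode(n=4, n_events=1)
        b = TreeNode(n=4, n_events=4)
        left = TreeNode(n=8, n_events=5, feature="x0", threshold=0.5, left=a, right=b)
        c = TreeNode(n=8, n_events=c_events)
        root = TreeNode(
            n=16, n_events=5 + c_events, feature="x1", threshold=0.5, left=left, right=c
        )
        return PrognosticTree(root=root, feature_names=("x1", "x0"))

    def test_single_leaf_sequence_has_length_one(self):
        t = PrognosticTree(root=TreeNode(n=10, n_events=3), feature_names=())
        seq = tree.prune_ccp(t)
        assert len(seq.trees) == 1 and seq.alphas == [0.0]

    def test_last_subtree_is_root_only(self, small_cohort):
        X = tree.tspc_design_matrix(small_cohort.head(5000))
        y = small_cohort.head(5000)["complication"].to_numpy()
        seq = tree.prune_ccp(tree.grow_tree(X, y, min_leaf=100))
        assert seq.trees[-1].root.is_leaf
        assert seq.trees[0].n_leaves >= seq.trees[-1].n_leaves

    def test_misclassification_alphas_match_manual_arithmetic(self):
        # weakest-link by hand (R = misclassified/16):
        #   inner node: R(t) = min(5,3)/16 = 3/16, R(T_t) = 1/16 + 0 -> g = 2/16
        #   root:       R(t) = min(6,10)/16 = 6/16, R(T_t) = 2/16, |T|=3
        #               -> g = (6/16 - 2/16) / 2 = 2/16  (tie: both collapse)
        seq = tree.prune_ccp(self._manual_tree(), risk_measure="misclassification")
        assert seq.alphas == pytest.approx([0.0, 2.0 / 16.0])
        assert [t.n_leaves for t in seq.trees] == [3, 1]

    def test_gini_sequence_prunes_inner_node_first(self):
        # with a pure right leaf (C has 0 events) the root split is strong:
        #   g(inner) = (2*5*3/8 - 2*1*3/4)/16 = 0.140625
        #   g(root)  = (2*5*11/16 - 1.5)/16/2 = 0.16796875 > g(inner)
        # so the inner node collapses first; then g(root) = 0.1953125
        seq = tree.prune_ccp(self._manual_tree(c_events=0), risk_measure="gini")
        assert [t.n_leaves for t in seq.trees] == [3, 2, 1]
        assert seq.alphas == pytest.approx([0.0, 0.140625, 0.1953125])

    def test_alphas_strictly_increasing_and_subtrees_nested(self, small_cohort):
        X = tree.tspc_design_matrix(small_cohort)
        y = small_cohort["complication"].to_numpy()
        seq = tree.prune_ccp(tree.grow_tree(X, y, min_leaf=200, max_depth=6))
        assert all(b > a for a, b in zip(seq.alphas, seq.alphas[1:]))
        # nestedness: every later partition is a coarsening of the earlier
        parts = [t.leaf_index(X) for t in seq.trees]
        for fine, coarse in zip(parts, parts[1:]):
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c


class TestCvSelect:
    def test_pure_noise_selects_root_in_majority_of_seeds(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame({"a": r.normal(size=3000), "b": r.integers(0, 2, 3000).astype(float)})
            y = (r.random(3000) < 0.05).astype(int)
            sel, _ = tree.cv_select(X, y, folds=5, seed=seed, min_leaf=50, max_depth=4)
            hits += sel.root.is_leaf
        assert hits >= 7

    def test_planted_tspc_partition_recovered(self):
        cfg = registry.GeneratorConfig(n=120_000, seed=314)
        cohort = registry.generate_cohort(cfg)
        X = tree.tspc_design_matrix(cohort)
        sel, _ = tree.cv_select(
            X, cohort["complication"].to_numpy(), folds=10, seed=1, min_leaf=1200, max_depth=6
        )
        published = np.asarray(tree.tspc_classify(cohort), dtype=object)
        assert tree.same_partition(sel.classify(X), published)

    def test_leave_one_out_matches_manual_fold_loop(self):
        r = np.random.default_rng(3)
        n = 20
        X = pd.DataFrame({"a": r.normal(size=n).round(1)})
        y = np.array([0, 1] * 10)
        sel, seq = tree.cv_select(X, y, folds=n, seed=0, min_leaf=2)
        K = len(seq.alphas)
        rep = np.empty(K)
        for k in range(K - 1):
            a, b = seq.alphas[k], seq.alphas[k + 1]
            rep[k] = np.sqrt(a * b) if a > 0 else b / 2
        rep[K - 1] = seq.alphas[-1]
        # brute-force LOO: an explicit loop over held-out records
        losses = np.zeros((K, n))
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            sub = tree.prune_ccp(tree.grow_tree(X.loc[keep], y[keep], min_leaf=2))
            for k in range(K):
                p = float(
                    np.clip(sub.subtree_for(rep[k]).predict_rate(X.iloc[[i]]), 1e-6, 1 - 1e-6)[0]
                )
                losses[k, i] = -(y[i] * np.log(p) + (1 - y[i]) * np.log1p(-p))
        assert np.allclose(losses.mean(axis=1), seq.cv_risk)

    def test_invariant_to_record_order(self, small_cohort):
        sub = small_cohort.head(8000)
        X = tree.tspc_design_matrix(sub).reset_index(drop=True)
        y = sub["complication"].to_numpy()
        sel_a, _ = tree.cv_select(X, y, folds=5, seed=9, min_leaf=100, max_depth=4)
        perm = np.random.default_rng(0).permutation(len(y))
        sel_b, _ = tree.cv_select(X.iloc[perm].reset_index(drop=True), y[perm],
                                  folds=5, seed=9, min_leaf=100, max_depth=4)
        la = sel_a.classify(X)
        lb = sel_b.classify(X)  # classify the *original* order with both trees
        assert tree.same_partition(la, lb)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            tree.cv_select(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]), folds=5)


class TestReportingAndSerialization:
    def test_tree_report_counts_and_means(self, small_cohort):
        labels = np.asarray(tree.tspc_classify(small_cohort), dtype=object)
        rep = tree.tree_report(labels, small_cohort["los_days"].to_numpy())
        assert rep["n"].sum() == len(small_cohort)
        assert list(rep["class"]) == ["very_low", "low", "moderate", "high", "very_high"]
        # mean LOS increases with risk class under the default calibration
        assert rep["mean_los"].is_monotonic_increasing

    def test_single_class_report(self):
        rep = tree.tree_report(np.array(["very_low"] * 5, dtype=object), np.array([3, 2, 4, 3, 3]))
        assert len(rep) == 1 and rep.loc[0, "n"] == 5

    def test_json_roundtrip_preserves_classification(self, small_cohort):
        sub = small_cohort.head(5000)
        X = tree.tspc_design_matrix(sub)
        t = tree.grow_tree(X, sub["complication"].to_numpy(), min_leaf=100, max_depth=3)
        t.assign_risk_labels()
        back = PrognosticTree.from_json(t.to_json())
        assert np.array_equal(t.classify(X), back.classify(X))

    def test_render_mentions_questions(self):
        X = pd.DataFrame({"age": [60.0] * 50 + [80.0] * 50})
        y = np.array([0] * 50 + [1] * 50)
        t = tree.grow_tree(X, y, min_leaf=5)
        assert "age >= 70" in t.render()
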