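"""Conditional inference tree/forest engine: split statistics, split-point
search, missing-value routing, growth and prediction."""

from itertools import combinations

import numpy as np
import pytest

from extrisk import (
    ConditionalInferenceForest,
    ForestConfig,
    TreeNode,
    best_split_point,
    route_case,
    select_split_variable,
    split_pvalue,
)


class TestSplitPvalue:
    def test_constant_feature_sentinel(self):
        x = np.full(10, 3.0)
        y = np.array([0, 1] * 5, dtype=float)
        assert split_pvalue(x, y).p_value == 1.0

    def test_perfect_separation_matches_exact_enumeration(self):
        # n=8, 4/4 split, x perfectly ordered with y
        x = np.arange(8, dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        p = split_pvalue(x, y).p_value
        # independent oracle: enumerate all C(8,4) label placements
        eh = y.mean()
        obs = abs(x @ y - eh * x.sum())
        stats = [abs(x[list(c)].sum() - eh * x.sum()) for c in combinations(range(8), 4)]
        p_exact = np.mean([s >= obs - 1e-9 for s in stats])
        assert p == pytest.approx(p_exact, abs=1e-12)
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_label_swap_invariance(self, rng):
        x = rng.standard_normal(40)
        y = (rng.random(40) < 0.4).astype(float)
        assert split_pvalue(x, y).p_value == pytest.approx(split_pvalue(x, 1 - y).p_value)

    def test_categorical_relabel_invariance(self, rng):
        x = rng.integers(0, 4, size=60).astype(float)
        y = (rng.random(60) < 0.5).astype(float)
        p1 = split_pvalue(x, y, kind="c").p_value
        relabeled = np.array([3.0, 0.0, 2.0, 1.0])[x.astype(int)]
        assert split_pvalue(relabeled, y, kind="c").p_value == pytest.approx(p1)

    def test_missing_excluded_from_statistic(self, rng):
        x = rng.standard_normal(30)
        y = (rng.random(30) < 0.5).astype(float)
        x_aug = np.concatenate([x, [np.nan] * 10])
        y_aug = np.concatenate([y, (rng.random(10) < 0.5).astype(float)])
        t = split_pvalue(x_aug, y_aug)
        assert t.n_used == 30


class TestSelectSplitVariable:
    def test_strong_predictor_wins(self, rng):
        hits = 0
        kinds = ["n"] * 10
        for _ in range(100):
            y = (rng.random(200) < 0.5).astype(float)
            X = rng.standard_normal((200, 10))
            X[:, 4] += 1.5 * y  # one strong predictor among 9 noise features
            sel = select_split_variable(X, y, np.arange(10), kinds, alpha=0.05)
            hits += sel is not None and sel[0] == 4
        assert hits >= 95

    def test_alpha_zero_always_stops(self, rng):
        y = (rng.random(50) < 0.5).astype(float)
        X = rng.standard_normal((50, 3))
        X[:, 0] += 5 * y
        assert select_split_variable(X, y, [0, 1, 2], ["n"] * 3, alpha=0.0) is None

    def test_no_candidates_stops(self, rng):
        y = (rng.random(20) < 0.5).astype(float)
        X = rng.standard_normal((20, 2))
        assert select_split_variable(X, y, [], ["n", "n"]) is None

    def test_bonferroni_adjustment_recorded(self, rng):
        y = (rng.random(100) < 0.5).astype(float)
        X = rng.standard_normal((100, 4))
        X[:, 2] += 2 * y
        sel = select_split_variable(X, y, np.arange(4), ["n"] * 4, alpha=0.05)
        assert sel is not None
        j, test = sel
        assert test.adj_p_value == pytest.approx(min(1.0, test.p_value * 4))


class TestBestSplitPoint:
    def test_numeric_midpoint(self):
        x = np.array([1.0, 2.0, 9.0, 10.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert best_split_point(x, y, min_leaf=1) == 5.5

    def test_min_leaf_blocks_split(self):
        x = np.array([1.0, 2.0, 9.0, 10.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert best_split_point(x, y, min_leaf=3) is None

    def test_categorical_isolates_pure_level(self):
        # levels 0,1 all class 0; level 2 all class 1
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1], dtype=float)
        left = best_split_point(x, y, kind="c", min_leaf=1)
        sides = ({int(c) for c in left}, {0, 1, 2} - {int(c) for c in left})
        assert {2} in sides

    def test_exhaustive_matches_scan_oracle(self, rng):
        # brute-force oracle over all cutpoints on random instances
        for _ in range(20):
            x = rng.integers(0, 6, size=30).astype(float)
            y = (rng.random(30) < 0.4).astype(float)
            if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
                continue
            cut = best_split_point(x, y, min_leaf=1)
            if cut is None:
                continue
            eh, n = y.mean(), len(y)

            def stat(c):
                left = x <= c
                wl = left.sum()
                if wl == 0 or wl == n:
                    return -np.inf
                s2 = eh * (1 - eh) * wl * (n - wl) / (n - 1)
                return (y[left].sum() - eh * wl) ** 2 / s2

            cands = (np.unique(x)[:-1] + np.unique(x)[1:]) / 2
            assert stat(cut) == pytest.approx(max(stat(c) for c in cands))


class TestRouting:
    def _node(self, p_left=0.7):
        return TreeNode(feature=0, kind="n", cut=5.0, p_left=p_left, p_adj=0.01,
                        left=TreeNode(counts=(1, 0), proportion=0.0, n_node=1),
                        right=TreeNode(counts=(0, 1), proportion=1.0, n_node=1))

    def test_below_cut_goes_left(self):
        assert route_case(self._node(), 4.0) == {"left": 1.0, "right": 0.0}
        assert route_case(self._node(), 5.0) == {"left": 1.0, "right": 0.0}  # <= rule
        assert route_case(self._node(), 5.1) == {"left": 0.0, "right": 1.0}

    def test_missing_training_proportional(self):
        w = route_case(self._node(0.7), float("nan"), training=True)
        assert w == {"left": pytest.approx(0.7), "right": pytest.approx(0.3)}

    def test_missing_prediction_heavier_child_ties_left(self):
        assert route_case(self._node(0.5), float("nan")) == {"left": 1.0, "right": 0.0}
        assert route_case(self._node(0.3), float("nan")) == {"left": 0.0, "right": 1.0}


class TestForest:
    def _xy(self, rng, n=300):
        X = rng.standard_normal((n, 5))
        logit = 1.8 * X[:, 0] - 1.2 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return X, y

    def test_all_labels_identical_gives_pure_leaves(self, rng):
        X = rng.standard_normal((50, 3))
        y = np.ones(50)
        f = ConditionalInferenceForest.fit(X, y, ["a", "b", "c"], ["n"] * 3,
                                           config=ForestConfig(n_trees=5), seed=0)
        assert np.all(f.predict_proba(X) == 1.0)
        assert all(t.root.is_leaf for t in f.trees)

    def test_seeded_determinism(self, rng):
        X, y = self._xy(rng)
        cfg = ForestConfig(n_trees=10)
        f1 = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5, cfg, seed=3)
        f2 = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5, cfg, seed=3)
        assert f1.structure_hash() == f2.structure_hash()

    def test_prediction_invariant_to_tree_order(self, rng):
        X, y = self._xy(rng)
        f = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=20), seed=1)
        p1 = f.predict_proba(X)
        f.trees = f.trees[::-1]
        assert np.allclose(f.predict_proba(X), p1)

    def test_probability_bounds_with_all_missing_row(self, rng):
        X, y = self._xy(rng)
        f = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=20), seed=1)
        p = f.predict_proba(np.full((1, 5), np.nan))
        assert 0.0 <= p[0] <= 1.0

    def test_duplicate_row_same_probability(self, rng):
        X, y = self._xy(rng)
        f = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=10), seed=1)
        row = X[[7]]
        assert f.predict_proba(np.vstack([row, row]))[0] == f.predict_proba(row)[0]

    def test_unknown_feature_columns_rejected(self, rng):
        X, y = self._xy(rng)
        f = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=3), seed=1)
        with pytest.raises(ValueError):
            f.predict_proba(X[:, :4])
        with pytest.raises(ValueError):
            f.predict_proba(X, feature_names=list("abcdX"))

    def test_monotone_under_label_enrichment(self, rng):
        # depth-1 stumps: adding at-risk duplicates of a row never lowers
        # that row's predicted probability
        X, y = self._xy(rng, n=200)
        cfg = ForestConfig(n_trees=30, max_depth=1)
        f0 = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5, cfg, seed=2)
        row = X[[0]]
        p0 = f0.predict_proba(row)[0]
        X_aug = np.vstack([X, np.repeat(row, 40, axis=0)])
        y_aug = np.concatenate([y, np.ones(40)])
        f1 = ConditionalInferenceForest.fit(X_aug, y_aug, list("abcde"), ["n"] * 5, cfg, seed=2)
        assert f1.predict_proba(row)[0] >= p0 - 1e-9

    def test_out_of_sample_recovery_beats_chance(self, rng):
        # synthetic recovery: holdout AUC clearly above the null
        from extrisk import auc

        X, y = self._xy(rng, n=500)
        train, test = np.arange(350), np.arange(350, 500)
        f = ConditionalInferenceForest.fit(X[train], y[train], list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=100), seed=4)
        a = auc(f.predict_proba(X[test]), y[test])
        n_pos = int(y[test].sum())
        n_neg = len(test) - n_pos
        se0 = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert a > 0.5 + 3 * se0

    def test_json_roundtrip(self, rng):
        X, y = self._xy(rng, n=120)
        f = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=5), seed=9)
        back = ConditionalInferenceForest.from_dict(f.to_dict())
        assert np.allclose(back.predict_proba(X), f.predict_proba(X))
        assert back.structure_hash() == f.structure_hash()

    def test_missing_values_handled_end_to_end(self, rng):
        X, y = self._xy(rng, n=400)
        mask = rng.random(X.shape) < 0.2
        X = np.where(mask, np.nan, X)
        f = ConditionalInferenceForest.fit(X, y, list("abcde"), ["n"] * 5,
                                           ForestConfig(n_trees=30), seed=5)
        p = f.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        assert not np.isnan(p).any()
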