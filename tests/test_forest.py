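"""Gini impurity, mean-decrease-impurity importances, CV training."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from toxsig.chem import AssayDataset
from toxsig.forest import (
    ForestConfig,
    ImportanceVector,
    gini_importance,
    gini_index,
    select_top_features,
    train_with_cv,
)
from toxsig.resampling import ResampleConfig


class TestGiniIndex:
    @pytest.mark.parametrize(
        "probs,expected",
        [((1.0, 0.0), 0.0), ((0.5, 0.5), 0.5), ((0.2, 0.8), 0.32),
         ((0.25, 0.25, 0.25, 0.25), 0.75)],
    )
    def test_formula(self, probs, expected):
        assert gini_index(probs) == pytest.approx(expected)

    def test_invalid_distribution_raises(self):
        with pytest.raises(ValueError):
            gini_index((0.5, 0.4))
        with pytest.raises(ValueError):
            gini_index((-0.1, 1.1))

    def test_maximized_at_uniform_zero_iff_pure(self, rng):
        for n in (2, 3, 5):
            uniform = gini_index([1 / n] * n)
            for _ in range(20):
                p = rng.dirichlet(np.ones(n))
                assert gini_index(p) <= uniform + 1e-12
                assert (gini_index(p) < 1e-12) == (p.max() > 1 - 1e-9)


def _make_learnable(rng, n=300, n_features=8, n_causal=3):
    X = rng.uniform(size=(n, n_features))
    y = (X[:, :n_causal].sum(axis=1) > n_causal / 2).astype(int)
    return X, y


class TestGiniImportance:
    def test_single_stump_concentrates_on_its_split_feature(self, rng):
        X = rng.uniform(size=(100, 6))
        y = (X[:, 3] > 0.5).astype(int)  # only feature 3 is informative
        forest = RandomForestClassifier(
            n_estimators=5, max_depth=1, max_features=None, random_state=0
        ).fit(X, y)
        imp = gini_importance(forest, [f"f{i}" for i in range(6)])
        assert imp.values[3] == pytest.approx(1.0)
        assert np.allclose(np.delete(imp.values, 3), 0.0)

    def test_depth_two_tree_matches_hand_computed_table(self):
        # 10 samples; root splits feature 0 (6|4), the impure right child
        # splits feature 1 into pure leaves.  Hand computation:
        #   root gini = 1 - (0.8^2 + 0.2^2) = 0.32
        #   f0 decrease = (10*0.32 - 6*0 - 4*0.5)/10 = 0.12
        #   f1 decrease = (4*0.5 - 0 - 0)/10       = 0.20
        #   normalized -> f0 = 0.375, f1 = 0.625
        X = np.array(
            [[0, 0], [0, 1], [0, 0], [0, 1], [0, 0], [0, 1],
             [1, 0], [1, 0], [1, 1], [1, 1]],
            dtype=float,
        )
        y = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1])
        forest = RandomForestClassifier(
            n_estimators=1, max_depth=2, max_features=None, bootstrap=False,
            random_state=0,
        ).fit(X, y)
        imp = gini_importance(forest, ["f0", "f1"])
        assert imp.values == pytest.approx([0.375, 0.625])

    def test_matches_sklearn_convention_with_per_tree_normalization(self, rng):
        X, y = _make_learnable(rng)
        forest = RandomForestClassifier(n_estimators=40, random_state=0).fit(X, y)
        imp = gini_importance(forest, [f"f{i}" for i in range(X.shape[1])],
                              per_tree_normalize=True)
        assert np.allclose(imp.values, forest.feature_importances_, atol=1e-9)

    def test_noise_feature_ranks_below_causal(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            X, y = _make_learnable(r, n=250, n_features=6, n_causal=3)
            X = np.hstack([X, r.uniform(size=(len(X), 1))])  # label-independent noise
            forest = RandomForestClassifier(n_estimators=60, random_state=seed).fit(X, y)
            imp = gini_importance(forest, [f"f{i}" for i in range(7)])
            assert imp.values[6] < imp.values[:3].min()

    def test_unfitted_forest_raises(self):
        with pytest.raises(ValueError):
            gini_importance(RandomForestClassifier(), ["f0"])

    def test_permuting_columns_permutes_importances(self, rng):
        # unique split gains (and unsplittable constant padding) make the
        # greedy tree invariant to column order up to relabeling
        X = np.array(
            [[0, 0], [0, 1], [0, 0], [0, 1], [0, 0], [0, 1],
             [1, 0], [1, 0], [1, 1], [1, 1]],
            dtype=float,
        )
        X = np.hstack([X, np.zeros((10, 2))])  # constant, never split
        y = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1])
        ids = ["f0", "f1", "f2", "f3"]
        tree_kwargs = dict(
            n_estimators=1, max_depth=2, max_features=None, bootstrap=False,
            random_state=0,
        )
        imp = gini_importance(RandomForestClassifier(**tree_kwargs).fit(X, y), ids)
        perm = rng.permutation(4)
        imp_p = gini_importance(
            RandomForestClassifier(**tree_kwargs).fit(X[:, perm], y),
            [ids[j] for j in perm],
        )
        by_name = dict(zip(imp_p.feature_ids, imp_p.values))
        assert np.allclose([by_name[i] for i in ids], imp.values, atol=1e-9)
        assert imp.values.sum() == pytest.approx(1.0, abs=1e-9)


def _dataset(rng, n=200, n_features=10, pos_frac=0.25):
    X = rng.uniform(size=(n, n_features))
    score = X[:, 0] + X[:, 1] - 1 + rng.normal(0, 0.2, n)
    y = (score > np.quantile(score, 1 - pos_frac)).astype(int)
    n_test = n // 4
    return AssayDataset(
        assay_id="a1",
        X_train=X[n_test:], y_train=y[n_test:],
        X_test=X[:n_test], y_test=y[:n_test],
        feature_ids=[f"f{i}" for i in range(n_features)],
    )


FAST_CV = dict(cv_folds=3, cv_repeats=1)


class TestTrainWithCv:
    def test_single_candidate_grid(self, rng):
        ds = _dataset(rng)
        fconf = ForestConfig(grid={"max_depth": [4], "n_estimators": [20]}, seed=0, **FAST_CV)
        model, best, table = train_with_cv(ds, ResampleConfig(seed=0), fconf)
        assert best == {"max_depth": 4, "n_estimators": 20}
        assert len(table) == 3  # folds x repeats
        assert hasattr(model, "estimators_")

    def test_degenerate_candidate_loses_on_learnable_problem(self):
        wins = 0
        for seed in range(5):
            ds = _dataset(np.random.default_rng(seed), n=240)
            fconf = ForestConfig(
                grid={"max_depth": [1, None], "n_estimators": [1, 40]},
                seed=seed, **FAST_CV,
            )
            _, best, _ = train_with_cv(ds, ResampleConfig(seed=seed), fconf)
            if best != {"max_depth": 1, "n_estimators": 1}:
                wins += 1
        assert wins == 5

    def test_deterministic_under_seed(self, rng):
        ds = _dataset(rng)
        fconf = ForestConfig(grid={"max_depth": [3, 6], "n_estimators": [15]},
                             seed=11, **FAST_CV)
        out1 = train_with_cv(ds, ResampleConfig(seed=11), fconf)
        out2 = train_with_cv(ds, ResampleConfig(seed=11), fconf)
        assert out1[1] == out2[1]
        imp1 = gini_importance(out1[0], ds.feature_ids)
        imp2 = gini_importance(out2[0], ds.feature_ids)
        assert np.array_equal(imp1.values, imp2.values)

    def test_too_few_minority_for_folds_raises(self, rng):
        ds = _dataset(rng, n=40, pos_frac=0.05)
        with pytest.raises(ValueError, match="fewer cv_folds"):
            train_with_cv(ds, ResampleConfig(), ForestConfig(cv_folds=10))

    def test_permuted_labels_score_at_chance(self):
        """In-fold resampling must not leak: null CV BA stays near 0.5."""
        scores = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.uniform(size=(200, 15))
            y = np.zeros(200, dtype=int)
            y[r.choice(200, 40, replace=False)] = 1  # labels independent of X
            ds = AssayDataset("a", X, y, X[:1], y[:1], [f"f{i}" for i in range(15)])
            fconf = ForestConfig(grid={"max_depth": [None], "n_estimators": [25]},
                                 cv_folds=5, cv_repeats=1, seed=seed)
            _, _, table = train_with_cv(ds, ResampleConfig(seed=seed), fconf)
            scores.append(table.score.mean())
        assert 0.45 <= float(np.mean(scores)) <= 0.55


class TestSelectTop:
    def test_ranks_by_importance(self):
        imp = ImportanceVector(["a", "b", "c"], [0.5, 0.3, 0.2])
        assert select_top_features(imp, k=2) == ["a", "b"]

    def test_ties_break_lexicographically(self):
        imp = ImportanceVector(["z", "m", "a", "q"], [0.25] * 4)
        assert select_top_features(imp, k=3) == ["a", "m", "q"]

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            select_top_features(ImportanceVector(["a"], [1.0]), k=2)
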