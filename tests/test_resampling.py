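"""SMOTE interpolation, ENN editing, and the combined resampler."""

import numpy as np
import pytest

from toxsig.chem import build_assay_datasets, imbalance_ratio
from toxsig.resampling import ResampleConfig, enn_edit, smote_enn, smote_oversample


def brute_force_knn(X, i, k):
    """Independent kNN oracle: exact distances, (distance, index) sort."""
    d = [(float(np.sum((X[j] - X[i]) ** 2)), j) for j in range(len(X)) if j != i]
    d.sort()
    return [j for _, j in d[:k]]


class TestSmote:
    def test_two_point_minority_interpolates_on_the_segment(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        synth = smote_oversample(X, 10, k=1, rng=rng)
        assert synth.shape == (10, 2)
        # every point is x + u*(other - x): coordinates equal, within [0, 1]
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert synth.min() >= 0 and synth.max() <= 1

    def test_zero_requested_returns_empty(self, rng):
        assert smote_oversample(np.ones((3, 2)), 0, k=1, rng=rng).shape[0] == 0

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            smote_oversample(np.ones((1, 2)), 5, k=1, rng=rng)
        with pytest.raises(ValueError):
            smote_oversample(np.ones((4, 2)), 5, k=4, rng=rng)

    def test_every_synthetic_point_lies_on_a_neighbour_segment(self, rng):
        X = rng.uniform(size=(30, 5))
        synth = smote_oversample(X, 200, k=5, rng=rng)
        for s in synth:
            ok = False
            for i in range(len(X)):
                for j in brute_force_knn(X, i, 5):
                    d = X[j] - X[i]
                    denom = float(d @ d)
                    u = float((s - X[i]) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.linalg.norm(X[i] + u * d - s) < 1e-9:
                        ok = True
                        break
                if ok:
                    break
            assert ok, f"synthetic point {s} not on any minority neighbour segment"

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(0).uniform(size=(20, 3))
        a = smote_oversample(X, 50, k=3, rng=np.random.default_rng(42))
        b = smote_oversample(X, 50, k=3, rng=np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestEnn:
    def test_majority_point_surrounded_by_minority_is_removed(self):
        X = np.array([[0.0], [0.1], [0.2], [0.15], [5.0], [5.1], [5.2]])
        y = np.array([1, 1, 1, 0, 0, 0, 0])  # index 3 is a majority point in minority turf
        kept = enn_edit(X, y, k=3)
        assert 3 not in kept
        assert set(kept) >= {0, 1, 2, 4, 5, 6}

    def test_separated_clusters_keep_everything(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(10, 0.1, (15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        assert len(enn_edit(X, y, k=3)) == 30

    def test_matches_brute_force_vote_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 45))
            X = rng.normal(size=(n, 3)) + rng.integers(0, 2, n)[:, None] * 1.5
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            kept = set(enn_edit(X, y, k=3).tolist())
            expected = set()
            for i in range(n):
                votes = [y[j] for j in brute_force_knn(X, i, 3)]
                if sum(v == y[i] for v in votes) >= len(votes) - sum(v == y[i] for v in votes):
                    expected.add(i)
            assert kept == expected

    def test_retained_set_shrinks_weakly_on_rerun(self, rng):
        X = rng.uniform(size=(60, 4))
        y = rng.integers(0, 2, 60)
        kept1 = enn_edit(X, y, k=3)
        frac1 = 1 - len(kept1) / len(y)
        kept2 = enn_edit(X[kept1], y[kept1], k=3)
        frac2 = 1 - len(kept2) / len(kept1)
        assert frac2 <= frac1 + 1e-12


class TestSmoteEnn:
    def test_balanced_separated_data_is_untouched(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 3)), rng.normal(5, 0.05, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        Xr, yr = smote_enn(X, y, ResampleConfig(seed=0))
        assert np.array_equal(Xr, X) and np.array_equal(yr, y)

    def test_minority_reaches_majority_count_when_separated(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (100, 3)), rng.normal(5, 0.05, (10, 3))])
        y = np.array([0] * 100 + [1] * 10)
        Xr, yr = smote_enn(X, y, ResampleConfig(seed=0))
        # post-SMOTE minority == majority; separation means ENN removes nothing
        assert int((yr == 1).sum()) == 100 and int((yr == 0).sum()) == 100

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            smote_enn(np.ones((5, 2)), np.ones(5), ResampleConfig())

    def test_retained_originals_are_unchanged(self, rng):
        X = rng.uniform(size=(80, 4))
        y = (rng.uniform(size=80) < 0.25).astype(int)
        Xr, yr = smote_enn(X, y, ResampleConfig(seed=3))
        original_rows = {tuple(np.round(r, 12)) for r in X}
        n_orig_retained = sum(tuple(np.round(r, 12)) in original_rows for r in Xr)
        assert n_orig_retained >= 1
        n_min, n_maj = int((y == 1).sum()), int((y == 0).sum())
        assert int((yr == 1).sum()) <= n_maj + n_min  # target*majority + originals

    def test_majority_scope_only_edits_majority(self, rng):
        X = rng.uniform(size=(60, 3))
        y = (rng.uniform(size=60) < 0.3).astype(int)
        Xr, yr = smote_enn(X, y, ResampleConfig(seed=1, enn_scope="majority"))
        # every original minority row must survive majority-scoped editing
        minority_rows = {tuple(np.round(r, 12)) for r in X[y == 1]}
        surviving = {tuple(np.round(r, 12)) for r in Xr[yr == 1]}
        assert minority_rows <= surviving

    def test_benchmark_assay_rebalances_near_parity(self, small_config, small_bundle):
        ds = build_assay_datasets(small_bundle.labels, small_bundle.matrix, small_bundle.split)[0]
        ratios = []
        for seed in range(5):
            Xr, yr = smote_enn(ds.X_train, ds.y_train, ResampleConfig(seed=seed))
            ratios.append(imbalance_ratio(yr))  # inactive/active after resampling
        assert all(0.8 <= r <= 1.25 for r in ratios), ratios
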