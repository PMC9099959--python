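"""Random-forest feature selection via Gini (mean-decrease-impurity) importance.

A forest is trained per assay on the SMOTE+ENN-resampled training set,
with hyper-parameters (tree depth, forest size) chosen by repeated
stratified cross-validation in which resampling is fit inside each
training fold only — validation folds keep the original class balance,
so fold scores are unbiased estimates of performance on imbalanced data.

Gini importance is computed by direct traversal of the fitted trees:
each internal node contributes its sample-weighted impurity decrease

    p(node) * [ Gini(node) - w_L * Gini(left) - w_R * Gini(right) ]

to the feature it splits on; contributions are summed per tree, averaged
over trees, and normalized to sum 1.  Only ranks are consumed downstream,
so the normalization convention does not affect selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .chem import AssayDataset
from .metrics import auc_roc, evaluate_predictions
from .resampling import ResampleConfig, smote_enn

__all__ = [
    "ForestConfig",
    "ImportanceVector",
    "gini_index",
    "gini_importance",
    "train_with_cv",
    "select_top_features",
]


def gini_index(probs: Sequence[float]) -> float:
    """Node impurity 1 - sum(p_i^2); 0 iff the node is pure."""
    p = np.asarray(probs, dtype=np.float64)
    if p.size == 0 or np.any(p < 0):
        raise ValueError("class probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class probabilities sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p * p))


@dataclass
class ImportanceVector:
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.feature_ids),):
            raise ValueError("importances misaligned with feature ids")
        if np.any(self.values < 0):
            raise ValueError("importances must be non-negative")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("importances must be normalized to sum 1")

    def to_frame(self) -> pd.DataFrame:
        order = np.lexsort((self.feature_ids, -self.values))
        return pd.DataFrame(
            {
                "protein_id": [self.feature_ids[i] for i in order],
                "importance": self.values[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


@dataclass
class ForestConfig:
    grid: dict = field(
        default_factory=lambda: {"max_depth": [None, 10, 20], "n_estimators": [100, 200]}
    )
    cv_folds: int = 10
    cv_repeats: int = 3
    seed: int = 0
    scoring: str = "balanced_accuracy"
    resample_inside_folds: bool = True  # False replicates resample-once-before-CV

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for key, vals in self.grid.items():
            for v in vals:
                if v is not None and v <= 0:
                    raise ValueError(f"grid value {v} for {key} must be positive")

    def candidates(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(self.grid[k] for k in keys))]


def gini_importance(
    forest: RandomForestClassifier,
    feature_ids: Sequence[str],
    per_tree_normalize: bool = False,
) -> ImportanceVector:
    """Mean-decrease-impurity importances from a fitted ensemble.

    ``per_tree_normalize=True`` normalizes each tree's vector before
    averaging (the scikit-learn convention) instead of once at the end;
    the two differ only by per-tree weighting, never in the single-tree
    case.
    """
    if not hasattr(forest, "estimators_"):
        raise ValueError("forest is not fitted")
    n_features = len(feature_ids)
    total = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        imp = np.zeros(n_features)
        w = t.weighted_n_node_samples
        root_w = w[0]
        internal = np.flatnonzero(t.children_left != -1)
        for node in internal:
            left, right = t.children_left[node], t.children_right[node]
            decrease = (
                w[node] * t.impurity[node]
                - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]
            ) / root_w
            imp[t.feature[node]] += decrease
        if per_tree_normalize and imp.sum() > 0:
            imp /= imp.sum()
        total += imp
    total /= len(forest.estimators_)
    s = total.sum()
    if s <= 0:
        raise ValueError("forest contains no informative splits")
    return ImportanceVector(feature_ids=list(feature_ids), values=total / s)


def _score(name: str, y_true, y_pred, scores) -> float:
    if name == "auc_roc":
        return auc_roc(y_true, scores)
    report = evaluate_predictions(y_true, y_pred)
    try:
        return getattr(report, name)
    except AttributeError:
        raise ValueError(f"unknown scoring metric {name!r}") from None


def _rng_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31 - 1))


def train_with_cv(
    dataset: AssayDataset,
    rconf: Optional[ResampleConfig] = None,
    fconf: Optional[ForestConfig] = None,
) -> tuple[RandomForestClassifier, dict, pd.DataFrame]:
    """Grid search with repeated stratified CV, then refit on everything.

    Resampling is applied to the training rows of each fold only; the
    validation fold is scored untouched.  Deterministic under the config
    seeds.  Returns (fitted model, best hyper-parameters, fold-level
    score table).
    """
    rconf = rconf or ResampleConfig()
    fconf = fconf or ForestConfig()
    X, y = dataset.X_train, dataset.y_train
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training partition must contain both classes")
    if counts.min() < fconf.cv_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples < {fconf.cv_folds} folds; "
            "use fewer cv_folds"
        )

    candidates = fconf.candidates()
    cv = RepeatedStratifiedKFold(
        n_splits=fconf.cv_folds, n_repeats=fconf.cv_repeats, random_state=_rng_seed(fconf.seed, 9)
    )
    splits = list(cv.split(X, y))

    pre_resampled = None
    if not fconf.resample_inside_folds:
        cfg = ResampleConfig(
            k_smote=rconf.k_smote, k_enn=rconf.k_enn, target_ratio=rconf.target_ratio,
            seed=_rng_seed(rconf.seed, 0), enn_scope=rconf.enn_scope,
        )
        pre_resampled = smote_enn(X, y, cfg)

    records = []
    mean_scores = []
    for ci, cand in enumerate(candidates):
        fold_scores = []
        for fi, (tr, va) in enumerate(splits):
            if fconf.resample_inside_folds:
                cfg = ResampleConfig(
                    k_smote=rconf.k_smote, k_enn=rconf.k_enn,
                    target_ratio=rconf.target_ratio,
                    seed=_rng_seed(rconf.seed, ci, fi), enn_scope=rconf.enn_scope,
                )
                Xr, yr = smote_enn(X[tr], y[tr], cfg)
            else:
                idx = np.ones(len(y), dtype=bool)
                idx[va] = False
                # fold-restricted view of the single pre-CV resample is not
                # reconstructible; the replication mode trains on the full
                # pre-resampled pool instead (the optimistic-bias variant)
                Xr, yr = pre_resampled
            model = RandomForestClassifier(
                random_state=_rng_seed(fconf.seed, ci, fi, 1), n_jobs=1, **cand
            )
            model.fit(Xr, yr)
            pred = model.predict(X[va])
            prob = model.predict_proba(X[va])[:, list(model.classes_).index(1)]
            s = _score(fconf.scoring, y[va], pred, prob)
            fold_scores.append(s)
            records.append({**cand, "repeat": fi // fconf.cv_folds, "fold": fi % fconf.cv_folds,
                            "score": s})
        mean_scores.append(float(np.mean(fold_scores)))

    best_idx = int(np.argmax(mean_scores))  # first-wins on exact ties
    best = candidates[best_idx]

    if pre_resampled is not None:
        X_final, y_final = pre_resampled
    else:
        cfg = ResampleConfig(
            k_smote=rconf.k_smote, k_enn=rconf.k_enn, target_ratio=rconf.target_ratio,
            seed=_rng_seed(rconf.seed, 0), enn_scope=rconf.enn_scope,
        )
        X_final, y_final = smote_enn(X, y, cfg)
    model = RandomForestClassifier(random_state=_rng_seed(fconf.seed, 7), n_jobs=1, **best)
    model.fit(X_final, y_final)
    return model, best, pd.DataFrame.from_records(records)


def select_top_features(importances: ImportanceVector, k: int = 100) -> list[str]:
    """Protein ids of the k largest importances, ties by lexicographic id."""
    n = len(importances.feature_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds feature count {n}")
    order = sorted(range(n), key=lambda i: (-importances.values[i], importances.feature_ids[i]))
    return [importances.feature_ids[i] for i in order[:k]]
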