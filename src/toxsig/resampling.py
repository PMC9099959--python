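"""SMOTE oversampling and edited-nearest-neighbours cleaning.

Highly imbalanced assay labels (inactive:active ratios of 5-70) push a
classifier toward the majority class.  The combined remedy implemented
here first synthesizes minority samples by linear interpolation between
minority nearest neighbours (SMOTE), then removes samples whose label
disagrees with the majority vote of their k nearest neighbours (ENN).

All neighbour searches use Euclidean distance on the raw interaction
scores (every feature already lives on the same [0, 1] scale) and break
distance ties by lower row index, so results are identical across
platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResampleConfig", "smote_oversample", "enn_edit", "smote_enn"]


@dataclass
class ResampleConfig:
    k_smote: int = 5
    k_enn: int = 3
    target_ratio: float = 1.0  # post-SMOTE minority/majority count ratio
    seed: int = 0
    enn_scope: str = "both"  # "both" or "majority"

    def __post_init__(self) -> None:
        if self.k_smote < 1 or self.k_enn < 1:
            raise ValueError("neighbour counts must be >= 1")
        if not (0 < self.target_ratio <= 1):
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.enn_scope not in ("both", "majority"):
            raise ValueError("enn_scope must be 'both' or 'majority'")


def _knn_indices(X: np.ndarray, Q: np.ndarray, k: int, exclude_self: bool = False,
                 query_offset: int | None = None) -> np.ndarray:
    """k nearest rows of X for each row of Q, ties broken by lower index.

    ``exclude_self`` removes the query's own row (identified by position
    ``query_offset + i`` in X) from its neighbour list.
    """
    # squared Euclidean via the expansion; stable argsort keeps tie order
    sq = (
        np.einsum("ij,ij->i", Q, Q)[:, None]
        + np.einsum("ij,ij->i", X, X)[None, :]
        - 2.0 * (Q @ X.T)
    )
    np.maximum(sq, 0.0, out=sq)
    if exclude_self:
        rows = np.arange(Q.shape[0])
        cols = rows + (query_offset or 0)
        sq[rows, cols] = np.inf
    order = np.argsort(np.round(sq, 12), axis=1, kind="stable")
    return order[:, :k]


def smote_oversample(
    X_minority: np.ndarray,
    n_synthetic: int,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Interpolated minority samples: x + u * (x_nn - x), u ~ U[0, 1].

    Each synthetic row picks a uniformly random minority base row, one of
    its ``k`` nearest minority neighbours, and an interpolation factor.
    """
    X_minority = np.asarray(X_minority, dtype=np.float64)
    if n_synthetic == 0:
        return np.zeros((0, X_minority.shape[1] if X_minority.ndim == 2 else 0))
    if X_minority.shape[0] < 2:
        raise ValueError("SMOTE needs at least 2 minority samples to interpolate")
    if k > X_minority.shape[0] - 1:
        raise ValueError(
            f"k={k} exceeds available minority neighbours ({X_minority.shape[0] - 1})"
        )
    rng = np.random.default_rng() if rng is None else rng
    nn = _knn_indices(X_minority, X_minority, k, exclude_self=True, query_offset=0)
    base = rng.integers(0, X_minority.shape[0], size=n_synthetic)
    pick = rng.integers(0, k, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    neigh = nn[base, pick]
    return X_minority[base] + u[:, None] * (X_minority[neigh] - X_minority[base])


def enn_edit(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    editable: np.ndarray | None = None,
) -> np.ndarray:
    """Indices retained after edited-nearest-neighbours cleaning.

    A row is removed iff the strict majority vote of its ``k`` nearest
    neighbours (itself excluded) disagrees with its own label; a tied
    vote keeps the row (removal needs positive evidence of noise).  All
    votes are evaluated against the original, unedited data in a single
    pass.  ``editable`` optionally restricts which rows may be removed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of rows ({n})")
    nn = _knn_indices(X, X, k, exclude_self=True, query_offset=0)
    votes_for_one = (y[nn] == 1).sum(axis=1)
    votes_for_zero = k - votes_for_one
    own_votes = np.where(y == 1, votes_for_one, votes_for_zero)
    other_votes = k - own_votes
    remove = other_votes > own_votes
    if editable is not None:
        remove &= np.asarray(editable, dtype=bool)
    return np.flatnonzero(~remove)


def smote_enn(
    X: np.ndarray,
    y: np.ndarray,
    config: ResampleConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE to the target class ratio, then ENN cleaning of the result.

    Original rows are never modified; retained originals appear unchanged
    in the output.  Raises on single-class input.
    """
    config = config or ResampleConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("resampling requires both classes present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()

    n_target = int(np.floor(config.target_ratio * n_maj))
    n_synth = max(0, n_target - n_min)
    rng = np.random.default_rng(config.seed)
    if n_synth > 0:
        X_min = X[y == minority]
        k = min(config.k_smote, X_min.shape[0] - 1)
        if k < 1:
            raise ValueError("SMOTE needs at least 2 minority samples")
        synth = smote_oversample(X_min, n_synth, k=k, rng=rng)
        X_aug = np.vstack([X, synth])
        y_aug = np.concatenate([y, np.full(n_synth, minority, dtype=np.int64)])
    else:
        X_aug, y_aug = X, y

    editable = None
    if config.enn_scope == "majority":
        editable = y_aug == majority
    keep = enn_edit(X_aug, y_aug, k=min(config.k_enn, len(y_aug) - 1), editable=editable)
    return X_aug[keep], y_aug[keep]
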