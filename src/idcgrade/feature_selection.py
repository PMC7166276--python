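"""Distance-based feature ranking and subset selection, plus a PCA baseline.

Each feature is scored by how far the grade-III samples sit from the
grade-II point set along that feature alone. With the feature z-scored
across the cohort, the raw separation is the mean squared distance from
each grade-III value to the set of grade-II values,

    D_j = mean_{x in III} [ (1/K) sum_{a in II} (x - a)^2 ],

which is mapped into [0, 1) by the separability score

    idx_j = 1 - exp(-(D_j / beta)^2),

a saturating, monotone transform of the raw distance; beta sets the scale
(``"auto"`` uses the median of the D_j, placing the median feature at
idx = 1 - 1/e). Features are ranked by descending idx, ties broken by
ascending feature index. An optional greedy max-min mode trades pure
separability for diversity among the already-selected features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import POSITIVE_GRADE
from .exceptions import ValidationError
from .gabor_features import FeatureMatrix


def point_set_distance(x, point_set) -> float:
    """Mean squared Euclidean distance from a point to a point set."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    pts = np.asarray(point_set, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] == 0:
        raise ValidationError("point set is empty")
    if pts.shape[1] != x.shape[0]:
        raise ValidationError(
            f"dimension mismatch: point has {x.shape[0]}, set has {pts.shape[1]}"
        )
    return float(np.mean(((pts - x) ** 2).sum(axis=1)))


def zscore_columns(values: np.ndarray) -> np.ndarray:
    """Column-wise standardization; constant columns map to zero."""
    values = np.asarray(values, dtype=np.float64)
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


@dataclass
class FeatureRanking:
    """Per-feature separability scores and the descending-idx order."""

    scores: np.ndarray   # idx values, [0, 1)
    dists: np.ndarray    # raw D values
    beta: float
    order: np.ndarray    # feature indices, descending idx
    feature_names: list

    def __len__(self):
        return self.scores.size

    def top(self, k: int) -> list[str]:
        return [self.feature_names[i] for i in self.order[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "feature_name": [self.feature_names[i] for i in self.order],
                "D": self.dists[self.order],
                "idx": self.scores[self.order],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def idx_score(dist, beta: float) -> np.ndarray:
    """Map raw distances into the [0, 1) separability score.

    Clamped to the largest double below 1 so the open upper bound holds
    even where ``exp`` underflows.
    """
    dist = np.asarray(dist, dtype=np.float64)
    return np.minimum(-np.expm1(-((dist / beta) ** 2)), np.nextafter(1.0, 0.0))


def score_features(matrix: FeatureMatrix, beta="auto") -> FeatureRanking:
    """Rank every feature by its between-class separability.

    Distances are computed per feature in its own z-scored 1-D space so
    raw feature scale cannot dominate. ``beta="auto"`` resolves to the
    median of the raw distances (so the median feature scores 1 - 1/e).
    """
    labels = matrix.labels
    pos = labels == POSITIVE_GRADE
    if not pos.any() or pos.all():
        raise ValidationError("feature scoring requires samples of both grades")
    z = zscore_columns(matrix.values)
    a = z[~pos]  # grade II point set, (K, p)
    b = z[pos]   # grade III samples,  (M, p)
    # D_j = mean over III of mean over II of squared difference, per feature.
    dists = ((b[:, None, :] - a[None, :, :]) ** 2).mean(axis=(0, 1))
    if beta == "auto":
        beta_val = float(np.median(dists))
        if beta_val <= 0:
            beta_val = 1.0
    else:
        beta_val = float(beta)
        if beta_val <= 0:
            raise ValidationError(f"beta must be positive, got {beta}")
    scores = idx_score(dists, beta_val)
    order = np.argsort(-scores, kind="stable")  # ties: ascending feature index
    return FeatureRanking(
        scores=scores,
        dists=dists,
        beta=beta_val,
        order=order,
        feature_names=list(matrix.feature_names),
    )


def select_subset(ranking: FeatureRanking, k: int) -> np.ndarray:
    """First ``k`` feature indices of the ranking (1 <= k <= n_features)."""
    if not 1 <= k <= len(ranking):
        raise ValidationError(f"k must be in [1, {len(ranking)}], got {k}")
    return ranking.order[:k].copy()


def select_greedy(matrix: FeatureMatrix, ranking: FeatureRanking, k: int) -> np.ndarray:
    """Greedy max-min diversity selection.

    Starts from the top-idx feature, then repeatedly adds the feature
    maximizing its minimum mean-squared column distance (in z-scored
    sample space) to the features already chosen; ties go to higher idx.
    A heuristic alternative to pure ranking, not the default.
    """
    if not 1 <= k <= len(ranking):
        raise ValidationError(f"k must be in [1, {len(ranking)}], got {k}")
    z = zscore_columns(matrix.values)
    chosen = [int(ranking.order[0])]
    while len(chosen) < k:
        remaining = [j for j in range(len(ranking)) if j not in chosen]
        min_d = np.array(
            [min(float(((z[:, j] - z[:, c]) ** 2).mean()) for c in chosen) for j in remaining]
        )
        best = max(
            range(len(remaining)),
            key=lambda i: (min_d[i], ranking.scores[remaining[i]]),
        )
        chosen.append(remaining[best])
    return np.asarray(chosen)


def pca_reduce(matrix: FeatureMatrix, k: int):
    """Project z-scored features onto the top-k principal axes.

    Returns ``(scores, explained_variance_ratio)`` with components in
    descending eigenvalue order. Baseline for comparison against the
    distance ranking; not used by the grading model itself.
    """
    from sklearn.decomposition import PCA

    n, p = matrix.values.shape
    if not 1 <= k <= min(n, p):
        raise ValidationError(f"k must be in [1, {min(n, p)}], got {k}")
    z = zscore_columns(matrix.values)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)
    return scores, pca.explained_variance_ratio_


def ranking_recovery(ranking: FeatureRanking, injected_names, top_n: int = 3) -> bool:
    """True if any injected (ground-truth discriminative) feature is in the top ranks."""
    top = set(ranking.top(top_n))
    return len(top & set(injected_names)) > 0
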