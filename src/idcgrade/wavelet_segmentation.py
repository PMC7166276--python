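"""Unsupervised tumor segmentation: 2-level DWT + K-means over pixel features.

The lesion ROI is decomposed with a 2-level 2-D discrete wavelet transform
(orthogonal wavelet, ``db2`` by default, periodized boundary so each level
halves the side to the ceiling). Every ROI pixel is then described by an
8-channel feature vector — the original intensity, the six detail-subband
magnitudes (horizontal/vertical/diagonal at both levels, upsampled back to
the ROI grid) and the level-2 approximation — and clustered with K-means
under squared Euclidean cost. The cluster whose member pixels are brightest
in the original (contrast-enhanced) ROI is taken as tumor, then reduced to
its largest 4-connected component to suppress speckle.

K-means is implemented directly (vectorized Lloyd iterations) because the
segmentation contract pins details a generic library leaves open: nearest-
center assignment with lowest-index tie-breaking, group-mean center
updates, stopping when the cost decrease falls below a tolerance, restart
selection by final cost, and reinitialization of emptied clusters at the
point farthest from its current center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from skimage import measure

from .exceptions import ConfigurationError, SegmentationError, ValidationError

#: Boundary mode for the DWT; periodized so a side of s maps to ceil(s/2)
#: per level (60 -> 30 -> 15) and the orthogonal transform reconstructs
#: perfectly.
_DWT_MODE = "periodization"


@dataclass
class WaveletDecomposition:
    """Two-level subband set: per-level (LH, HL, HH) details plus level-2 LL."""

    levels: tuple  # ((LH1, HL1, HH1), (LH2, HL2, HH2)) as 2-D arrays
    approximation: np.ndarray  # level-2 LL
    wavelet: str
    original_shape: tuple
    _coeffs: list = field(repr=False, default=None)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def dwt_decompose(roi: np.ndarray, wavelet: str = "db2", n_levels: int = 2) -> WaveletDecomposition:
    """Full dyadic subband decomposition of a square ROI.

    Raises :class:`ConfigurationError` for unknown wavelet names and
    :class:`ValidationError` if the ROI is too small for ``n_levels``.
    """
    roi = np.asarray(roi, dtype=np.float64)
    if roi.ndim != 2:
        raise ValidationError(f"ROI must be 2-D, got shape {roi.shape}")
    if min(roi.shape) < 2 ** n_levels:
        raise ValidationError(
            f"ROI side {min(roi.shape)} too small for {n_levels}-level decomposition"
        )
    try:
        pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet!r}") from exc
    coeffs = pywt.wavedec2(roi, wavelet, mode=_DWT_MODE, level=n_levels)
    # wavedec2 orders coarsest-first: [LL_n, (LH_n, HL_n, HH_n), ..., (LH_1, ...)]
    levels = tuple(tuple(coeffs[-lvl]) for lvl in range(1, n_levels + 1))
    return WaveletDecomposition(
        levels=levels,
        approximation=coeffs[0],
        wavelet=wavelet,
        original_shape=roi.shape,
        _coeffs=coeffs,
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse transform; recovers the ROI to floating tolerance."""
    rec = pywt.waverec2(decomp._coeffs, decomp.wavelet, mode=_DWT_MODE)
    h, w = decomp.original_shape
    return rec[:h, :w]


@dataclass
class PixelFeatureStack:
    """Per-pixel clustering features on the ROI grid.

    ``vectors`` is (n_pixels, depth), row-major over the ROI; each channel
    is min-max normalized to [0, 1] (constant channels become all zeros).
    """

    vectors: np.ndarray
    shape: tuple
    depth: int


def _upsample_nearest(sub: np.ndarray, factor: int, shape: tuple) -> np.ndarray:
    up = np.repeat(np.repeat(sub, factor, axis=0), factor, axis=1)
    return up[: shape[0], : shape[1]]


def _minmax(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi - lo <= 0:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def build_feature_stack(roi: np.ndarray, decomp: WaveletDecomposition) -> PixelFeatureStack:
    """Stack intensity + subband-magnitude channels for clustering.

    Depth is 1 (original) + 3 per level (detail magnitudes) + 1 (final
    approximation) = 8 for the default two levels. Subbands are brought
    back to the ROI grid by nearest-neighbor (pixel-replication)
    upsampling.
    """
    roi = np.asarray(roi, dtype=np.float64)
    if roi.shape != tuple(decomp.original_shape):
        raise ValidationError(
            f"ROI shape {roi.shape} does not match decomposition "
            f"{tuple(decomp.original_shape)}"
        )
    channels = [roi]
    for lvl, triple in enumerate(decomp.levels, start=1):
        factor = 2 ** lvl
        for sub in triple:
            channels.append(_upsample_nearest(np.abs(sub), factor, roi.shape))
    channels.append(
        _upsample_nearest(decomp.approximation, 2 ** decomp.n_levels, roi.shape)
    )
    stacked = np.stack([_minmax(c) for c in channels], axis=-1)
    vectors = stacked.reshape(-1, stacked.shape[-1])
    return PixelFeatureStack(vectors=vectors, shape=roi.shape, depth=stacked.shape[-1])


@dataclass
class ClusterModel:
    """Fitted K-means state: centers, hard assignments, and final cost.

    ``cost`` is the summed within-cluster squared Euclidean distance,
    recomputable from ``centers`` + ``labels`` + the data.
    ``cost_history`` is the (non-increasing) per-iteration cost of the
    winning restart.
    """

    centers: np.ndarray
    labels: np.ndarray
    cost: float
    n_iter: int
    converged: bool
    cost_history: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def membership(self) -> np.ndarray:
        """Binary membership matrix U (clusters x points), columns sum to 1."""
        u = np.zeros((self.n_clusters, self.labels.size), dtype=int)
        u[self.labels, np.arange(self.labels.size)] = 1
        return u

    def recompute_cost(self, data: np.ndarray) -> float:
        data = np.asarray(data, dtype=np.float64)
        diffs = data - self.centers[self.labels]
        return float(np.sum(diffs * diffs))


def _sq_dists(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # (n, c) squared Euclidean distances, ||x||^2 - 2 x.c + ||c||^2 form
    d2 = (
        (data ** 2).sum(axis=1)[:, None]
        - 2.0 * data @ centers.T
        + (centers ** 2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _lloyd_once(data, unique, c, rng, max_iter, tol):
    init_idx = rng.choice(unique.shape[0], size=c, replace=False)
    centers = unique[init_idx].astype(np.float64)
    history = []
    prev_cost = np.inf
    converged = False
    labels = None
    for _ in range(max_iter):
        d2 = _sq_dists(data, centers)
        labels = np.argmin(d2, axis=1)  # argmin ties -> lowest cluster index
        # Reseed emptied clusters at the point farthest from its own center.
        for i in range(c):
            if not np.any(labels == i):
                assigned = d2[np.arange(data.shape[0]), labels]
                far = int(np.argmax(assigned))
                centers[i] = data[far]
                d2 = _sq_dists(data, centers)
                labels = np.argmin(d2, axis=1)
        cost = float(d2[np.arange(data.shape[0]), labels].sum())
        history.append(cost)
        if prev_cost - cost < tol:
            converged = True
            break
        prev_cost = cost
        for i in range(c):
            centers[i] = data[labels == i].mean(axis=0)
    return centers, labels, history, converged


def kmeans_cluster(
    stack,
    c: int = 4,
    n_restarts: int = 10,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> ClusterModel:
    """K-means under squared Euclidean cost, best of ``n_restarts`` runs.

    ``stack`` may be a :class:`PixelFeatureStack` or a plain (n, d) array.
    Each restart initializes centers at ``c`` distinct data vectors drawn
    at random, iterates nearest-center assignment / group-mean updates,
    and stops once the cost decrease drops below ``tol``; the restart with
    the smallest final cost wins (ties go to the earlier restart).
    """
    data = stack.vectors if isinstance(stack, PixelFeatureStack) else np.asarray(stack, dtype=np.float64)
    if data.ndim == 1:
        data = data[:, None]
    if c < 2:
        raise ValidationError(f"need c >= 2 clusters, got {c}")
    unique = np.unique(data, axis=0)
    if unique.shape[0] < c:
        raise ValidationError(
            f"only {unique.shape[0]} distinct points for c={c} clusters"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers, labels, history, converged = _lloyd_once(data, unique, c, rng, max_iter, tol)
        if best is None or history[-1] < best[2][-1]:
            best = (centers, labels, history, converged)
    centers, labels, history, converged = best
    return ClusterModel(
        centers=centers,
        labels=labels,
        cost=history[-1],
        n_iter=len(history),
        converged=converged,
        cost_history=np.asarray(history),
    )


@dataclass
class TumorMask:
    """Boolean tumor mask on the ROI grid.

    ``cluster_id``, ``cost`` and ``seed`` record how a segmented mask was
    produced; they stay ``None`` for ground-truth or hand-made masks.
    """

    mask: np.ndarray
    cluster_id: int | None = None
    cost: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def jaccard(self, other: "TumorMask") -> float:
        a, b = self.mask, np.asarray(other.mask if isinstance(other, TumorMask) else other, dtype=bool)
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 1.0
        return float(np.logical_and(a, b).sum() / union)


def select_tumor_cluster(model: ClusterModel, roi: np.ndarray) -> TumorMask:
    """Pick the brightest cluster (highest mean ROI intensity) as tumor.

    After selection the mask is reduced to its largest 4-connected
    component. Raises :class:`SegmentationError` (with per-cluster
    diagnostics) if the selection is empty.
    """
    roi = np.asarray(roi, dtype=np.float64)
    flat = roi.ravel()
    if flat.size != model.labels.size:
        raise ValidationError("cluster model was not fit on this ROI")
    sizes = np.bincount(model.labels, minlength=model.n_clusters)
    means = np.full(model.n_clusters, -np.inf)
    for i in range(model.n_clusters):
        if sizes[i]:
            means[i] = flat[model.labels == i].mean()
    chosen = int(np.argmax(means))
    mask = (model.labels == chosen).reshape(roi.shape)
    if not mask.any():
        raise SegmentationError(
            "selected tumor cluster is empty",
            diagnostics={"cluster_sizes": sizes.tolist(), "chosen": chosen},
        )
    comp = measure.label(mask, connectivity=1)
    counts = np.bincount(comp.ravel())
    counts[0] = 0  # background label
    largest = int(np.argmax(counts))
    return TumorMask(comp == largest, cluster_id=chosen, cost=model.cost)


@dataclass
class SegmentationConfig:
    """Settings for the DWT + K-means segmentation stage."""

    seed: int
    wavelet: str = "db2"
    levels: int = 2
    k_clusters: int = 4
    restarts: int = 10
    max_iter: int = 100
    tol: float = 1e-6

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        known = {"wavelet", "levels", "k_clusters", "restarts", "max_iter", "tol", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown segmentation config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigurationError("segmentation config requires an explicit seed")
        return cls(**d)


def segment_tumor(roi: np.ndarray, config: SegmentationConfig) -> TumorMask:
    """Full segmentation chain: DWT -> feature stack -> K-means -> mask.

    Deterministic for a fixed config (the seed drives all restarts).
    """
    decomp = dwt_decompose(roi, wavelet=config.wavelet, n_levels=config.levels)
    stack = build_feature_stack(roi, decomp)
    model = kmeans_cluster(
        stack,
        c=config.k_clusters,
        n_restarts=config.restarts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=config.seed,
    )
    mask = select_tumor_cluster(model, roi)
    mask.seed = config.seed
    return mask


def write_mask(mask: TumorMask, path, meta: dict | None = None) -> None:
    """Persist a mask as a 0/255 PNG plus a JSON sidecar of metadata."""
    from .dataset_io import save_image

    path = Path(path)
    save_image(mask.mask.astype(np.uint8) * 255, path)
    sidecar = dict(meta or {})
    sidecar["n_pixels"] = mask.n_pixels
    for key in ("cluster_id", "cost", "seed"):
        value = getattr(mask, key)
        if value is not None and key not in sidecar:
            sidecar[key] = value
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
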