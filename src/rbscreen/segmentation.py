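"""Background removal: hue thresholding, colour k-means, white-cluster removal.

The stage converts the RGB image to HSV, min-max normalizes the hue channel,
posterizes it by multi-level Otsu thresholding (exhaustive between-class
variance maximization on a 64-bin hue histogram), converts back to RGB, and
clusters the colours with seeded k-means (K = 3 by default).  The cluster
whose centroid lies nearest to pure white is treated as background and its
pixels are painted with the fill colour; all other pixels of the original
image pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "LabelMap",
    "SegmentationConfig",
    "multi_otsu_thresholds",
    "hue_multilevel_threshold",
    "lloyd_kmeans",
    "kmeans_color_segment",
    "remove_white_cluster",
    "segment_image",
]


@dataclass
class LabelMap:
    """Per-pixel integer cluster/level ids in {0..K-1}."""

    grid: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("label grid must be 2-D")
        if self.grid.min() < 0 or self.grid.max() >= self.K:
            raise ValueError("label ids must lie in {0..K-1}")


@dataclass(frozen=True)
class SegmentationConfig:
    n_hue_levels: int = 3
    K: int = 3
    white_fill: tuple[int, int, int] = (255, 255, 255)
    seed: int = 0
    max_kmeans_iter: int = 100
    kmeans_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_hue_levels < 2:
            raise ValueError("n_hue_levels must be >= 2")


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("segmentation requires an RGB image; convert grayscale to RGB first")
    return image


def multi_otsu_thresholds(hist: np.ndarray, n_levels: int) -> list[int]:
    """Exhaustively choose n_levels-1 threshold bins maximizing between-class
    variance of the binned histogram.

    Returns the upper bin index of each class but the last; a value in bin b
    belongs to class k iff thresholds[k-1] < b <= thresholds[k].
    """
    hist = np.asarray(hist, dtype=float)
    n_bins = hist.size
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram")
    p = hist / total
    bins = np.arange(n_bins)
    # cumulative weight and mass for O(1) class statistics
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * bins)])

    def class_var(edges: tuple[int, ...]) -> float:
        score = 0.0
        lo = 0
        for hi in (*edges, n_bins - 1):
            w = cw[hi + 1] - cw[lo]
            if w > 0:
                m = (cm[hi + 1] - cm[lo]) / w
                score += w * m * m
            lo = hi + 1
        return score

    best_edges = None
    best_score = -np.inf
    for edges in combinations(range(n_bins - 1), n_levels - 1):
        s = class_var(edges)
        if s > best_score:
            best_score = s
            best_edges = edges
    return list(best_edges)


def _normalize_hue(hue: np.ndarray) -> np.ndarray:
    lo, hi = hue.min(), hue.max()
    if hi - lo == 0:
        return np.zeros_like(hue)
    return (hue - lo) / (hi - lo)


def hue_multilevel_threshold(image: np.ndarray, n_levels: int = 3,
                             n_bins: int = 64) -> LabelMap:
    """Posterize the normalized hue channel into ``n_levels`` Otsu classes."""
    image = _require_rgb(image)
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    hue = rgb2hsv(image)[..., 0]
    hue = _normalize_hue(hue)
    if hue.max() == hue.min():
        # constant hue: degenerate, single level
        return LabelMap(grid=np.zeros(hue.shape, dtype=int), K=n_levels)
    bin_idx = np.minimum((hue * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(bin_idx.ravel(), minlength=n_bins)
    edges = multi_otsu_thresholds(hist, n_levels)
    labels = np.searchsorted(np.asarray(edges), bin_idx, side="left")
    return LabelMap(grid=labels, K=n_levels)


def lloyd_kmeans(points: np.ndarray, K: int, seed: int = 0, max_iter: int = 100,
                 tol: float = 1e-4) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Seeded Lloyd k-means with farthest-point (k-means++-style) seeding.

    The first centroid is a seeded random point; each further centroid is the
    point farthest from its nearest chosen centroid (ties -> lowest index).
    Returns (labels, centroids, within-cluster-SS history, one entry per
    assignment step).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if K > n:
        raise ValueError("K exceeds the number of points")
    rng = np.random.default_rng(seed)
    centroids = np.empty((K, points.shape[1]))
    centroids[0] = points[int(rng.integers(n))]
    if K > 1:
        d2 = ((points - centroids[0]) ** 2).sum(axis=1)
        for k in range(1, K):
            centroids[k] = points[int(np.argmax(d2))]
            d2 = np.minimum(d2, ((points - centroids[k]) ** 2).sum(axis=1))

    history: list[float] = []
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist2 = cdist(points, centroids, metric="sqeuclidean")
        labels = np.argmin(dist2, axis=1)  # ties -> lowest centroid id
        history.append(float(dist2[np.arange(n), labels].sum()))
        new_centroids = centroids.copy()
        for k in range(K):
            members = labels == k
            if members.any():
                new_centroids[k] = points[members].mean(axis=0)
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    dist2 = cdist(points, centroids, metric="sqeuclidean")
    labels = np.argmin(dist2, axis=1)
    history.append(float(dist2[np.arange(n), labels].sum()))
    return labels, centroids, history


def kmeans_color_segment(image: np.ndarray,
                         config: SegmentationConfig | None = None
                         ) -> tuple[LabelMap, np.ndarray]:
    """Cluster RGB triples into ``config.K`` colour clusters (seeded Lloyd)."""
    config = config or SegmentationConfig()
    image = _require_rgb(image)
    flat = image.reshape(-1, 3).astype(float)
    n_distinct = np.unique(flat, axis=0).shape[0]
    if config.K > n_distinct:
        raise ValueError(f"K={config.K} exceeds the {n_distinct} distinct colours present")
    labels, centroids, _ = lloyd_kmeans(flat, config.K, seed=config.seed,
                                        max_iter=config.max_kmeans_iter,
                                        tol=config.kmeans_tol)
    return LabelMap(grid=labels.reshape(image.shape[:2]), K=config.K), centroids


def remove_white_cluster(image: np.ndarray, labels: LabelMap, centroids: np.ndarray,
                         fill: tuple[int, int, int] = (255, 255, 255)) -> np.ndarray:
    """Paint the cluster whose centroid is nearest pure white with ``fill``."""
    image = _require_rgb(image)
    centroids = np.asarray(centroids, dtype=float)
    white = np.array([255.0, 255.0, 255.0])
    target = int(np.argmin(np.linalg.norm(centroids - white, axis=1)))
    out = image.copy()
    out[labels.grid == target] = np.asarray(fill, dtype=image.dtype)
    return out


def segment_image(image: np.ndarray,
                  config: SegmentationConfig | None = None) -> np.ndarray:
    """Full background-removal pipeline.

    Hue normalization -> multi-level hue thresholding (posterized hue) ->
    back to RGB -> k-means colour clustering -> white-cluster removal.  The
    posterized image only steers the clustering; the returned image is the
    original with the background cluster painted with the fill colour.
    """
    config = config or SegmentationConfig()
    image = _require_rgb(image)
    hsv = rgb2hsv(image)
    hue = _normalize_hue(hsv[..., 0])
    level_map = hue_multilevel_threshold(image, config.n_hue_levels)
    # replace each pixel's hue by its level's mean normalized hue, then undo
    # the normalization so the posterized image stays in the original gamut
    lo, hi = hsv[..., 0].min(), hsv[..., 0].max()
    post_hue = hue.copy()
    for level in range(config.n_hue_levels):
        members = level_map.grid == level
        if members.any():
            post_hue[members] = hue[members].mean()
    hsv_post = hsv.copy()
    hsv_post[..., 0] = post_hue * (hi - lo) + lo
    posterized = np.clip(np.rint(hsv2rgb(hsv_post) * 255.0), 0, 255).astype(np.uint8)

    labels, centroids = kmeans_color_segment(posterized, config)
    return remove_white_cluster(image, labels, centroids, config.white_fill)
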