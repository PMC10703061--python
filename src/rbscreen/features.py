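"""Handcrafted texture features, a seeded conv filter bank, and fusion.

The handcrafted path quantizes the grayscale image to ``L`` levels, counts
gray-level co-occurrences ``C(i, j)`` of pixel pairs ``(p, p + offset)`` for a
set of spatial offsets, normalizes each matrix, and summarizes it by the four
classic Haralick statistics

    contrast     = sum (i - j)^2 p(i, j)
    correlation  = sum (i - mu_i)(j - mu_j) p(i, j) / (sigma_i sigma_j)
    energy       = sum p(i, j)^2
    homogeneity  = sum p(i, j) / (1 + |i - j|)

The learned-feature stand-in is an untrained, seeded bank of random
convolution kernels followed by bias, ReLU, and non-overlapping max-pooling;
its output dimensionality is configuration-determined.  The two vectors are
fused by concatenation under disjoint name prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d
from skimage.color import rgb2gray

from .core import FeatureVector

__all__ = [
    "GLCMConfig",
    "GLCMatrix",
    "GLCMStats",
    "ConvBankConfig",
    "quantize_gray",
    "compute_glcm",
    "glcm_statistics",
    "handcrafted_features",
    "filter_bank_kernels",
    "conv_filterbank_features",
    "fuse_features",
]

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization depth, pair offsets (d_row, d_col), and matrix options."""

    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        for off in self.offsets:
            if tuple(off) == (0, 0):
                raise ValueError("offsets must be nonzero")


@dataclass
class GLCMatrix:
    """L x L co-occurrence counts (or probabilities) for one offset."""

    matrix: np.ndarray
    offset: tuple[int, int]
    normalized: bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GLCM must be square")


@dataclass(frozen=True)
class GLCMStats:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    degenerate_correlation: bool = False

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.contrast, self.correlation, self.energy, self.homogeneity)


def _to_gray8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        image = rgb2gray(image) * 255.0
    return image


def quantize_gray(image: np.ndarray, L: int) -> np.ndarray:
    """Uniformly bin [0, 255] intensities into L equal-width levels."""
    if L < 2:
        raise ValueError("L must be >= 2")
    image = _to_gray8(image)
    q = np.floor(image.astype(float) * L / 256.0).astype(int)
    return np.clip(q, 0, L - 1)


def compute_glcm(image: np.ndarray, offset: tuple[int, int],
                 config: GLCMConfig | None = None) -> GLCMatrix:
    """Count ordered gray-level pairs at ``(row + d_row, col + d_col)``.

    With ``symmetric`` the transpose is added; with ``normalize`` the matrix
    is divided by its total so entries form a probability distribution.
    """
    config = config or GLCMConfig()
    image = np.asarray(image, dtype=int)
    if image.ndim != 2:
        raise ValueError("quantized image must be 2-D")
    L = config.levels
    if image.min() < 0 or image.max() >= L:
        raise ValueError(f"image values must lie in 0..{L - 1}")
    dr, dc = int(offset[0]), int(offset[1])
    h, w = image.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    C = np.zeros((L, L), dtype=float)
    if r1 > r0 and c1 > c0:
        src = image[r0:r1, c0:c1].ravel()
        dst = image[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        np.add.at(C, (src, dst), 1.0)
    if config.symmetric:
        C = C + C.T
    if config.normalize:
        total = C.sum()
        if total > 0:
            C /= total
    return GLCMatrix(matrix=C, offset=(dr, dc), normalized=config.normalize)


def glcm_statistics(glcm: GLCMatrix) -> GLCMStats:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    Degenerate marginals (zero variance) yield correlation 0 with
    ``degenerate_correlation=True`` so constant images remain processable.
    """
    if not glcm.normalized:
        raise ValueError("glcm_statistics requires a normalized GLCM")
    p = glcm.matrix
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    denom = np.sqrt(var_i * var_j)
    if denom == 0.0:
        return GLCMStats(contrast, 0.0, energy, homogeneity, degenerate_correlation=True)
    corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / denom)
    return GLCMStats(contrast, corr, energy, homogeneity)


def handcrafted_features(image: np.ndarray,
                         config: GLCMConfig | None = None) -> FeatureVector:
    """Per-offset normalized GLCM statistics, 4 x n_offsets values."""
    config = config or GLCMConfig()
    q = quantize_gray(image, config.levels)
    stat_config = GLCMConfig(levels=config.levels, offsets=config.offsets,
                             symmetric=config.symmetric, normalize=True)
    values: list[float] = []
    names: list[str] = []
    for off in config.offsets:
        stats = glcm_statistics(compute_glcm(q, off, stat_config))
        for stat_name, v in zip(("contrast", "correlation", "energy", "homogeneity"),
                                stats.as_tuple()):
            values.append(v)
            names.append(f"glcm[{off[0]},{off[1]}]_{stat_name}")
    return FeatureVector(values=np.array(values), names=names)


@dataclass(frozen=True)
class ConvBankConfig:
    """Untrained conv bank: seeded random kernels, bias, ReLU, max-pool."""

    n_filters: int = 8
    kernel: int = 3
    stride: int = 1
    bias: float = 0.0
    pool: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel side must be odd and >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.pool < 1:
            raise ValueError("pool must be >= 1")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")


def filter_bank_kernels(config: ConvBankConfig) -> np.ndarray:
    """The fixed seeded kernel stack (n_filters, kernel, kernel)."""
    rng = np.random.default_rng(config.seed)
    return rng.standard_normal((config.n_filters, config.kernel, config.kernel))


def conv_filterbank_features(image: np.ndarray, config: ConvBankConfig | None = None,
                             kernels: np.ndarray | None = None) -> FeatureVector:
    """Valid-mode filtering + bias + ReLU + non-overlapping max-pool, flattened.

    ``kernels`` overrides the seeded bank (used e.g. to test monotonicity with
    nonnegative kernels); convolution follows the usual feature-extraction
    convention of sliding the un-flipped kernel (cross-correlation).
    """
    config = config or ConvBankConfig()
    image = _to_gray8(image).astype(float) / 255.0
    if image.ndim != 2:
        raise ValueError("conv filter bank expects a grayscale image")
    if min(image.shape) < config.kernel:
        raise ValueError("image must be at least as large as the kernel")
    if kernels is None:
        kernels = filter_bank_kernels(config)
    values: list[float] = []
    names: list[str] = []
    for f_idx, kernel in enumerate(kernels):
        fmap = correlate2d(image, kernel, mode="valid")
        fmap = fmap[::config.stride, ::config.stride] + config.bias
        fmap = np.maximum(fmap, 0.0)  # ReLU
        p = config.pool
        if fmap.shape[0] < p or fmap.shape[1] < p:
            raise ValueError("pool window larger than feature map")
        hp, wp = fmap.shape[0] // p, fmap.shape[1] // p
        pooled = fmap[:hp * p, :wp * p].reshape(hp, p, wp, p).max(axis=(1, 3))
        for r in range(hp):
            for c in range(wp):
                values.append(float(pooled[r, c]))
                names.append(f"conv{f_idx}_r{r}_c{c}")
    return FeatureVector(values=np.array(values), names=names)


def fuse_features(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Concatenate two feature vectors; name spaces must be disjoint."""
    clash = set(a.names) & set(b.names)
    if clash:
        raise ValueError(f"feature name collision: {sorted(clash)[:5]}")
    return FeatureVector(values=np.concatenate([a.values, b.values]),
                         names=list(a.names) + list(b.names))
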