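"""Image smoothing, mask dilation, diffusion inpainting, and augmentation.

Specular light spots on fundus photographs are removed by treating the image
as a diffusing field: the spot mask is first dilated so the saturated region
connects to valid surrounding pixels, then the masked pixels are filled by
iterative 4-neighbour averaging (Jacobi sweeps) until convergence.  This is
harmonic (Laplace) inpainting — the transport-free limit of fluid-flow
inpainting — and inherits the discrete maximum principle: filled values never
leave the range of the surrounding boundary values.

Augmentation provides flips, rescaling, random/sliding crops and
texture-kernel pasting (re-sampling a patch of the image onto itself at a
seeded location), all label-preserving and seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .core import LabeledImage

__all__ = [
    "StructuringElement",
    "InpaintConfig",
    "AugmentConfig",
    "median_filter",
    "dilate_mask",
    "inpaint_diffusion",
    "augment_image",
]


def _square_footprint() -> np.ndarray:
    return np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class StructuringElement:
    """Odd-sided binary footprint for morphological dilation."""

    footprint: np.ndarray = field(default_factory=_square_footprint)

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or any(s % 2 == 0 for s in fp.shape):
            raise ValueError("structuring element must be 2-D with odd side lengths")
        object.__setattr__(self, "footprint", fp)


@dataclass(frozen=True)
class InpaintConfig:
    """Controls the diffusion fill.

    ``tolerance`` is the maximum per-pixel change per sweep on the [0, 1]
    intensity scale at which the iteration stops.
    """

    max_iterations: int = 500
    tolerance: float = 1e-3
    dilation_element: StructuringElement = field(default_factory=StructuringElement)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Sliding-window median with edge-replication padding.

    RGB images are filtered per channel; shape and dtype are preserved.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    image = np.asarray(image)
    if image.ndim == 2:
        return ndi.median_filter(image, size=window, mode="nearest")
    if image.ndim == 3:
        out = np.empty_like(image)
        for c in range(image.shape[2]):
            out[..., c] = ndi.median_filter(image[..., c], size=window, mode="nearest")
        return out
    raise ValueError("image must be 2-D grayscale or 3-D RGB")


def dilate_mask(mask: np.ndarray, element: StructuringElement | None = None) -> np.ndarray:
    """Minkowski dilation of a binary mask; output is a superset of the input."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    element = element or StructuringElement()
    return ndi.binary_dilation(mask, structure=element.footprint)


def inpaint_diffusion(image: np.ndarray, mask: np.ndarray,
                      config: InpaintConfig | None = None) -> np.ndarray:
    """Fill masked pixels by harmonic diffusion from their surroundings.

    The mask is first dilated by ``config.dilation_element``; the (dilated)
    masked pixels are then relaxed by Jacobi 4-neighbour averaging until the
    largest per-sweep change drops below ``config.tolerance`` or
    ``max_iterations`` is reached.  Unmasked pixels are never modified.
    8-bit input is processed on the [0, 1] scale and re-quantized on output.
    """
    config = config or InpaintConfig()
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image spatial shape")
    hole = dilate_mask(mask, config.dilation_element)
    if not hole.any():
        return image.copy()
    if hole.all():
        raise ValueError("mask (after dilation) covers the entire image: no boundary data")

    was_uint8 = image.dtype == np.uint8
    work = image.astype(float)
    if was_uint8:
        work = work / 255.0
    if work.ndim == 2:
        work = work[..., None]

    # seed hole pixels at the mean of the known pixels for faster relaxation
    known_mean = work[~hole].reshape(-1, work.shape[2]).mean(axis=0)
    work[hole] = known_mean

    for _ in range(config.max_iterations):
        padded = np.pad(work, ((1, 1), (1, 1), (0, 0)), mode="edge")
        neigh = (padded[:-2, 1:-1] + padded[2:, 1:-1]
                 + padded[1:-1, :-2] + padded[1:-1, 2:]) / 4.0
        delta = np.abs(neigh[hole] - work[hole]).max()
        work[hole] = neigh[hole]
        if delta < config.tolerance:
            break

    if image.ndim == 2:
        work = work[..., 0]
    if was_uint8:
        out = np.clip(np.rint(work * 255.0), 0, 255).astype(np.uint8)
    else:
        out = work.astype(image.dtype)
    # contract: unmasked pixels pass through untouched
    out[~hole] = image[~hole]
    return out


@dataclass(frozen=True)
class AugmentConfig:
    """Ordered list of augmentation op specs.

    Each op is a ``(name, params)`` pair with names drawn from
    ``horizontal_flip``, ``vertical_flip``, ``rescale`` (``size=(h, w)``),
    ``random_crop`` (``size=(h, w), seed``), ``sliding_crop``
    (``size=(h, w), stride``), ``texture_kernel_paste``
    (``kernel_size, n_pastes, seed``).
    """

    ops: tuple = ()


def _crop(image: LabeledImage, r0: int, c0: int, size: tuple[int, int]) -> LabeledImage:
    h, w = size
    mask = image.tumor_mask
    return LabeledImage(
        pixels=image.pixels[r0:r0 + h, c0:c0 + w].copy(),
        label=image.label,
        tumor_mask=None if mask is None else mask[r0:r0 + h, c0:c0 + w].copy(),
    )


def _flip(image: LabeledImage, axis: int) -> LabeledImage:
    mask = image.tumor_mask
    return LabeledImage(
        pixels=np.flip(image.pixels, axis=axis).copy(),
        label=image.label,
        tumor_mask=None if mask is None else np.flip(mask, axis=axis).copy(),
    )


def _rescale(image: LabeledImage, size: tuple[int, int]) -> LabeledImage:
    out = resize(image.pixels, size, preserve_range=True, anti_aliasing=True)
    mask = image.tumor_mask
    if mask is not None:
        mask = resize(mask.astype(float), size, order=0, preserve_range=True) > 0.5
    return LabeledImage(pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
                        label=image.label, tumor_mask=mask)


def _texture_paste(image: LabeledImage, kernel_size: int, n_pastes: int,
                   seed: int) -> LabeledImage:
    """Hard-paste seeded same-image patches (texture kernels) onto the image."""
    if kernel_size < 1 or kernel_size > min(image.pixels.shape[:2]):
        raise ValueError("kernel_size must fit inside the image")
    rng = np.random.default_rng(seed)
    pixels = image.pixels.copy()
    h, w = pixels.shape[:2]
    k = kernel_size
    for _ in range(n_pastes):
        sr = int(rng.integers(0, h - k + 1))
        sc = int(rng.integers(0, w - k + 1))
        dr = int(rng.integers(0, h - k + 1))
        dc = int(rng.integers(0, w - k + 1))
        patch = image.pixels[sr:sr + k, sc:sc + k].copy()
        pixels[dr:dr + k, dc:dc + k] = patch
    mask = image.tumor_mask
    return LabeledImage(pixels=pixels, label=image.label,
                        tumor_mask=None if mask is None else mask.copy())


def augment_image(image: LabeledImage, config: AugmentConfig) -> list[LabeledImage]:
    """Apply each configured op; one output per op application (a sliding
    crop yields one output per window).  Labels propagate unchanged."""
    outputs: list[LabeledImage] = []
    h, w = image.pixels.shape[:2]
    for name, params in config.ops:
        params = dict(params)
        if name == "horizontal_flip":
            outputs.append(_flip(image, axis=1))
        elif name == "vertical_flip":
            outputs.append(_flip(image, axis=0))
        elif name == "rescale":
            outputs.append(_rescale(image, tuple(params["size"])))
        elif name == "random_crop":
            ch, cw = params["size"]
            if ch > h or cw > w:
                raise ValueError("crop size exceeds image size")
            rng = np.random.default_rng(params.get("seed", 0))
            r0 = int(rng.integers(0, h - ch + 1))
            c0 = int(rng.integers(0, w - cw + 1))
            outputs.append(_crop(image, r0, c0, (ch, cw)))
        elif name == "sliding_crop":
            ch, cw = params["size"]
            stride = int(params.get("stride", ch))
            if ch > h or cw > w:
                raise ValueError("crop size exceeds image size")
            for r0 in range(0, h - ch + 1, stride):
                for c0 in range(0, w - cw + 1, stride):
                    outputs.append(_crop(image, r0, c0, (ch, cw)))
        elif name == "texture_kernel_paste":
            outputs.append(_texture_paste(image, int(params["kernel_size"]),
                                          int(params.get("n_pastes", 1)),
                                          int(params.get("seed", 0))))
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
    return outputs
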