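"""Seeded generators for fundus-like images and feature tables.

Retinoblastoma presents on fundus photographs as a yellowish-white, textured
lesion inside the bright circular retinal field.  The image generator emulates
exactly that appearance cue — a dark surround, a reddish circular field with
band-limited background texture, and (for the diseased class) one brighter
blob with its own finer texture, returned together with its ground-truth
mask.  Specular light spots (saturated discs) can be added on demand so the
inpainting stage has a known target to restore.

The table generator produces a two-class sample-by-feature matrix in which a
known subset of columns carries a configurable standardized mean shift while
the remaining columns are class-independent noise.  Every generator is
bit-reproducible for a fixed spec.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import CLASS_LABELS, HEALTHY, TUMOR, FeatureTable, LabeledImage

__all__ = [
    "SyntheticImageSpec",
    "SyntheticTableSpec",
    "generate_fundus_image",
    "add_light_spots",
    "generate_image_dataset",
    "generate_feature_table",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic fundus-like image.

    ``fundus_radius_frac`` is the field radius as a fraction of
    ``min(width, height)``; ``tumor_brightness_gain`` multiplies intensities
    inside the lesion; ``texture_scale`` is the correlation length (pixels) of
    the band-limited background texture.
    """

    width: int = 128
    height: int = 128
    fundus_radius_frac: float = 0.45
    background_noise_sigma: float = 8.0
    tumor_radius_range: tuple[int, int] = (8, 16)
    tumor_brightness_gain: float = 1.6
    texture_scale: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("width and height must be >= 32")
        if not 0.0 < self.fundus_radius_frac <= 0.5:
            raise ValueError("fundus_radius_frac must lie in (0, 0.5]")
        if self.background_noise_sigma < 0:
            raise ValueError("background_noise_sigma must be >= 0")
        r_min, r_max = self.tumor_radius_range
        if not 0 < r_min <= r_max:
            raise ValueError("tumor_radius_range must satisfy 0 < min <= max")
        if r_max >= self.fundus_radius_px:
            raise ValueError("tumor_radius_range.max must be smaller than the fundus radius")
        if self.tumor_brightness_gain <= 1.0:
            raise ValueError("tumor_brightness_gain must be > 1")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be > 0")

    @property
    def fundus_radius_px(self) -> float:
        return self.fundus_radius_frac * min(self.width, self.height)


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Parameters of a synthetic two-class feature table.

    ``effect_size`` is the class-mean separation of informative columns in
    units of ``noise_sigma``; ``class_balance`` is the diseased-class
    fraction.
    """

    n_samples: int = 200
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 2.0
    noise_sigma: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("n_informative must satisfy 0 < k <= n_features")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


def _field_texture(rng: np.random.Generator, shape: tuple[int, int], scale: float,
                   sigma: float) -> np.ndarray:
    """Band-limited noise: white noise smoothed at `scale`, rescaled to `sigma`."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma=scale)
    sd = noise.std()
    if sd > 0:
        noise *= sigma / sd
    return noise


def generate_fundus_image(spec: SyntheticImageSpec, label: str) -> LabeledImage:
    """Render one fundus-like image; diseased images carry one bright lesion.

    Deterministic for a fixed ``(spec, label)`` pair.
    """
    if label not in CLASS_LABELS:
        raise ValueError(f"label must be one of {CLASS_LABELS}, got {label!r}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.fundus_radius_px
    dist = np.hypot(rows - cy, cols - cx)
    field = dist <= radius

    # reddish retinal field with a mild radial falloff and band-limited texture
    falloff = 1.0 - 0.3 * (dist / max(radius, 1.0)) ** 2
    texture = _field_texture(rng, (h, w), spec.texture_scale, spec.background_noise_sigma)
    base = np.empty((h, w, 3), dtype=float)
    for ch, level in enumerate((175.0, 85.0, 55.0)):
        base[..., ch] = level * falloff + texture
    surround = 8.0 + 2.0 * rng.standard_normal((h, w, 3))
    img = np.where(field[..., None], base, surround)

    tumor_mask = None
    if label == TUMOR:
        r_min, r_max = spec.tumor_radius_range
        r_t = float(rng.uniform(r_min, r_max))
        # lesion center uniform inside the field, kept fully inside it
        max_off = radius - r_t
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rho = max_off * np.sqrt(rng.uniform())
        ty, tx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
        tumor_mask = np.hypot(rows - ty, cols - tx) <= r_t
        # yellowish-white lesion: brighter, desaturated, with finer texture
        fine = _field_texture(rng, (h, w), spec.texture_scale / 2.0,
                              1.5 * spec.background_noise_sigma)
        lesion = img * spec.tumor_brightness_gain
        lesion[..., 1] += 55.0  # push green up -> yellowish-white
        lesion[..., 2] += 35.0
        lesion += fine[..., None]
        img = np.where(tumor_mask[..., None], lesion, img)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, label=label, tumor_mask=tumor_mask)


def add_light_spots(image: LabeledImage, n_spots: int, spot_radius: int,
                    seed: int = 0) -> tuple[LabeledImage, np.ndarray]:
    """Overlay saturated specular discs inside the fundus field.

    Returns the spotted image and the binary mask of the saturated pixels.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    if spot_radius <= 0:
        raise ValueError("spot_radius must be > 0")
    pixels = image.pixels.copy()
    h, w = pixels.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    if n_spots:
        rng = np.random.default_rng(seed)
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        # keep spots (and a 1-px dilation ring) well inside the fundus field
        field_r = 0.35 * min(h, w) - spot_radius
        for _ in range(n_spots):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rho = max(field_r, 1.0) * np.sqrt(rng.uniform())
            sy, sx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            mask |= np.hypot(rows - sy, cols - sx) <= spot_radius
        pixels[mask] = 255
    spotted = LabeledImage(pixels=pixels, label=image.label,
                           tumor_mask=None if image.tumor_mask is None
                           else image.tumor_mask.copy())
    return spotted, mask


def _derived_seed(dataset_seed: int, index: int) -> int:
    """Counter-based per-item seed, stable across platforms."""
    ss = np.random.SeedSequence([int(dataset_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_image_dataset(spec: SyntheticImageSpec, n_images: int,
                           tumor_fraction: float, seed: int = 0) -> list[LabeledImage]:
    """Generate a labeled dataset with exactly round(n * fraction) diseased images."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    n_tumor = int(round(n_images * tumor_fraction))
    labels = [TUMOR] * n_tumor + [HEALTHY] * (n_images - n_tumor)
    order = np.random.default_rng(seed).permutation(n_images)
    images = []
    for i in order:
        item_spec = dataclasses.replace(spec, seed=_derived_seed(seed, int(i)))
        images.append(generate_fundus_image(item_spec, labels[int(i)]))
    return images


def generate_feature_table(spec: SyntheticTableSpec) -> FeatureTable:
    """Draw a two-class table whose informative columns shift by
    ``effect_size * noise_sigma`` between classes."""
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.n_informative
    n_tumor = int(round(n * spec.class_balance))
    y = np.array([TUMOR] * n_tumor + [HEALTHY] * (n - n_tumor))
    y = y[rng.permutation(n)]
    X = rng.normal(0.0, spec.noise_sigma, size=(n, d))
    informative = np.zeros(d, dtype=bool)
    informative[rng.choice(d, size=k, replace=False)] = True
    shift = spec.effect_size * spec.noise_sigma
    X[np.ix_(y == TUMOR, informative)] += shift
    names = [f"f{j:03d}" for j in range(d)]
    return FeatureTable(X=X, labels=y, feature_names=names, informative_mask=informative)
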