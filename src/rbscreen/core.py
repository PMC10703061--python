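"""Shared data containers for the screening pipeline.

The pipeline moves three kinds of objects between stages: labeled images
(a pixel grid plus a two-class label and, for diseased samples, a ground-truth
lesion mask), per-image feature vectors, and sample-by-feature tables used by
the wrapper feature selector and the evaluators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

HEALTHY = "healthy"
TUMOR = "tumor"
CLASS_LABELS = (HEALTHY, TUMOR)

LABEL_COLUMN = "label"


def _as_pixel_array(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError("pixels must be an HxW grayscale or HxWx3 RGB array")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("pixel intensities must lie in [0, 255]")
    return arr


@dataclass
class LabeledImage:
    """An 8-bit image with its class label and optional lesion mask.

    ``tumor_mask`` is present exactly when ``label == "tumor"`` (it may be
    all-False after e.g. a crop that discards the lesion, but never absent).
    """

    pixels: np.ndarray
    label: str
    tumor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = _as_pixel_array(self.pixels)
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")
        if (self.tumor_mask is not None) != (self.label == TUMOR):
            raise ValueError("tumor_mask must be present iff label == 'tumor'")
        if self.tumor_mask is not None:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
            if self.tumor_mask.shape != self.pixels.shape[:2]:
                raise ValueError("tumor_mask shape must match image spatial shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class FeatureVector:
    """An ordered list of named real-valued features for one sample."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.names = list(self.names)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class FeatureTable:
    """n samples x D features with a two-class label vector.

    ``informative_mask`` is synthetic-only ground truth flagging which columns
    carry class signal; it is None for tables extracted from images.
    """

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = list(self.feature_names)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match number of rows")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match number of columns")
        if self.informative_mask is not None:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape != (self.X.shape[1],):
                raise ValueError("informative_mask must have one entry per column")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV; informative ground truth, when present,
        goes to a ``<stem>.informative.csv`` sidecar listing column names."""
        path = Path(path)
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[LABEL_COLUMN] = self.labels
        df.to_csv(path, index=False)
        if self.informative_mask is not None:
            names = [n for n, m in zip(self.feature_names, self.informative_mask) if m]
            sidecar = path.with_suffix(".informative.csv")
            pd.DataFrame({"informative_feature": names}).to_csv(sidecar, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path)
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"feature CSV must contain a {LABEL_COLUMN!r} column")
        labels = df[LABEL_COLUMN].to_numpy()
        feats = df.drop(columns=[LABEL_COLUMN])
        mask = None
        sidecar = path.with_suffix(".informative.csv")
        if sidecar.exists():
            informative = set(pd.read_csv(sidecar)["informative_feature"])
            mask = np.array([c in informative for c in feats.columns], dtype=bool)
        return cls(feats.to_numpy(dtype=float), labels, list(feats.columns), mask)
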