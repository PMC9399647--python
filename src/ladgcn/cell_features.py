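"""Per-nucleus feature vectors: shape, GLCM texture and a patch descriptor.

Every nucleus contributes 8 shape features (second-moments ellipse axes,
orientation, eccentricity, circularity-style roundness, area, solidity,
perimeter), 4 gray-level co-occurrence texture features (dissimilarity,
homogeneity, angular second moment, energy) and a local patch descriptor
computed on the 64 x 64 window centered on its centroid.  The descriptor
slot is pluggable so a learned patch encoder can be dropped in; the
default is a deterministic 12-float summary (per-channel mean/std plus
coarse 2-level grayscale averages), which also carries a strong local
cell-density signal.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

__all__ = [
    "SHAPE_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "shape_features",
    "texture_features",
    "patch_descriptor",
    "default_descriptor_names",
    "featurize_tile",
    "FeatureNormalizer",
]

SHAPE_FEATURE_NAMES = (
    "major_axis_length",
    "minor_axis_length",
    "orientation",
    "eccentricity",
    "roundness",
    "area",
    "solidity",
    "perimeter",
)
TEXTURE_FEATURE_NAMES = ("dissimilarity", "homogeneity", "asm", "energy")

_GLCM_LEVELS = 32
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def shape_features(instance_mask: np.ndarray) -> np.ndarray:
    """8 shape descriptors of a single binary instance mask.

    Axes, orientation and eccentricity come from the second-moments
    ellipse; roundness is the circularity 4*pi*A/P^2 (clipped to 1 for
    rasterization overshoot); solidity is area over convex-hull area.
    The perimeter is the 4-direction Crofton estimate, which is much
    closer to the true boundary length of rasterized convex shapes than
    the chain-code contour length.
    """
    mask = np.asarray(instance_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty instance mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter_crofton)
    roundness = 1.0 if perimeter <= 0 else min(1.0, 4.0 * np.pi * area / perimeter**2)
    orientation = float(props.orientation)
    if orientation >= np.pi / 2:  # fold the closed endpoint onto [-pi/2, pi/2)
        orientation -= np.pi
    return np.array(
        [
            float(props.axis_major_length),
            float(props.axis_minor_length),
            orientation,
            float(props.eccentricity),
            roundness,
            area,
            float(props.solidity),
            perimeter,
        ]
    )


def texture_features(
    image: np.ndarray,
    instance_mask: np.ndarray,
    angles: tuple[float, ...] = _GLCM_ANGLES,
    levels: int = _GLCM_LEVELS,
) -> np.ndarray:
    """GLCM texture statistics over the instance bounding box.

    Intensities inside the bounding box are min-max quantized to
    ``levels`` gray levels; a symmetric, normalized co-occurrence matrix
    at offset distance 1 is computed per angle and the four statistics
    are averaged over angles.  ``energy = sqrt(ASM)`` by definition.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = rgb2gray(image)
    mask = np.asarray(instance_mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty instance mask")
    patch = image[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    if patch.shape[0] < 2 or patch.shape[1] < 2:
        raise ValueError("instance bounding box must be at least 2x2 px")
    lo, hi = patch.min(), patch.max()
    if hi - lo < 1e-12:
        quant = np.zeros(patch.shape, dtype=np.uint8)
    else:
        quant = np.clip((patch - lo) / (hi - lo) * levels, 0, levels - 1).astype(np.uint8)
    glcm = graycomatrix(quant, [1], list(angles), levels=levels, symmetric=True, normed=True)
    dissimilarity = float(graycoprops(glcm, "dissimilarity").mean())
    homogeneity = float(graycoprops(glcm, "homogeneity").mean())
    asm = float(graycoprops(glcm, "ASM").mean())
    return np.array([dissimilarity, homogeneity, asm, np.sqrt(asm)])


def patch_descriptor(image: np.ndarray, centroid: tuple[float, float], size: int = 64) -> np.ndarray:
    """Default 12-float descriptor of the size x size window at `centroid`.

    Windows clipped by the tile border are zero-padded.  Features:
    per-channel mean and std (6), the four quadrant means of the
    grayscale window (4) and the two Haar-like left-right / top-bottom
    quadrant differences (2).  Intensities are scaled to [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None].repeat(3, axis=2)
    if image.max() > 1.5:
        image = image / 255.0
    h, w = image.shape[:2]
    r0 = int(round(centroid[0])) - size // 2
    c0 = int(round(centroid[1])) - size // 2
    patch = np.zeros((size, size, 3), dtype=np.float64)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        patch[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    means = patch.mean(axis=(0, 1))
    stds = patch.std(axis=(0, 1))
    gray = patch.mean(axis=2)
    half = size // 2
    q = np.array(
        [
            gray[:half, :half].mean(),
            gray[:half, half:].mean(),
            gray[half:, :half].mean(),
            gray[half:, half:].mean(),
        ]
    )
    haar = np.array([(q[0] + q[2]) - (q[1] + q[3]), (q[0] + q[1]) - (q[2] + q[3])])
    return np.concatenate([means, stds, q, haar])


def default_descriptor_names() -> list[str]:
    return (
        [f"patch_mean_{c}" for c in "rgb"]
        + [f"patch_std_{c}" for c in "rgb"]
        + [f"patch_quadrant_{i}" for i in range(4)]
        + ["patch_haar_lr", "patch_haar_tb"]
    )


def featurize_tile(
    image: np.ndarray,
    instance_mask: np.ndarray,
    descriptor: Callable[[np.ndarray, tuple[float, float]], np.ndarray] | None = None,
    descriptor_dim: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and centroid list for every instance in a tile.

    Rows are ordered by ascending label id (row k corresponds to label
    k+1 when labels are contiguous).  Columns are 8 shape + 4 texture +
    descriptor features.  A tile with zero instances yields an empty
    matrix with the correct column count.
    """
    if descriptor is None:
        descriptor = patch_descriptor
    mask = np.asarray(instance_mask)
    gray = rgb2gray(np.asarray(image)) if np.asarray(image).ndim == 3 else np.asarray(image)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    n_cols = len(SHAPE_FEATURE_NAMES) + len(TEXTURE_FEATURE_NAMES) + descriptor_dim
    feats = np.zeros((labels.size, n_cols), dtype=np.float64)
    centroids = np.zeros((labels.size, 2), dtype=np.float64)
    for k, lab in enumerate(labels):
        inst = mask == lab
        rows, cols = np.nonzero(inst)
        centroid = (rows.mean(), cols.mean())
        centroids[k] = centroid
        row = [shape_features(inst)]
        try:
            row.append(texture_features(gray * 255.0, inst))
        except ValueError:  # bounding box thinner than 2 px
            row.append(np.array([0.0, 1.0, 1.0, 1.0]))
        row.append(np.asarray(descriptor(image, centroid), dtype=np.float64))
        feats[k] = np.concatenate(row)
    return feats, centroids


class FeatureNormalizer:
    """Per-column z-score normalization with persistable statistics."""

    def __init__(self, mean: np.ndarray | None = None, std: np.ndarray | None = None):
        self.mean = None if mean is None else np.asarray(mean, dtype=np.float64)
        self.std = None if std is None else np.asarray(std, dtype=np.float64)

    def fit(self, X: np.ndarray) -> "FeatureNormalizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std < 1e-12] = 1.0
        self.std = std
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("normalizer is not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("normalizer is not fitted")
        return np.asarray(X, dtype=np.float64) * self.std + self.mean

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureNormalizer":
        d = json.loads(Path(path).read_text())
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))
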