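"""Polar-ray representation of nucleus contours and a classical fallback segmenter.

An instance footprint is summarised as a center plus the lengths of
``n = 36`` rays cast at 10-degree steps; connecting the 36 ray endpoints
in angular order (starting from 0 degrees) reconstructs the contour.
Geometry uses (x, y) = (col, row): angle 0 points along +x (columns) and
angles increase counter-clockwise in that frame.

`fallback_segment` is a threshold/watershed instance segmenter so the
pipeline runs when no trained nucleus detector (and no ground-truth
mask) is available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "N_RAYS",
    "PolarInstance",
    "encode_polar",
    "decode_polar",
    "polygon_area",
    "fallback_segment",
    "save_polar_instances",
    "load_polar_instances",
]

N_RAYS = 36
_ANGLES = np.deg2rad(10.0 * np.arange(N_RAYS))
_STEP = 0.5  # sub-pixel sampling step along each ray, px


@dataclasses.dataclass
class PolarInstance:
    """Center (row, col) plus 36 non-negative ray lengths in pixels."""

    center: tuple[float, float]
    rays: np.ndarray
    instance_id: int = 0

    def __post_init__(self):
        self.rays = np.asarray(self.rays, dtype=np.float64)
        if self.rays.shape != (N_RAYS,):
            raise ValueError(f"expected {N_RAYS} rays, got shape {self.rays.shape}")
        if not np.all(np.isfinite(self.rays)) or np.any(self.rays < 0):
            raise ValueError("rays must be finite and non-negative")


def encode_polar(
    instance_mask: np.ndarray,
    center: tuple[float, float] | None = None,
    instance_id: int = 0,
) -> PolarInstance:
    """Measure the 36 ray lengths of a binary instance mask.

    Each ray length is the distance to the farthest foreground pixel along
    the ray (sampled every 0.5 px), which tolerates mild non-convexity; it
    is 0 where the center never sees foreground in that direction.
    """
    mask = np.asarray(instance_mask).astype(bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("instance mask must be a 2-D array with >= 1 foreground pixel")
    rows, cols = np.nonzero(mask)
    if center is None:
        center = (rows.mean(), cols.mean())
    cr, cc = float(center[0]), float(center[1])
    h, w = mask.shape
    rmax = float(np.hypot(h, w))
    r = np.arange(0.0, rmax + _STEP, _STEP)
    # (x, y) = (col, row): +x along columns, CCW in that frame
    rr = np.rint(cr + np.sin(_ANGLES)[:, None] * r[None, :]).astype(int)
    cc_idx = np.rint(cc + np.cos(_ANGLES)[:, None] * r[None, :]).astype(int)
    valid = (rr >= 0) & (rr < h) & (cc_idx >= 0) & (cc_idx < w)
    hit = np.zeros_like(valid)
    hit[valid] = mask[rr[valid], cc_idx[valid]]
    lengths = np.where(hit.any(axis=1), r[np.where(hit, np.arange(r.size), -1).max(axis=1)], 0.0)
    return PolarInstance(center=(cr, cc), rays=lengths, instance_id=instance_id)


def decode_polar(
    pi: PolarInstance, out_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the contour polygon and its rasterized mask.

    Returns ``(vertices, mask)`` where ``vertices`` is a (36, 2) array of
    (row, col) polygon vertices in angular order and ``mask`` a boolean
    rasterization.  All-zero rays give an empty mask.
    """
    cr, cc = pi.center
    vr = cr + pi.rays * np.sin(_ANGLES)
    vc = cc + pi.rays * np.cos(_ANGLES)
    vertices = np.stack([vr, vc], axis=1)
    if out_shape is None:
        out_shape = (
            int(np.ceil(vr.max())) + 2 if vr.size else 1,
            int(np.ceil(vc.max())) + 2 if vc.size else 1,
        )
    mask = np.zeros(out_shape, dtype=bool)
    if np.any(pi.rays > 0):
        rr, cc_idx = draw_polygon(vr, vc, shape=out_shape)
        mask[rr, cc_idx] = True
    return vertices, mask


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given (row, col) vertices."""
    v = np.asarray(vertices, dtype=np.float64)
    r, c = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


def fallback_segment(
    image: np.ndarray,
    min_size: int = 20,
    min_peak_distance: int = 7,
    smoothing_sigma: float = 2.0,
) -> np.ndarray:
    """Classical instance segmentation: Otsu + distance-transform watershed.

    Nuclei are assumed darker than background.  Touching nuclei are split
    at the watershed between smoothed distance-transform peaks.  Returns
    an integer label mask (0 = background); may be empty.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    gray = rgb2gray(image)
    if gray.max() - gray.min() < 1e-9:
        return np.zeros(gray.shape, dtype=np.int32)
    fg = gray < threshold_otsu(gray)
    # remove objects below min_size px (max_size is an inclusive threshold)
    fg = remove_small_objects(fg, max_size=min_size - 1)
    if not fg.any():
        return np.zeros(gray.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    dist_s = gaussian(dist, sigma=smoothing_sigma)
    coords = peak_local_max(dist_s, min_distance=min_peak_distance, labels=fg, exclude_border=False)
    if len(coords) == 0:
        return cc_label(fg, connectivity=1).astype(np.int32)
    markers = np.zeros(gray.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist_s, markers, mask=fg)
    # relabel sequentially and drop fragments below the size floor
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() >= min_size:
            out[region] = next_id
            next_id += 1
    return out


def save_polar_instances(instances: list[PolarInstance], path: str | Path) -> None:
    payload = [
        {"id": int(p.instance_id), "center": [p.center[0], p.center[1]], "rays": p.rays.tolist()}
        for p in instances
    ]
    Path(path).write_text(json.dumps(payload))


def load_polar_instances(path: str | Path) -> list[PolarInstance]:
    payload = json.loads(Path(path).read_text())
    return [
        PolarInstance(center=tuple(d["center"]), rays=np.asarray(d["rays"]), instance_id=d["id"])
        for d in payload
    ]
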