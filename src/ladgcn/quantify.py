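"""Slide-level growth-pattern quantification in 5% increments.

A tumor-masked region is cut into tiles, every tile is classified, and
the per-class tile proportions are rounded to the clinical 5% reporting
increments with a largest-remainder scheme so the rounded values always
sum to 100%.  A color-coded class map records the spatial layout of the
predictions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .polar_contour import fallback_segment
from .train_eval import TrainedModel, make_sample

__all__ = ["QuantReport", "tile_region", "round_to_increment", "quantify_slide", "PALETTE"]

#: tile overlay colors: red, green, yellow, blue, cyan, then extras
PALETTE = (
    (255, 0, 0),
    (0, 255, 0),
    (255, 255, 0),
    (0, 0, 255),
    (0, 255, 255),
    (255, 0, 255),
    (255, 128, 0),
    (128, 0, 255),
)


@dataclasses.dataclass
class QuantReport:
    class_names: tuple[str, ...]
    counts: np.ndarray  # tiles per class
    raw_percent: np.ndarray  # counts / total * 100
    rounded_percent: np.ndarray  # multiples of 5 summing to 100
    dominant: str
    class_map: np.ndarray  # H x W x 3 uint8 overlay
    tiles: pd.DataFrame  # row0, col0, pred columns

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_names": list(self.class_names),
            "counts": self.counts.tolist(),
            "raw_percent": self.raw_percent.tolist(),
            "rounded_percent": self.rounded_percent.tolist(),
            "dominant": self.dominant,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def tile_region(
    image: np.ndarray,
    tumor_mask: np.ndarray,
    tile: int = 256,
    stride: int | None = None,
) -> list[tuple[int, int]]:
    """Grid positions (row0, col0) of tiles >= 50% inside the tumor mask.

    Tiles are non-overlapping by default (stride = tile); extents are
    half-open and 0-based.  An empty mask yields zero tiles.
    """
    mask = np.asarray(tumor_mask).astype(bool)
    if mask.shape != np.asarray(image).shape[:2]:
        raise ValueError("tumor mask must match image size")
    stride = stride or tile
    coords = []
    for r0 in range(0, mask.shape[0] - tile + 1, stride):
        for c0 in range(0, mask.shape[1] - tile + 1, stride):
            if mask[r0 : r0 + tile, c0 : c0 + tile].mean() >= 0.5:
                coords.append((r0, c0))
    return coords


def round_to_increment(counts: Sequence[int], increment: int = 5) -> np.ndarray:
    """Largest-remainder rounding of tile counts to percentage increments.

    Works in integer arithmetic on quota units (100/increment per slide),
    so the rounded percentages are exact multiples of the increment and
    always sum to exactly 100.  Remainder ties go to the lower class index.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    if total == 0:
        raise ValueError("no classified tiles to quantify")
    units = 100 // increment
    num = counts * units
    base = num // total
    rem = num % total
    leftover = int(units - base.sum())
    order = sorted(range(counts.size), key=lambda i: (-rem[i], i))
    out = base.copy()
    for i in order[:leftover]:
        out[i] += 1
    return out * increment


def quantify_slide(
    image: np.ndarray,
    tumor_mask: np.ndarray,
    classifier: TrainedModel | Callable[[np.ndarray], int],
    tile: int = 256,
    stride: int | None = None,
    class_names: Sequence[str] | None = None,
    segmenter: Callable[[np.ndarray], np.ndarray] = fallback_segment,
) -> QuantReport:
    """Classify every tumor tile and report 5%-increment proportions.

    ``classifier`` is either a TrainedModel (tiles are segmented with
    ``segmenter`` to build the cell graph — no ground-truth masks exist
    at inference) or any callable mapping a tile image to a class index.
    """
    image = np.asarray(image)
    coords = tile_region(image, tumor_mask, tile=tile, stride=stride)
    if not coords:
        raise ValueError("tumor mask selects zero tiles")
    if isinstance(classifier, TrainedModel):
        names = classifier.class_names
        pipe = classifier.pipeline
        samples = []
        for r0, c0 in coords:
            patch = image[r0 : r0 + tile, c0 : c0 + tile]
            samples.append(
                make_sample(patch, segmenter(patch), k=pipe["k"], d=pipe["d"], image_size=pipe["image_size"])
            )
        preds = classifier.predict(samples)
    else:
        if class_names is None:
            raise ValueError("class_names is required with a callable classifier")
        names = tuple(class_names)
        preds = np.array([int(classifier(image[r0 : r0 + tile, c0 : c0 + tile])) for r0, c0 in coords])
    counts = np.bincount(preds, minlength=len(names))
    raw = 100.0 * counts / counts.sum()
    rounded = round_to_increment(counts)
    class_map = np.zeros((*np.asarray(tumor_mask).shape, 3), dtype=np.uint8)
    for (r0, c0), p in zip(coords, preds):
        class_map[r0 : r0 + tile, c0 : c0 + tile] = PALETTE[p % len(PALETTE)]
    tiles = pd.DataFrame(
        {"row0": [c[0] for c in coords], "col0": [c[1] for c in coords], "pred": [names[p] for p in preds]}
    )
    return QuantReport(
        class_names=names,
        counts=counts,
        raw_percent=raw,
        rounded_percent=rounded,
        dominant=names[int(counts.argmax())],
        class_map=class_map,
        tiles=tiles,
    )


def save_class_map(report: QuantReport, path: str | Path) -> None:
    iio.imwrite(Path(path), report.class_map)
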