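"""Pixel-grid geometry shared by every pipeline stage.

Conventions, fixed once for the whole package:

* images are row-major ``(height, width)`` arrays, origin at the top-left,
  y increasing downward;
* bounding boxes are 0-based and half-open, ``[x1, x2) x [y1, y2)``, so
  ``width = x2 - x1`` and ``area = width * height`` without +1 corrections;
* binary masks are boolean arrays (True = animal foreground) and travel on
  disk as single-channel PNG with 0 = background, 255 = foreground.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import imageio.v3 as iio
import numpy as np
from skimage.measure import label as _sklabel

__all__ = [
    "BBox",
    "Detection",
    "iou",
    "aspect_ratio",
    "crop",
    "connected_components",
    "load_mask",
    "save_mask",
    "read_detections",
    "write_detections",
]


@dataclass(frozen=True, order=True)
class BBox:
    """Half-open axis-aligned pixel box ``[x1, x2) x [y1, y2)``."""

    x1: int
    y1: int
    x2: int
    y2: int

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {self}")
        if min(self.x1, self.y1) < 0:
            raise ValueError(f"negative coordinates in {self}")

    @property
    def width(self) -> int:
        return self.x2 - self.x1

    @property
    def height(self) -> int:
        return self.y2 - self.y1

    @property
    def area(self) -> int:
        return self.width * self.height

    def to_json(self) -> dict:
        return {"x1": self.x1, "y1": self.y1, "x2": self.x2, "y2": self.y2}


@dataclass(frozen=True)
class Detection:
    """One detector output: a box, a confidence, optionally an instance mask.

    ``mask_ref`` points at the instance mask (a path or any identifier the
    caller resolves); ``mask`` may carry the boolean raster directly when the
    detection never touches disk, e.g. straight out of the simulator.
    """

    frame_index: int
    box: BBox
    score: float
    mask_ref: Optional[str] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    def area(self) -> int:
        """Mask foreground count when a mask is attached, else box area."""
        if self.mask is not None:
            return int(np.count_nonzero(self.mask))
        return self.box.area


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def aspect_ratio(box: BBox) -> float:
    """Width over height. Side-view cattle have ratio well above 1."""
    return box.width / box.height


def crop(mask: np.ndarray, box: BBox) -> np.ndarray:
    """Sub-raster of ``mask`` under ``box``; box must lie within bounds."""
    h, w = mask.shape[:2]
    if box.x2 > w or box.y2 > h:
        raise IndexError(f"box {box} exceeds mask bounds {w}x{h}")
    return mask[box.y1 : box.y2, box.x1 : box.x2]


def connected_components(mask: np.ndarray) -> list[tuple[np.ndarray, BBox]]:
    """8-connected foreground components with tight boxes, largest first.

    8-connectivity keeps thin diagonal leg junctions attached to the body,
    so one silhouette stays one component. Returns ``[]`` on empty masks.
    """
    labels = _sklabel(mask, connectivity=2)
    out: list[tuple[np.ndarray, BBox]] = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        ys, xs = np.nonzero(comp)
        box = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        out.append((comp, box))
    out.sort(key=lambda t: -int(np.count_nonzero(t[0])))
    return out


# ---------------------------------------------------------------------------
# wire formats


def load_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG as a boolean mask."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


_FIELDS = ("frame", "x1", "y1", "x2", "y2", "score")


def _det_to_record(d: Detection) -> dict:
    rec = {"frame": d.frame_index, **d.box.to_json(), "score": d.score}
    if d.mask_ref is not None:
        rec["mask"] = d.mask_ref
    return rec


def _record_to_det(rec: dict) -> Detection:
    box = BBox(int(rec["x1"]), int(rec["y1"]), int(rec["x2"]), int(rec["y2"]))
    return Detection(
        frame_index=int(rec["frame"]),
        box=box,
        score=float(rec["score"]),
        mask_ref=rec.get("mask") or None,
    )


def read_detections(path: str | Path) -> list[Detection]:
    """Read detections from JSON-lines or CSV (sniffed by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            return [_record_to_det(row) for row in csv.DictReader(fh)]
    with open(path) as fh:
        return [_record_to_det(json.loads(line)) for line in fh if line.strip()]


def write_detections(dets: Iterable[Detection], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_FIELDS) + ["mask"])
            writer.writeheader()
            for d in dets:
                writer.writerow(_det_to_record(d))
    else:
        with open(path, "w") as fh:
            for d in dets:
                fh.write(json.dumps(_det_to_record(d)) + "\n")
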