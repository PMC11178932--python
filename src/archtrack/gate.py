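"""Post-detector plausibility gates applied before tracking.

Four pure predicates clean up the raw instance segmentations from the lane
camera: a width gate (merged two-animal blobs are too wide, fragments too
narrow), an area gate (humans walking the lane are far smaller than cattle),
an aspect-ratio gate (partially visible animals at the frame edge are taller
than wide), and entrance/exit classification against the two lane thresholds.
Each gate returns the kept detections plus the rejected ones tagged with a
reason, so kept + rejected is always a permutation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .geometry import BBox, Detection, aspect_ratio

__all__ = [
    "GateConfig",
    "Rejection",
    "RoiZone",
    "gate_width",
    "gate_area",
    "gate_aspect",
    "in_roi",
    "apply_gates",
]


@dataclass(frozen=True)
class GateConfig:
    """Thresholds for the detection gates and the lane region of interest.

    Width bounds default to fractions of the frame width (cattle in a
    side-view lane camera span a predictable share of the image); the
    minimum area is tied to ``w_min`` so the config stays scale-free.
    """

    frame_width: int = 1280
    frame_height: int = 720
    w_min: int = 0
    w_max: int = 0
    a_min: int = 0
    tha_left: int = 0
    tha_right: int = 0
    tha_a: float = 1.0
    entrance_edge: str = "x1"  # which box edge is tested at the entrance
    width_on_mask: bool = False  # width gate on mask column extent, not box

    def __post_init__(self) -> None:
        # unset geometry-dependent fields get scale-free defaults
        if self.w_min == 0:
            object.__setattr__(self, "w_min", round(0.15 * self.frame_width))
        if self.w_max == 0:
            object.__setattr__(self, "w_max", round(0.60 * self.frame_width))
        if self.a_min == 0:
            object.__setattr__(self, "a_min", round(0.5 * self.w_min**2))
        if self.tha_left == 0:
            object.__setattr__(self, "tha_left", round(0.15 * self.frame_width))
        if self.tha_right == 0:
            object.__setattr__(self, "tha_right", round(0.92 * self.frame_width))
        if not 0 <= self.tha_left < self.tha_right <= self.frame_width:
            raise ValueError("require 0 <= tha_left < tha_right <= frame_width")
        if not 0 < self.w_min < self.w_max <= self.frame_width:
            raise ValueError("require 0 < w_min < w_max <= frame_width")
        if self.tha_a <= 0:
            raise ValueError("tha_a must be positive")
        if self.entrance_edge not in ("x1", "x2"):
            raise ValueError("entrance_edge must be 'x1' or 'x2'")


@dataclass(frozen=True)
class Rejection:
    detection: Detection
    reason: str


class RoiZone(str, Enum):
    BEFORE_ENTRANCE = "before_entrance"
    INSIDE = "inside"
    BEYOND_EXIT = "beyond_exit"


def _width(det: Detection, cfg: GateConfig) -> int:
    if cfg.width_on_mask and det.mask is not None:
        cols = det.mask.any(axis=0)
        if not cols.any():
            return 0
        import numpy as np

        idx = np.nonzero(cols)[0]
        return int(idx[-1] - idx[0] + 1)
    return det.box.width


def gate_width(
    dets: Sequence[Detection], cfg: GateConfig
) -> tuple[list[Detection], list[Rejection]]:
    """Keep detections with plausible cattle width, ``w_min <= w <= w_max``.

    Over-wide regions are merged multi-animal blobs; under-wide ones are
    fragments or noise.
    """
    kept, rejected = [], []
    for d in dets:
        w = _width(d, cfg)
        if w > cfg.w_max:
            rejected.append(Rejection(d, "too_wide"))
        elif w < cfg.w_min:
            rejected.append(Rejection(d, "too_narrow"))
        else:
            kept.append(d)
    return kept, rejected


def gate_area(
    dets: Sequence[Detection], cfg: GateConfig
) -> tuple[list[Detection], list[Rejection]]:
    """Reject regions smaller than a cattle could be (humans, debris)."""
    kept, rejected = [], []
    for d in dets:
        if d.area() >= cfg.a_min:
            kept.append(d)
        else:
            rejected.append(Rejection(d, "small_area"))
    return kept, rejected


def gate_aspect(
    dets: Sequence[Detection], cfg: GateConfig
) -> tuple[list[Detection], list[Rejection]]:
    """Keep boxes at least ``tha_a`` times wider than tall.

    A silhouette half-clipped by the frame edge loses width but not height,
    so partial animals entering or leaving the lane fail this gate.
    """
    kept, rejected = [], []
    for d in dets:
        if aspect_ratio(d.box) >= cfg.tha_a:
            kept.append(d)
        else:
            rejected.append(Rejection(d, "low_aspect"))
    return kept, rejected


def in_roi(box: BBox, cfg: GateConfig) -> RoiZone:
    """Classify a box against the lane's entrance and exit thresholds."""
    if box.x2 <= cfg.tha_left:
        return RoiZone.BEFORE_ENTRANCE
    if box.x2 >= cfg.tha_right:
        return RoiZone.BEYOND_EXIT
    return RoiZone.INSIDE


def apply_gates(
    dets: Sequence[Detection], cfg: GateConfig
) -> tuple[list[Detection], list[Rejection]]:
    """Width, then area, then aspect gate. Order is immaterial: each gate is
    a pure per-detection predicate."""
    kept, rej = gate_width(dets, cfg)
    kept, rej2 = gate_area(kept, cfg)
    kept, rej3 = gate_aspect(kept, cfg)
    return kept, rej + rej2 + rej3
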