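"""Back-curvature and head-position features from a silhouette crop.

A sound cow walks with a flat back and a steady head; a lame cow arches its
back and bobs its head. Four features capture this from a single binary
silhouette, seven numbers total, in fixed order:

* ``f1`` — head height: vertical distance from the frame top to the topmost
  head pixel, divided by the animal's box height (scale-free head bob cue);
* ``f2`` — background fraction of the strip spanning the top 10% of the
  frame height, restricted to the animal's columns (a raised head/withers
  fills the strip, lowering the value);
* ``f3a..f3c`` — heights of three points sampled on the dorsal profile at
  15%, 50% and 85% of crop width (rear, midriff, head/neck), each divided
  by crop height;
* ``f4a, f4b`` — the two slopes between those points,
  ``(y_p2 - y_p1)/(x_p2 - x_p1)`` and ``(y_p2 - y_p3)/(x_p2 - x_p3)``.
  A flat back gives (0, 0); an arch pushes the midpoint up, driving the
  first slope negative and the second positive, with magnitudes growing
  with arch severity.

Rows are counted downward from the image top, so "higher" anatomy means a
*smaller* y value throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BBox, crop

__all__ = [
    "FeatureError",
    "BackProfile",
    "CurvaturePoints",
    "FeatureVector",
    "FEATURE_NAMES",
    "back_profile",
    "curvature_points",
    "f1",
    "f2",
    "f3",
    "f4",
    "extract_features",
]

FEATURE_NAMES = ("f1", "f2", "f3a", "f3b", "f3c", "f4a", "f4b")

SAMPLE_FRACTIONS = (0.15, 0.50, 0.85)  # rear, midriff, head/neck columns
FALLBACK_FRACTION = 0.05  # empty sample column: search this far for one


class FeatureError(ValueError):
    """Silhouette too degenerate for feature extraction; frame is skipped."""


@dataclass(frozen=True)
class BackProfile:
    """Per-column topmost foreground row of a crop; -1 marks empty columns."""

    top_y: np.ndarray
    width: int
    height: int


@dataclass(frozen=True)
class CurvaturePoints:
    p1: tuple[int, int]
    p2: tuple[int, int]
    p3: tuple[int, int]


@dataclass(frozen=True)
class FeatureVector:
    f1: float
    f2: float
    f3: tuple[float, float, float]
    f4: tuple[float, float]

    def as_tuple(self) -> tuple[float, ...]:
        return (self.f1, self.f2, *self.f3, *self.f4)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def back_profile(silhouette: np.ndarray) -> BackProfile:
    """Topmost foreground row per column (the dorsal line of the animal)."""
    sil = np.asarray(silhouette, bool)
    if not sil.any():
        raise FeatureError("empty silhouette")
    h, w = sil.shape
    any_fg = sil.any(axis=0)
    top = np.where(any_fg, sil.argmax(axis=0), -1)
    return BackProfile(top_y=top.astype(int), width=w, height=h)


def _sample_column(profile: BackProfile, fraction: float) -> int:
    """Column index at ``fraction`` of the width, with a bounded fallback to
    the nearest non-empty column (leg gaps and mask noise should not kill a
    frame)."""
    w = profile.width
    c = min(max(_round_half_away(fraction * w), 0), w - 1)
    if profile.top_y[c] >= 0:
        return c
    radius = max(1, _round_half_away(FALLBACK_FRACTION * w))
    for off in range(1, radius + 1):
        for cand in (c - off, c + off):
            if 0 <= cand < w and profile.top_y[cand] >= 0:
                return cand
    raise FeatureError(f"no foreground within ±{radius} px of column {c}")


def curvature_points(silhouette: np.ndarray) -> CurvaturePoints:
    """The three dorsal-profile points at 15/50/85% of the crop width."""
    profile = back_profile(silhouette)
    cols = [_sample_column(profile, f) for f in SAMPLE_FRACTIONS]
    if not cols[0] < cols[1] < cols[2]:
        raise FeatureError(f"sample columns not increasing: {cols}")
    pts = [(c, int(profile.top_y[c])) for c in cols]
    return CurvaturePoints(*pts)


def f1(frame_mask: np.ndarray, box: BBox, normalize: bool = True) -> float:
    """Head height: frame-top distance of the head-column's topmost pixel.

    The head column is the 85% column of the crop mapped back to frame
    coordinates. Normalized by the animal's box height by default; the raw
    pixel row is available with ``normalize=False``.
    """
    sil = crop(frame_mask, box)
    profile = back_profile(sil)
    c = _sample_column(profile, SAMPLE_FRACTIONS[2])
    frame_row = box.y1 + int(profile.top_y[c])
    return frame_row / box.height if normalize else float(frame_row)


def f2(frame_mask: np.ndarray, box: BBox, strip_fraction: float = 0.10) -> float:
    """Background fraction of the top strip of the frame over the animal's
    columns.

    The strip spans rows ``[0, strip_fraction * frame_height)`` and columns
    ``[x1, x2)``; the value is (# background pixels) / (strip area).
    """
    frame_h = frame_mask.shape[0]
    n_rows = _round_half_away(strip_fraction * frame_h)
    if n_rows < 1:
        raise FeatureError("strip has no rows at this frame height")
    strip = np.asarray(frame_mask[:n_rows, box.x1 : box.x2], bool)
    if strip.shape[1] == 0:
        raise FeatureError("zero-width box")
    return float(np.size(strip) - np.count_nonzero(strip)) / strip.size


def f3(silhouette: np.ndarray) -> tuple[float, float, float]:
    """Dorsal point heights (y_p1, y_p2, y_p3) / crop height."""
    pts = curvature_points(silhouette)
    h = silhouette.shape[0]
    return (pts.p1[1] / h, pts.p2[1] / h, pts.p3[1] / h)


def f4(silhouette: np.ndarray) -> tuple[float, float]:
    """The two dorsal slopes, in pixel units (y down, so an arch makes the
    first slope negative and the second positive)."""
    pts = curvature_points(silhouette)
    (x1_, y1_), (x2_, y2_), (x3_, y3_) = pts.p1, pts.p2, pts.p3
    return ((y2_ - y1_) / (x2_ - x1_), (y2_ - y3_) / (x2_ - x3_))


def extract_features(
    frame_mask: np.ndarray,
    box: BBox,
    strip_fraction: float = 0.10,
    direction: str = "right",
    normalize_f1: bool = True,
) -> FeatureVector:
    """All four features for one frame; raises FeatureError on degenerate
    silhouettes (caller logs and skips the frame).

    ``direction`` states the travel direction; animals walking left are
    mirrored before extraction so the head always sits at the 85% column.
    """
    if direction not in ("right", "left"):
        raise ValueError("direction must be 'right' or 'left'")
    sil = crop(frame_mask, box)
    if direction == "left":
        sil = sil[:, ::-1]
        # mirror the frame columns under the box so f1/f2 see the same geometry
        frame_mask = np.array(frame_mask)
        frame_mask[:, box.x1 : box.x2] = frame_mask[:, box.x1 : box.x2][:, ::-1]
    v1 = f1(frame_mask, box, normalize=normalize_f1)
    v2 = f2(frame_mask, box, strip_fraction=strip_fraction)
    v3 = f3(sil)
    v4 = f4(sil)
    return FeatureVector(f1=v1, f2=v2, f3=v3, f4=v4)
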