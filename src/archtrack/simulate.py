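"""Synthetic side-view walking-cattle silhouettes with ground truth.

Stands in for the farm's lane-camera footage: each animal is a parametric
silhouette (body block, head block, legs) translating left to right through
a 1280x720 frame at ~13 fps. Lameness is expressed exactly where the real
cue lives — the dorsal line: the back profile is a half-sine arch of
amplitude ``arch_amplitude`` (0 = flat back = sound), and the head block
oscillates vertically by ``head_bob_amplitude`` as the gait phase advances
frame by frame. The generator also reproduces the detector's failure modes
that the downstream stages must absorb: dropout spans (frames with no
detection while the animal is plainly visible) and merged blobs (two
overlapping animals reported as one wide region).

Everything is deterministic: silhouettes are pure functions of their
parameters, and the only randomness (per-animal parameter draws and
detection-score jitter) flows from the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage.measure import label as _sklabel

from .geometry import BBox, Detection

__all__ = [
    "SilhouetteParams",
    "AnimalSpec",
    "ScenarioConfig",
    "GroundTruth",
    "SequenceResult",
    "make_silhouette",
    "make_sequence",
    "make_dataset",
]

# layout fractions of the silhouette crop (shared by body/head/leg placement)
_BODY_SPAN = 0.75  # body occupies the left 75% of the crop width
_HEAD_START = 0.72  # head block starts here, overlapping the body for connectivity
_NECK_DEPTH = 0.55  # head block reaches this fraction of body height downward
_LEG_WIDTH = 0.08  # leg bar width as a fraction of the body span

#: gait cycle length in frames at the default 13 fps (slow walk, ~0.6 Hz)
GAIT_PERIOD_FRAMES = 22.0


@dataclass(frozen=True)
class SilhouetteParams:
    """Geometry of one animal's silhouette, in pixels of the full frame.

    Defaults describe a cow filling roughly half of a 1280x720 frame, the
    working scale of the lane camera; tests run the same geometry scaled to
    320x180.
    """

    body_length: int = 560
    body_height: int = 230
    arch_amplitude: float = 0.0
    head_bob_amplitude: float = 0.0
    leg_length: int = 110
    n_legs: int = 4
    gait_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.body_length < 20 or self.body_height < 8 or self.leg_length < 1:
            raise ValueError("silhouette too small to be connected")
        if self.arch_amplitude < 0 or self.head_bob_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def headroom(self) -> int:
        """Rows reserved above the back baseline for arch and head bob."""
        return math.ceil(self.arch_amplitude) + math.ceil(self.head_bob_amplitude) + 1

    @property
    def crop_height(self) -> int:
        return self.headroom + self.body_height + self.leg_length

    @property
    def crop_width(self) -> int:
        return self.body_length


def _round(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_silhouette(p: SilhouetteParams) -> np.ndarray:
    """Render one silhouette crop.

    The back line is ``top0 - a * sin(pi * x / body_span)`` over the body
    span; the head block at the right end sits at
    ``top0 - b * sin(gait_phase)``, so with ``a = b = 0`` the whole top
    profile is a constant row. Legs hang as vertical bars below the belly.
    """
    W, H = p.crop_width, p.crop_height
    top0 = p.headroom
    sil = np.zeros((H, W), dtype=bool)

    span = _round(_BODY_SPAN * W)
    xs = np.arange(span)
    top = top0 - np.floor(p.arch_amplitude * np.sin(np.pi * xs / span) + 0.5).astype(int)
    belly = top0 + p.body_height
    for x in range(span):
        sil[top[x] : belly, x] = True

    bob = _round(p.head_bob_amplitude * math.sin(p.gait_phase))
    head_top = top0 - bob
    hx0 = _round(_HEAD_START * W)
    neck = top0 + _round(_NECK_DEPTH * p.body_height)
    sil[max(head_top, 0) : neck, hx0:W] = True

    leg_w = max(2, _round(_LEG_WIDTH * span))
    for i in range(p.n_legs):
        frac = 0.10 + 0.80 * (i / max(p.n_legs - 1, 1))
        cx = _round(frac * span)
        x0 = max(cx - leg_w // 2, 0)
        sil[belly : belly + p.leg_length, x0 : x0 + leg_w] = True

    if _sklabel(sil, connectivity=2).max() != 1:
        raise ValueError(f"silhouette parameters {p} produce a disconnected mask")
    return sil


@dataclass(frozen=True)
class AnimalSpec:
    entry_frame: int
    speed: float  # px/frame, left-to-right
    params: SilhouetteParams
    lameness_level: int = 1

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.lameness_level not in (1, 2, 3, 4):
            raise ValueError("lameness_level must be 1..4")


@dataclass(frozen=True)
class ScenarioConfig:
    """One lane-camera recording session."""

    frame_width: int = 1280
    frame_height: int = 720
    fps: float = 13.0
    tha_left: int = 0
    tha_right: int = 0
    animals: tuple[AnimalSpec, ...] = ()
    dropout_spans: tuple[tuple[int, int, int], ...] = ()  # (animal, first, last)
    merge_overlaps: bool = False  # overlapping silhouettes detected as one blob
    baseline_fraction: float = 0.12  # back baseline row as fraction of frame height
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tha_left == 0:
            object.__setattr__(self, "tha_left", round(0.15 * self.frame_width))
        if self.tha_right == 0:
            object.__setattr__(self, "tha_right", round(0.92 * self.frame_width))
        entries = [a.entry_frame for a in self.animals]
        if entries != sorted(entries):
            raise ValueError("animal entry frames must be non-decreasing")


@dataclass(frozen=True)
class GroundTruth:
    """Tight boxes and instance masks per frame, plus per-animal labels."""

    per_frame: dict[int, list[tuple[int, BBox, np.ndarray]]]
    lameness_levels: tuple[int, ...]
    visibility_spans: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class SequenceResult:
    frames: dict[int, np.ndarray]  # frame index -> union foreground mask
    detections: list[Detection]
    truth: GroundTruth
    n_frames: int


def _place_animal(
    spec: AnimalSpec, frame_index: int, cfg: ScenarioConfig
) -> Optional[tuple[np.ndarray, BBox]]:
    """Instance mask (frame-sized) and tight box, or None when off-frame."""
    if frame_index < spec.entry_frame:
        return None
    steps = frame_index - spec.entry_frame
    x_left = _round(steps * spec.speed)
    if x_left >= cfg.frame_width:
        return None
    p = replace(
        spec.params,
        gait_phase=spec.params.gait_phase + 2 * math.pi * steps / GAIT_PERIOD_FRAMES,
    )
    sil = make_silhouette(p)
    # anchor the back baseline at a fixed frame row so arch raises the back
    # toward the frame top regardless of the crop's internal headroom
    y_top = _round(cfg.baseline_fraction * cfg.frame_height) - p.headroom
    y_top = max(y_top, 0)
    frame = np.zeros((cfg.frame_height, cfg.frame_width), dtype=bool)
    w_vis = min(sil.shape[1], cfg.frame_width - x_left)
    h_vis = min(sil.shape[0], cfg.frame_height - y_top)
    frame[y_top : y_top + h_vis, x_left : x_left + w_vis] = sil[:h_vis, :w_vis]
    if not frame.any():
        return None
    ys, xs = np.nonzero(frame)
    box = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    return frame, box


def make_sequence(cfg: ScenarioConfig) -> SequenceResult:
    """Render a scenario into frames, detections and ground truth.

    Detections are tight boxes over instance masks; frames inside a dropout
    span emit no detection for that animal while the truth mask persists.
    With ``merge_overlaps`` set, animals whose silhouettes intersect are
    reported as a single union blob, the way a segmentation network fails
    on touching animals.
    """
    rng = np.random.default_rng(cfg.seed)
    dropout = {(a, f) for a, f0, f1 in cfg.dropout_spans for f in range(f0, f1 + 1)}

    per_frame: dict[int, list[tuple[int, BBox, np.ndarray]]] = {}
    frames: dict[int, np.ndarray] = {}
    detections: list[Detection] = []
    first_seen: list[Optional[int]] = [None] * len(cfg.animals)
    last_seen: list[Optional[int]] = [None] * len(cfg.animals)

    def _exit_frame(spec: AnimalSpec) -> int:
        # first frame at which the silhouette's left edge is off-frame
        return spec.entry_frame + math.ceil(cfg.frame_width / spec.speed)

    n_frames = max((_exit_frame(a) for a in cfg.animals), default=0)
    for f in range(n_frames):
        placed = []
        for ai, spec in enumerate(cfg.animals):
            res = _place_animal(spec, f, cfg)
            if res is not None:
                placed.append((ai, res[1], res[0]))
                if first_seen[ai] is None:
                    first_seen[ai] = f
                last_seen[ai] = f
        if not placed:
            continue

        per_frame[f] = placed
        union = np.zeros((cfg.frame_height, cfg.frame_width), dtype=bool)
        for _, _, m in placed:
            union |= m
        frames[f] = union

        visible = [(ai, box, m) for ai, box, m in placed if (ai, f) not in dropout]
        groups: list[list[tuple[int, BBox, np.ndarray]]] = [[v] for v in visible]
        if cfg.merge_overlaps and len(visible) > 1:
            merged: list[list[tuple[int, BBox, np.ndarray]]] = []
            for item in visible:
                hit = None
                for g in merged:
                    if any((item[2] & other[2]).any() for other in g):
                        hit = g
                        break
                (hit.append(item) if hit else merged.append([item]))
            groups = merged
        for g in groups:
            mask = np.zeros_like(union)
            for _, _, m in g:
                mask |= m
            ys, xs = np.nonzero(mask)
            box = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
            score = 0.90 + 0.10 * float(rng.random())
            detections.append(Detection(frame_index=f, box=box, score=score, mask=mask))

    if any(s is None for s in first_seen):
        raise ValueError("an animal never becomes visible in the frame")
    truth = GroundTruth(
        per_frame=per_frame,
        lameness_levels=tuple(a.lameness_level for a in cfg.animals),
        visibility_spans=tuple(
            (fs, ls) for fs, ls in zip(first_seen, last_seen)  # type: ignore[misc]
        ),
    )
    return SequenceResult(
        frames=frames, detections=detections, truth=truth, n_frames=n_frames
    )


# ---------------------------------------------------------------------------
# labelled feature dataset through the full front half of the pipeline


#: reduced working geometry for dataset generation (1/4 of the camera frame)
DATASET_FRAME = (320, 180)
DATASET_SILHOUETTE = dict(body_length=140, body_height=58, leg_length=28)
DATASET_SPEED = 4.0

#: arch-amplitude distribution (px at the reduced scale): sound animals sit
#: at the base mean; the lame mean is ``effect`` within-class SDs above it
ARCH_BASE_MEAN = 2.0
ARCH_SD = 1.5
BOB_RANGE = (1.0, 3.0)  # head-bob amplitude, same draw for both classes


def _animal_samples(
    level: int, arch: float, bob: float, frames_per_animal: int, animal_id: int
):
    """Run one animal through gate -> tracker -> features; labelled rows."""
    from .classify import FrameSample
    from .features import extract_features
    from .gate import GateConfig, apply_gates
    from .tracker import TrackerConfig, TrackerState, finalize, step

    w, h = DATASET_FRAME
    params = SilhouetteParams(
        arch_amplitude=arch, head_bob_amplitude=bob, **DATASET_SILHOUETTE
    )
    cfg = ScenarioConfig(
        frame_width=w,
        frame_height=h,
        animals=(AnimalSpec(0, DATASET_SPEED, params, lameness_level=level),),
        seed=animal_id,
    )
    seq = make_sequence(cfg)
    gate = GateConfig(frame_width=w, frame_height=h)
    tcfg = TrackerConfig(gate=gate)
    state = TrackerState(config=tcfg)
    by_frame: dict[int, list] = {}
    for d in seq.detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    for f in range(seq.n_frames):
        kept, _ = apply_gates(by_frame.get(f, []), gate)
        step(state, kept, f)
    records = finalize(state)
    if not records:
        raise RuntimeError("animal never produced a confirmed transit")
    rows = []
    label = "sound" if level == 1 else "lame"
    for fi, det in records[0].frames:
        vec = extract_features(det.mask, det.box)
        rows.append(
            FrameSample.from_vector(vec, label, animal_id=animal_id, lameness_level=level)
        )
        if len(rows) == frames_per_animal:
            break
    if len(rows) < frames_per_animal:
        raise RuntimeError(
            f"transit yielded {len(rows)} frames, need {frames_per_animal}"
        )
    return rows


def make_dataset(
    n_sound: int,
    n_lame: int,
    frames_per_animal: int = 30,
    effect: float = 4.0,
    seed: int = 0,
) -> list:
    """Labelled frame-feature table from simulated transits.

    Each animal draws an arch amplitude from its class distribution
    (``effect`` = mean separation in units of the within-class SD; 0 makes
    the classes identically distributed) and walks the full pipeline front
    half, so the rows are exactly what the classifier sees in production.
    Returns ``(n_sound + n_lame) * frames_per_animal`` FrameSample rows.
    """
    if n_sound < 1 or n_lame < 1:
        raise ValueError("need at least one animal per class")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    rows: list = []
    animal_id = 0
    for cls, n in (("sound", n_sound), ("lame", n_lame)):
        mean = ARCH_BASE_MEAN + (effect * ARCH_SD if cls == "lame" else 0.0)
        for _ in range(n):
            arch = max(float(rng.normal(mean, ARCH_SD)), 0.0)
            bob = float(rng.uniform(*BOB_RANGE))
            if cls == "sound":
                level = 1
            else:
                level = 2 if rng.random() < 0.75 else 3
            rows.extend(
                _animal_samples(level, arch, bob, frames_per_animal, animal_id)
            )
            animal_id += 1
    return rows
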