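"""Lifetime-gated IoU tracker for lane transits.

Animals walk a single lane left to right past a side-view camera, one or two
at a time. That makes heavyweight multi-object trackers unnecessary: a local
ID is born when an unmatched detection appears at the entrance threshold,
frames are associated to open IDs greedily by IoU against the last seen box,
an unmatched ID is *held* (box frozen, lifetime counter ticking) through
detector dropouts, and the ID is retired either at the exit threshold
(completed transit, exported) or after ``max_life`` consecutive held frames
(lost, discarded). No motion model, no appearance features: at ~13 fps a
walking animal overlaps its previous box by a wide margin, so a permissive
IoU threshold with greedy matching is enough.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .gate import GateConfig
from .geometry import BBox, Detection, crop, iou, save_mask

__all__ = [
    "TrackerConfig",
    "Track",
    "TrackerState",
    "TrackRecord",
    "match_iou",
    "step",
    "finalize",
    "tracking_accuracy",
]


@dataclass(frozen=True)
class TrackerConfig:
    gate: GateConfig
    iou_min: float = 0.30
    max_life: int = 10  # held frames before a silent ID is discarded
    min_life: int = 3  # consecutive hits before a new ID is confirmed
    max_concurrent: int = 2  # lane holds at most this many animals

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_min <= 1.0:
            raise ValueError("iou_min must be in (0, 1]")
        if self.max_life < 1 or self.min_life < 1:
            raise ValueError("max_life and min_life must be >= 1")


@dataclass
class Track:
    """Lifecycle of one local ID.

    ``lifetime`` counts consecutive frames the ID has been held without a
    matching detection (0 while matched); ``hits`` counts consecutive
    matched frames while the ID is still pending confirmation.
    """

    local_id: int
    state: str = "pending"  # pending -> active -> closed | dropped
    last_box: BBox = None  # type: ignore[assignment]
    lifetime: int = 0
    hits: int = 0
    frames: list[tuple[int, Detection]] = field(default_factory=list)

    @property
    def frame_range(self) -> tuple[int, int]:
        return self.frames[0][0], self.frames[-1][0]


@dataclass
class TrackerState:
    config: TrackerConfig
    next_id: int = 1
    open_tracks: list[Track] = field(default_factory=list)
    finished_tracks: list[Track] = field(default_factory=list)
    current_frame: int = -1


def match_iou(
    open_tracks: Sequence[Track], dets: Sequence[Detection], iou_min: float
) -> list[tuple[Track, Detection]]:
    """Greedy one-to-one association on descending IoU.

    Ties break deterministically on (lower local ID, lower detection index).
    Pairs below ``iou_min`` never match.
    """
    scored = []
    for ti, t in enumerate(open_tracks):
        for di, d in enumerate(dets):
            s = iou(t.last_box, d.box)
            if s >= iou_min:
                scored.append((-s, t.local_id, di, ti))
    scored.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for _, _, di, ti in scored:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        pairs.append((open_tracks[ti], dets[di]))
    return pairs


def _entrance_coord(box: BBox, gate: GateConfig) -> int:
    return box.x1 if gate.entrance_edge == "x1" else box.x2


def step(
    state: TrackerState, dets: Sequence[Detection], frame_index: int
) -> list[dict]:
    """Advance the tracker by one frame; returns the event log entries.

    Detections must already have passed the gates. Event kinds: ``created``,
    ``matched``, ``held``, ``closed``, ``dropped``, plus ``ignored`` when a
    fresh entrance candidate would exceed the concurrent-track limit.
    """
    if frame_index <= state.current_frame:
        raise ValueError(
            f"frame_index must increase: got {frame_index} after {state.current_frame}"
        )
    state.current_frame = frame_index
    cfg = state.config
    gate = cfg.gate
    events: list[dict] = []

    pairs = match_iou(state.open_tracks, dets, cfg.iou_min)
    matched_tracks = {id(t) for t, _ in pairs}
    matched_dets = {id(d) for _, d in pairs}

    for t, d in pairs:
        t.last_box = d.box
        t.lifetime = 0
        t.frames.append((frame_index, d))
        if t.state == "pending":
            t.hits += 1
            if t.hits >= cfg.min_life:
                t.state = "active"
        events.append({"frame": frame_index, "event": "matched", "track": t.local_id})

    # unmatched detections at the entrance spawn new pending IDs
    for d in dets:
        if id(d) in matched_dets:
            continue
        if _entrance_coord(d.box, gate) < gate.tha_left:
            if len(state.open_tracks) >= cfg.max_concurrent:
                events.append({"frame": frame_index, "event": "ignored", "x1": d.box.x1})
                continue
            t = Track(local_id=state.next_id, last_box=d.box, hits=1)
            if t.hits >= cfg.min_life:
                t.state = "active"
            t.frames.append((frame_index, d))
            state.next_id += 1
            state.open_tracks.append(t)
            events.append({"frame": frame_index, "event": "created", "track": t.local_id})

    # unmatched open tracks are held with a frozen box; long silence drops them
    for t in state.open_tracks:
        if id(t) in matched_tracks or t.frames[-1][0] == frame_index:
            continue
        t.lifetime += 1
        t.hits = 0  # a gap breaks the pending confirmation streak
        if t.lifetime >= cfg.max_life:
            t.state = "dropped"
            events.append({"frame": frame_index, "event": "dropped", "track": t.local_id})
        else:
            events.append({"frame": frame_index, "event": "held", "track": t.local_id})

    # transit completion: the box's right edge reaches the exit threshold
    for t in state.open_tracks:
        if t.state in ("pending", "active") and t.last_box.x2 >= gate.tha_right:
            t.state = "closed"
            events.append({"frame": frame_index, "event": "closed", "track": t.local_id})

    still_open = [t for t in state.open_tracks if t.state in ("pending", "active")]
    done = [t for t in state.open_tracks if t.state in ("closed", "dropped")]
    state.open_tracks = still_open
    state.finished_tracks.extend(done)
    return events


@dataclass(frozen=True)
class TrackRecord:
    local_id: int
    frames: tuple[tuple[int, Detection], ...]
    frame_range: tuple[int, int]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def finalize(
    state: TrackerState,
    out_dir: str | Path | None = None,
    frame_masks: Optional[dict[int, "np.ndarray"]] = None,  # noqa: F821
) -> list[TrackRecord]:
    """Close out the stream and export one record per completed transit.

    Tracks still active when the stream ends are treated as completed;
    pending (never-confirmed) and dropped tracks export nothing. With
    ``out_dir`` set, each record writes ``ID_<n>/`` holding per-frame binary
    mask crops (when masks are available) and a ``manifest.json``.
    """
    for t in state.open_tracks:
        if t.state == "active":
            t.state = "closed"
        else:
            t.state = "dropped"
        state.finished_tracks.append(t)
    state.open_tracks = []

    records = [
        TrackRecord(t.local_id, tuple(t.frames), t.frame_range)
        for t in state.finished_tracks
        if t.state == "closed"
    ]
    records.sort(key=lambda r: r.local_id)

    if out_dir is not None:
        out_dir = Path(out_dir)
        for rec in records:
            folder = out_dir / f"ID_{rec.local_id}"
            manifest = {
                "local_id": rec.local_id,
                "frame_range": list(rec.frame_range),
                "n_frames": rec.n_frames,
                "boxes": {str(fi): d.box.to_json() for fi, d in rec.frames},
            }
            folder.mkdir(parents=True, exist_ok=True)
            with open(folder / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1, sort_keys=True)
            for fi, d in rec.frames:
                mask = d.mask
                if mask is None and frame_masks is not None:
                    mask = frame_masks.get(fi)
                if mask is None:
                    continue
                try:
                    save_mask(
                        crop(mask, d.box),
                        folder / "binary_mask" / f"frame_{fi:06d}.png",
                    )
                except OSError as exc:  # pragma: no cover - surfaced with context
                    raise OSError(f"writing crop for ID {rec.local_id} frame {fi}") from exc
    return records


def tracking_accuracy(n_correct: int, n_total: int) -> float:
    """Percentage of correctly tracked transits, 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("require 0 <= n_correct <= n_total")
    from .metrics import _round_half_up

    return _round_half_up(100.0 * n_correct / n_total, 2)
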