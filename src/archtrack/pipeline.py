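"""End-to-end orchestration: gate -> track -> features -> classify -> report.

One YAML config drives a run. Input is either a simulated scenario (the
``simulate`` section) or recorded detections plus mask PNGs (``input``
section); output is a per-animal daily report of lameness verdicts, plus
every intermediate artifact (per-ID track folders, features CSV, verdicts
CSV, event log), all stamped with a hash of the effective config so a run
can be reproduced or any stage rerun in isolation from the previous stage's
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .classify import (
    ClassifierSpec,
    TrainedModel,
    aggregate_animal,
    predict_frames,
    train,
)
from .features import FEATURE_NAMES, FeatureError, extract_features
from .gate import GateConfig, apply_gates
from .geometry import Detection, load_mask, read_detections
from .simulate import (
    AnimalSpec,
    ScenarioConfig,
    SilhouetteParams,
    make_dataset,
    make_sequence,
)
from .tracker import TrackerConfig, TrackerState, TrackRecord, finalize, step

__all__ = ["PipelineConfig", "DailyReport", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "archtrack_out"
    seed: int = 0
    simulate: Optional[dict] = None  # scenario description (see _scenario)
    input: Optional[dict] = None  # {"detections": path, "masks_dir": path}
    gate: dict = field(default_factory=dict)
    tracker: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    threshold: float = 0.5

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class DailyReport:
    animals: tuple[dict, ...]  # local_id, n_frames, lame_probability, label
    summary: dict
    config_hash: str

    def to_json(self) -> dict:
        return {
            "animals": list(self.animals),
            "summary": self.summary,
            "config_hash": self.config_hash,
        }


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _scenario(cfg: PipelineConfig) -> ScenarioConfig:
    sim = dict(cfg.simulate or {})
    animals = tuple(
        AnimalSpec(
            entry_frame=a.get("entry_frame", 0),
            speed=a.get("speed", 4.0),
            params=SilhouetteParams(**a.get("silhouette", {})),
            lameness_level=a.get("lameness_level", 1),
        )
        for a in sim.pop("animals", [])
    )
    sim.setdefault("seed", cfg.seed)
    return ScenarioConfig(animals=animals, **sim)


def _gate_config(cfg: PipelineConfig, frame_width: int, frame_height: int) -> GateConfig:
    kw = dict(cfg.gate)
    kw.setdefault("frame_width", frame_width)
    kw.setdefault("frame_height", frame_height)
    return GateConfig(**kw)


def _resolve_model(cfg: PipelineConfig) -> Optional[TrainedModel]:
    section = cfg.classifier
    if not section:
        return None
    if "model" in section:
        return TrainedModel.load(section["model"])
    tr = dict(section.get("train", {}))
    spec = ClassifierSpec(
        algorithm=tr.pop("algorithm", "adaboost"),
        hyperparameters=tr.pop("hyperparameters", {}),
        seed=tr.pop("seed", cfg.seed),
    )
    samples = make_dataset(
        n_sound=tr.pop("n_sound", 12),
        n_lame=tr.pop("n_lame", 12),
        frames_per_animal=tr.pop("frames_per_animal", 20),
        effect=tr.pop("effect", 4.0),
        seed=tr.pop("data_seed", cfg.seed),
    )
    return train(samples, spec)


def run_pipeline(cfg: PipelineConfig) -> DailyReport:
    """Execute the full chain and write all artifacts under ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------- inputs
    if cfg.simulate is not None:
        scen = _scenario(cfg)
        seq = make_sequence(scen)
        dets = seq.detections
        frame_w, frame_h = scen.frame_width, scen.frame_height
        n_frames = seq.n_frames
    elif cfg.input is not None:
        dets = read_detections(cfg.input["detections"])
        masks_dir = Path(cfg.input.get("masks_dir", "."))
        loaded = []
        frame_w = frame_h = 0
        for d in dets:
            mask = load_mask(masks_dir / d.mask_ref) if d.mask_ref else None
            if mask is not None:
                frame_h, frame_w = mask.shape
            loaded.append(
                Detection(d.frame_index, d.box, d.score, mask_ref=d.mask_ref, mask=mask)
            )
        dets = loaded
        if frame_w == 0:
            frame_w = cfg.gate.get("frame_width", 1280)
            frame_h = cfg.gate.get("frame_height", 720)
        n_frames = (max((d.frame_index for d in dets), default=-1)) + 1
    else:
        raise ValueError("config needs either a 'simulate' or an 'input' section")

    # --------------------------------------------------- gate and track
    gate = _gate_config(cfg, frame_w, frame_h)
    tracker_cfg = TrackerConfig(gate=gate, **cfg.tracker)
    state = TrackerState(config=tracker_cfg)
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame_index, []).append(d)

    events_path = out / "events.jsonl"
    rejections_path = out / "rejections.jsonl"
    with open(events_path, "w") as ev_fh, open(rejections_path, "w") as rej_fh:
        for f in range(n_frames):
            kept, rejected = apply_gates(by_frame.get(f, []), gate)
            for r in rejected:
                rej_fh.write(
                    json.dumps(
                        {"frame": f, "reason": r.reason, **r.detection.box.to_json()}
                    )
                    + "\n"
                )
            for e in step(state, kept, f):
                ev_fh.write(json.dumps(e, sort_keys=True) + "\n")
    records = finalize(state, out_dir=out / "tracks")

    # --------------------------------------------------------- features
    fkw = dict(cfg.features)
    strip = fkw.get("strip_fraction", 0.10)
    direction = fkw.get("direction", "right")
    feats: dict[int, list[tuple[int, tuple[float, ...]]]] = {}
    with open(out / "features.csv", "w") as fh, open(out / "skips.jsonl", "w") as skip_fh:
        fh.write("local_id,frame," + ",".join(FEATURE_NAMES) + "\n")
        for rec in records:
            rows = []
            for fi, det in rec.frames:
                if det.mask is None:
                    continue
                try:
                    vec = extract_features(
                        det.mask, det.box, strip_fraction=strip, direction=direction
                    )
                except FeatureError as exc:
                    skip_fh.write(
                        json.dumps(
                            {"local_id": rec.local_id, "frame": fi, "reason": str(exc)}
                        )
                        + "\n"
                    )
                    continue
                rows.append((fi, vec.as_tuple()))
                fh.write(
                    f"{rec.local_id},{fi},"
                    + ",".join(f"{v:.6f}" for v in vec.as_tuple())
                    + "\n"
                )
            feats[rec.local_id] = rows

    # --------------------------------------- classify and aggregate
    model = _resolve_model(cfg)
    animal_rows = []
    for rec in records:
        rows = feats.get(rec.local_id, [])
        entry = {"local_id": rec.local_id, "n_frames": len(rows)}
        if model is not None and rows:
            from .classify import FrameSample

            samples = [FrameSample(r[1], "sound") for r in rows]
            preds = predict_frames(model, samples)
            verdict = aggregate_animal(preds, threshold=cfg.threshold)
            entry["lame_probability"] = round(verdict.lame_probability, 6)
            entry["label"] = verdict.label
        animal_rows.append(entry)

    with open(out / "verdicts.csv", "w") as fh:
        fh.write("local_id,n_frames,lame_probability,label\n")
        for row in animal_rows:
            fh.write(
                f"{row['local_id']},{row['n_frames']},"
                f"{row.get('lame_probability', '')},{row.get('label', '')}\n"
            )

    summary = {
        "n_animals": len(animal_rows),
        "n_lame": sum(1 for r in animal_rows if r.get("label") == "lame"),
        "n_sound": sum(1 for r in animal_rows if r.get("label") == "sound"),
        "seed": cfg.seed,
    }
    report = DailyReport(
        animals=tuple(animal_rows), summary=summary, config_hash=cfg.config_hash()
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
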