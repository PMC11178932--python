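"""Lifetime-gated IoU tracker: hand-traced scenarios and properties."""

import itertools
import json

import pytest

from archtrack import (
    AnimalSpec,
    BBox,
    Detection,
    GateConfig,
    ScenarioConfig,
    SilhouetteParams,
    Track,
    TrackerConfig,
    TrackerState,
    apply_gates,
    finalize,
    make_sequence,
    match_iou,
    step,
    tracking_accuracy,
)
from archtrack.geometry import iou

GATE = GateConfig(frame_width=1000, frame_height=500, w_min=50, w_max=400,
                  a_min=2000, tha_left=200, tha_right=900)


def cfg(**kw):
    kw.setdefault("gate", GATE)
    return TrackerConfig(**kw)


def det(frame, x1, y1=100, w=150, h=100):
    return Detection(frame, BBox(x1, y1, x1 + w, y1 + h), 1.0)


def run(config, frames):
    """Feed per-frame detection lists; return (state, events)."""
    state = TrackerState(config=config)
    events = []
    for f, dets in enumerate(frames):
        events.extend(step(state, dets, f))
    return state, events


class TestHandTraces:
    def test_single_transit_three_frames(self):
        """One animal entering before the left threshold: exactly one ID,
        created at frame 0, matched on the next two frames."""
        frames = [[det(0, 50)], [det(1, 80)], [det(2, 110)]]
        state, events = run(cfg(min_life=1), frames)
        kinds = [(e["frame"], e["event"]) for e in events]
        assert kinds == [(0, "created"), (1, "matched"), (2, "matched")]
        assert state.open_tracks[0].local_id == 1
        assert state.next_id == 2

    def test_drop_after_max_life_then_new_id(self):
        """10 consecutive undetected frames retire the ID; a reappearing
        detection afterwards gets a fresh ID."""
        frames = [[det(0, 50)], [det(1, 80)], [det(2, 110)]]
        frames += [[] for _ in range(10)]  # silence: held x9, dropped on 10th
        c = cfg(min_life=1, max_life=10)
        state, events = run(c, frames)
        drops = [e for e in events if e["event"] == "dropped"]
        assert [e["frame"] for e in drops] == [12]
        held = [e for e in events if e["event"] == "held"]
        assert len(held) == 9
        # reappearance near the entrance spawns ID 2, never resurrects ID 1
        ev = step(state, [det(13, 110)], 13)
        assert ev == [{"frame": 13, "event": "created", "track": 2}]

    def test_dropout_shorter_than_max_life_keeps_id(self):
        frames = [[det(0, 50)], [det(1, 80)]]
        frames += [[] for _ in range(9)]  # 9 held frames < max_life = 10
        frames += [[det(11, 80)]]  # frozen box still overlaps -> same ID
        state, events = run(cfg(min_life=1, max_life=10), frames)
        assert not [e for e in events if e["event"] == "dropped"]
        assert state.next_id == 2
        assert state.open_tracks[0].frames[-1][0] == 11

    def test_exit_closes_and_never_reopens(self):
        # 150 px steps with 300 px boxes keep IoU = 0.33 >= iou_min
        frames = [[det(f, 50 + 150 * f, w=300)] for f in range(5)]
        # frame 4: x2 = 650 + 300 = 950 >= tha_right -> closed
        state, events = run(cfg(min_life=1), frames)
        assert events[-1] == {"frame": 4, "event": "closed", "track": 1}
        assert state.open_tracks == []
        # a detection to its right cannot re-open the track (and is not at
        # the entrance, so no new ID either)
        ev = step(state, [det(5, 700, w=250)], 5)
        assert ev == []
        assert state.next_id == 2

    def test_entrance_condition_required_for_new_id(self):
        """A detection appearing mid-lane (x1 >= tha_left) is a detector
        artifact, not an entering animal: no ID is created."""
        state, events = run(cfg(min_life=1), [[det(0, 400)]])
        assert events == []
        assert state.open_tracks == []

    def test_pending_confirmation_min_life(self):
        frames = [[det(0, 50)], [det(1, 80)], [det(2, 110)]]
        state, _ = run(cfg(min_life=3), frames)
        assert state.open_tracks[0].state == "active"
        state2, _ = run(cfg(min_life=3), frames[:2])
        assert state2.open_tracks[0].state == "pending"

    def test_concurrent_limit(self):
        d1 = det(0, 10, y1=50)
        d2 = det(0, 10, y1=300)
        d3 = det(0, 30, y1=180, w=60, h=40)
        state, events = run(cfg(min_life=1, max_concurrent=2), [[d1, d2, d3]])
        assert sum(e["event"] == "created" for e in events) == 2
        assert sum(e["event"] == "ignored" for e in events) == 1

    def test_non_monotone_frame_index_rejected(self):
        state, _ = run(cfg(), [[det(0, 50)]])
        with pytest.raises(ValueError):
            step(state, [], 0)


class TestMatchIoU:
    def track(self, tid, x1, y1=100, w=150, h=100):
        return Track(local_id=tid, last_box=BBox(x1, y1, x1 + w, y1 + h))

    def test_simple_match_and_no_match(self):
        t = self.track(1, 100)
        d_close = det(0, 110)
        d_far = det(0, 700)
        assert match_iou([t], [d_close], 0.3) == [(t, d_close)]
        assert match_iou([t], [d_far], 0.3) == []

    @pytest.mark.parametrize("n_tracks,n_dets", [(2, 2), (3, 3), (3, 2)])
    def test_greedy_equals_enumeration_oracle(self, n_tracks, n_dets):
        """Greedy result equals explicit greedy enumeration over all pairs
        with distinct IoUs."""
        tracks = [self.track(i + 1, 100 * i + 10, y1=100 + 7 * i) for i in range(n_tracks)]
        dets = [det(0, 100 * j + 40, y1=100 + 11 * j) for j in range(n_dets)]
        got = match_iou(tracks, dets, 0.01)
        # oracle: repeatedly pick the globally best remaining pair
        remaining = [
            (iou(t.last_box, d.box), ti, di)
            for ti, t in enumerate(tracks)
            for di, d in enumerate(dets)
            if iou(t.last_box, d.box) >= 0.01
        ]
        expected = []
        used_t, used_d = set(), set()
        for s, ti, di in sorted(remaining, key=lambda x: (-x[0], x[1], x[2])):
            if ti not in used_t and di not in used_d:
                used_t.add(ti)
                used_d.add(di)
                expected.append((tracks[ti], dets[di]))
        assert set((id(t), id(d)) for t, d in got) == set(
            (id(t), id(d)) for t, d in expected
        )

    def test_one_to_one(self):
        tracks = [self.track(1, 100), self.track(2, 120)]
        d = det(0, 110)
        pairs = match_iou(tracks, [d], 0.1)
        assert len(pairs) == 1


def simulate_and_track(scen, tracker_cfg=None):
    seq = make_sequence(scen)
    gate = GateConfig(frame_width=scen.frame_width, frame_height=scen.frame_height)
    tcfg = tracker_cfg or TrackerConfig(gate=gate)
    state = TrackerState(config=tcfg)
    by_frame = {}
    for d in seq.detections:
        by_frame.setdefault(d.frame_index, []).append(d)
    events = []
    for f in range(seq.n_frames):
        kept, _ = apply_gates(by_frame.get(f, []), gate)
        events.extend(step(state, kept, f))
    return state, events, seq


SMALL = SilhouetteParams(body_length=140, body_height=58, leg_length=28)


class TestOnSyntheticTransits:
    def test_id_conservation_two_transits(self, tmp_path):
        """Two animals separated in time: exactly two IDs, two exported
        folders, no switches."""
        scen = ScenarioConfig(
            frame_width=320,
            frame_height=180,
            animals=(AnimalSpec(0, 8, SMALL), AnimalSpec(60, 8, SMALL)),
        )
        state, events, seq = simulate_and_track(scen)
        records = finalize(state, out_dir=tmp_path)
        assert [r.local_id for r in records] == [1, 2]
        assert sorted(p.name for p in tmp_path.iterdir()) == ["ID_1", "ID_2"]
        manifest = json.loads((tmp_path / "ID_1" / "manifest.json").read_text())
        assert manifest["n_frames"] == len(records[0].frames)
        assert (tmp_path / "ID_1" / "binary_mask").exists()

    @pytest.mark.parametrize("gap,expect_ids", [(5, 1), (9, 1), (10, 2), (12, 2)])
    def test_dropout_threshold_splits_id(self, gap, expect_ids):
        """Dropout < max_life never splits an ID; >= max_life always does
        (while the animal is still in the entrance zone, where a new ID can
        legally be born)."""
        scen = ScenarioConfig(
            frame_width=320,
            frame_height=180,
            tha_left=80,
            animals=(AnimalSpec(0, 4, SMALL),),
            dropout_spans=((0, 1, gap),),  # frames 1..gap emit no detection
        )
        gate = GateConfig(frame_width=320, frame_height=180, tha_left=80)
        state, events, _ = simulate_and_track(
            scen, TrackerConfig(gate=gate, min_life=1)
        )
        created = [e for e in events if e["event"] == "created"]
        assert len(created) == expect_ids
        dropped = [e for e in events if e["event"] == "dropped"]
        assert len(dropped) == (1 if expect_ids == 2 else 0)

    def test_determinism_byte_identical_events(self):
        scen = ScenarioConfig(
            frame_width=320, frame_height=180, animals=(AnimalSpec(0, 6, SMALL),), seed=5
        )
        logs = []
        for _ in range(2):
            _, events, _ = simulate_and_track(scen)
            logs.append("\n".join(json.dumps(e, sort_keys=True) for e in events))
        assert logs[0] == logs[1]

    def test_lifetime_bound(self):
        scen = ScenarioConfig(
            frame_width=320,
            frame_height=180,
            animals=(AnimalSpec(0, 4, SMALL),),
            dropout_spans=((0, 2, 40),),
        )
        state, _, _ = simulate_and_track(scen)
        for t in state.open_tracks + state.finished_tracks:
            assert t.lifetime <= state.config.max_life


class TestFinalize:
    def test_empty_stream(self, tmp_path):
        state = TrackerState(config=cfg())
        assert finalize(state, out_dir=tmp_path) == []
        assert not any(p.is_dir() for p in tmp_path.iterdir())

    def test_dropped_pending_absent(self):
        state, _ = run(cfg(min_life=5, max_life=2), [[det(0, 50)], [], []])
        assert finalize(state) == []


class TestTrackingAccuracy:
    @pytest.mark.parametrize(
        "correct,total,expected", [(63, 64, 98.44), (7, 7, 100.00), (0, 5, 0.00)]
    )
    def test_values(self, correct, total, expected):
        assert tracking_accuracy(correct, total) == expected

    def test_zero_total(self):
        with pytest.raises(ValueError):
            tracking_accuracy(0, 0)
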