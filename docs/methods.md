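# Methods

This note documents the models, conventions and design decisions behind
`archtrack`, in the order the pipeline runs.

## Coordinate and mask conventions

Images are row-major `(height, width)` arrays with the origin at the
top-left and y increasing downward, so "higher" anatomy means a smaller
row index. Bounding boxes are 0-based and half-open,
`[x1, x2) × [y1, y2)`: widths, heights and areas are plain differences
with no +1 corrections, and IoU is exactly the pixel-set
intersection-over-union under this interpretation (verified against
brute-force pixel enumeration in the tests). Masks are boolean in memory
and 0/255 single-channel PNG on disk. Connected components use
8-connectivity: side-view silhouettes have thin, often diagonal leg/body
junctions, and 4-connectivity would split one animal into body and leg
fragments.

Anyone comparing raw pixel counts against a pipeline using inclusive
boxes should expect off-by-one differences in widths and areas; the
half-open convention was chosen for arithmetic cleanliness, as no
convention is canonical for this kind of data.

## Detection gates

Each gate is a pure per-detection predicate, so gate order is immaterial
and `kept + rejected` is always a permutation of the input. The width
gate keeps `w_min ≤ width ≤ w_max` (box width by default; mask column
extent behind `width_on_mask` for pipelines whose boxes are loose). The
area gate keeps `area ≥ a_min`, with area the mask foreground count when
a mask is attached and the box area otherwise. The aspect gate keeps
`width/height ≥ tha_a`.

No published values exist for these thresholds — they are farm- and
camera-specific — so the defaults are scale-free fractions of the frame
width calibrated on the synthetic herd: `w_min = 0.15·W_frame`,
`w_max = 0.60·W_frame`, `a_min = 0.5·w_min²`, `tha_a = 1.0`,
`tha_left = 0.15·W_frame`, `tha_right = 0.92·W_frame`. At the default
silhouette scale (an animal spanning ~44 % of the frame width) a single
animal passes all gates, a two-animal union blob with ≥ 40 % overlap
fails the width gate, and an upright human silhouette fails the area
gate. Entrance/exit classification is evaluated on the box's right edge
`x2` by default (the exit rule is defined on `x2`; the entrance test is
configurable to `x1` via `entrance_edge`, and track *creation* uses `x1`
— see below).

## Tracker

The tracker is deliberately minimal: at ~13 fps a walking cow overlaps
its previous box by a wide margin, so greedy one-to-one association on
descending IoU with a permissive threshold (`iou_min = 0.30`) is
sufficient, and no motion model or appearance feature is used. Ties break
deterministically (lower local ID, then lower detection index), which
makes event logs byte-identical across reruns.

Per frame, in order: (1) match detections to open tracks; (2) matched
tracks update their box, reset their lifetime and append the frame;
(3) unmatched detections with `x1 < tha_left` — an animal appearing at
the entrance — create a pending track with a fresh, strictly increasing
local ID; (4) unmatched tracks are *held*: box frozen, lifetime
incremented, and at `lifetime = MAX_LIFE` the ID is dropped;
(5) any track whose `x2 ≥ tha_right` is closed as a completed transit.
`MAX_LIFE = 10` frames. A pending track is confirmed (becomes active)
after `MIN_LIFE = 3` consecutive hits; a gap resets the streak. This
confirmation gate exists to suppress one-frame ghost detections near the
entrance; 3 frames is short against a typical 30+-frame transit. At most
`max_concurrent = 2` tracks may be open (the lane physically holds one or
two animals); excess entrance candidates are logged and ignored.

End-of-stream handling: tracks still *active* when the stream ends are
closed and exported (the recording simply stopped mid-transit); pending
and dropped tracks export nothing. Exported records become per-ID folders
with binary-mask crops and a manifest.

Consequences verified by the tests: a dropout shorter than `MAX_LIFE`
never splits an ID; a dropout of `MAX_LIFE` or longer always retires the
ID, and the reappearing animal receives a new one only while it is still
in the entrance zone — an animal reappearing mid-lane stays untracked,
which is the conservative choice for a screening system (a missed transit
rather than a corrupted one).

## Features

The crop is taken from the animal's tight box; travel direction is
head-right, and a `direction: left` flag mirrors the crop first. Dorsal
sample columns sit at 15/50/85 % of the crop width
(round-half-away-from-zero, clamped), with a fallback to the nearest
populated column within ±5 % of the width so leg gaps or mask noise do
not discard a frame; beyond that the frame is skipped with a logged
reason (this also covers head-overlapping-body postures, which produce
degenerate profiles).

Two interpretation decisions worth flagging. First, `F1` is normalized by
the animal's box height — the raw head-row value varies with animal size
and is available behind `normalize=False`. The head-top distance is
measured from the *frame* top, not the crop top (the crop-top distance of
the silhouette's highest point is 0 by construction whenever the head is
highest, which would destroy the signal). Second, the `F2` strip spans
the top 10 % of the *frame* height but is restricted to the animal's box
columns: a full-width strip would be dominated by background and by any
second animal in frame. Its value is the background fraction of that
strip, in [0, 1].

`F3`/`F4` depend only on crop geometry, so they are invariant to x/y
translation of the animal in the frame; `F1`/`F2` deliberately are not
(they carry the head-height signal). All seven values are finite on every
non-degenerate frame, with `F2`, `F3` bounded in [0, 1].

## Classification and aggregation

Frame-level binary classification (sound = locomotion level 1, lame =
levels 2–3; the single level-4 animal class is excluded from the binary
task by default) over the 7-number vector, with five classical learners
behind one interface: SVC (RBF), random forest, decision tree, AdaBoost,
SGD (hinge). No published hyperparameters exist, so library defaults are
used, seeded, and embedded in the saved model artifact. SVM and SGD are
wrapped with a standard scaler — margin-based learners need comparable
feature scales; tree ensembles are scale-free and run raw. Learners
without calibrated probabilities expose a logistic squash of their
decision margin so every model emits a [0, 1] lame-score.

The per-animal verdict is the mean frame score across the transit against
a 0.5 threshold. Averaging across ~30 frames suppresses single-frame
segmentation noise; the verdict is invariant to frame order.

Two splits are provided and they answer different questions: the default
seeded stratified *per-frame* split (fraction 690/1031) benchmarks frame
classification on a mixed pool, while `split_by_animal` keeps whole
transits on one side — the correct protocol for claiming generalization
to unseen animals, and the one used in the parameter-recovery tests
(per-frame splits leak animal identity: frames of the same animal are
nearly identical, so any memorizing learner scores near 100 % regardless
of signal).

## Evaluation arithmetic

Precision `100·TP/(TP+FP)` and recall `100·TP/(TP+FN)`, both to 2
decimals (round-half-up); TN is carried for sheet compatibility but
enters neither. `detection_accuracy` defaults to `TP/(TP+FP+FN)` — the
natural definition without true negatives — and offers a `sheet_compat`
mode that returns precision, reproducing evaluation sheets whose accuracy
column duplicates precision even when misses are present. Macro-averages
support both rounding and truncation because published summary
percentages follow one or the other depending on the table; the
acceptance script pins the mode per quantity. One bundled tracking-sheet
row (61/62) is printed truncated while its neighbours are rounded; the
package rounds consistently and the tests document the 0.01 discrepancy
on that row.

## Synthetic herd

The simulator emulates exactly the degrees of freedom the features read.
A silhouette is a body block whose top line is
`top0 − a·sin(π·x/body_span)` (half-sine arch, amplitude `a` in px; the
field's "arched back" is not formalized anywhere, and a single-amplitude
arch makes monotonicity properties well-defined), a head block at the
right end displaced vertically by `b·sin(gait_phase)` with the phase
advancing over a 22-frame gait cycle (~0.6 Hz at 13 fps), and four leg
bars. With `a = b = 0` the top profile is a constant row, so a sound
animal yields `F4 = (0, 0)` exactly. Silhouettes are anchored so the back
*baseline* sits at 12 % of the frame height regardless of arch: an arch
raises the mid-back toward the frame top, which is what makes `F2`
informative.

Transits translate left-to-right at constant speed through a 1280×720
frame (tests and dataset generation use the same geometry at 320×180 for
speed); detections are tight boxes over the instance masks with seeded
score jitter. Dropout spans omit detections while truth persists; with
`merge_overlaps`, intersecting silhouettes are emitted as a single union
blob, reproducing the segmentation failure on touching animals.

`make_dataset` drives each simulated animal through the real gate →
tracker → feature chain (not a shortcut around it). Per animal, the arch
amplitude is drawn from N(2.0, 1.5²) px for sound and
N(2.0 + effect·1.5, 1.5²) for lame (clipped at 0), so `effect` is the
class separation in within-class SD units and `effect = 0` makes the
classes identically distributed; head-bob amplitude is drawn U(1, 3)
identically for both classes, leaving arch as the single lameness knob.
Default problem sizes — 20–36 animals, 20–30 frames per transit — keep
the full suite and the acceptance script in the tens of seconds while
giving the statistical tests stable bands.

What the simulator does *not* model: texture and lighting, occlusion
other than full dropout, perspective/size change along the lane,
non-constant walking speed, stride-phase coupling between arch and bob,
and real segmentation noise at the mask boundary. Passing tests therefore
demonstrate that the pipeline's logic is correct and that the features
separate the geometric cue they were designed for — not that the system
reaches any particular accuracy on farm video.

## Known limitations

* The tracker has no re-identification: an ID lost mid-lane is gone.
* Merged blobs are discarded, not split; simultaneous transits that touch
  for their whole overlap window lose both animals' frames (the gates log
  every rejection so such sessions are auditable).
* Features assume a single animal per crop and a roughly horizontal
  posture; steep lanes or head-down grazing postures would need a
  recalibrated strip fraction and sample columns.
* The classifier stack is frame-independent; no temporal model (gait
  periodicity) is exploited beyond the mean-score aggregation.
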