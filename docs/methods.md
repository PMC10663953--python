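# Methods

## The problem

Phenotyping individual locomotion in a group pen requires a persistent
identity per bird. In tracking-by-detection, a per-frame detector proposes
bounding boxes and a tracker links them across frames; every linking error
either switches a bird's identity to another track (ID-switch) or drops it
altogether (ID-loss). This package implements the tracker, the evaluation
metrics that quantify those errors against sparse human-annotated
trajectories, and the circumstance analysis that asks where and why tracks
die — together with a pen simulator that generates inputs with the error
structure the analysis assumes.

## Tracker

The tracker is the classic SORT recipe. State per track:
x = [x, y, s, r, ẋ, ẏ, ṡ]ᵀ with box center (x, y), area s, aspect ratio r;
r carries no velocity and is constant under prediction. The motion model is
linear constant velocity: F is the identity with unit couplings from
(x, y, s) to their velocities. Measurements are the (x, y, s, r) of a
detected box; detection confidence is carried as metadata only, since a
linear measurement matrix H cannot map a state containing (s, r) onto a
(w, h, c) measurement. Association maximises total IOU between detections
and predicted boxes via `scipy.optimize.linear_sum_assignment`; assigned
pairs under the gate (IOU < 0.3) dissolve into unmatched on both sides.

Lifecycle: unmatched detections seed tentative tracks with zero velocities;
a track is emitted only while it was updated this frame and its
`hit_streak` (consecutive matches) is at least `min_hits = 3`, except during
the first `min_hits` frames of a run (avoiding a dead zone at sequence
start); `hit_streak` resets to zero after any missed frame; tracks die when
unmatched for more than `max_age = 1` frame. Track IDs are positive and
never reused.

Numeric constants (all configurable): R = diag(1, 1, 10, 10),
P₀ = diag(10, 10, 10, 10, 10⁴, 10⁴, 10⁴),
Q = diag(1, 1, 1, 1, 0.01, 0.01, 10⁻⁴) — the widely used reference values
for this tracker family; the large initial velocity variances encode that
velocities are unobservable from a single detection. If a prediction would
drive the area non-positive, the area velocity is zeroed first. Determinism:
detections are sorted by (left, top) before assignment so ties resolve
identically on every run.

## Tracking evaluation

Ground truth is sparse: trajectories annotated every `eval_interval` frames
(1,500 frames ≈ 1 min at 25 fps in the motivating study; tests and examples
use smaller intervals at desk scale). Matching predicted IDs to ground-truth
birds is done per evaluation frame by Hungarian assignment, but the cost of
a (bird, ID) pair is the product of the frame IOU (gated at ≥ 0.5) and a
trajectory-level **global alignment score** — the Jaccard count
c/(T_g + T_p − c), where c is the number of evaluation frames in which the
pair overlaps above the gate and T_g, T_p their numbers of appearance
frames. The weighting makes ambiguous frames resolve toward the ID that
covers the trajectory overall, keeping the association temporally
consistent.

From the association table:

- **ID-switches**: changes of the associated ID along a trajectory,
  scanning evaluation frames in order. Unmatched frames neither count as a
  switch nor change the remembered ID — losses are analysed separately, and
  an annotated bird briefly unmatched then re-matched to the same ID has
  suffered no identity error.
- **Tracklets**: maximal runs of consecutive evaluation frames with one
  associated ID. Unmatched frames terminate a run (without counting a
  switch). A run of k frames lasts k × interval minutes, so a single-frame
  tracklet lasts one minute by definition. Distance is the summed
  displacement of ground-truth centers within the run, converted to meters;
  the predicted-center displacement is reported alongside so the offset
  between track and bird can be inspected.

## Detection evaluation

Within a frame, predictions at or above the confidence threshold are
matched one-to-one to ground truth by Hungarian assignment on IOU
(the matcher is a design choice — it is consistent with the one-to-one
matching used everywhere else in the package); assigned pairs with
IOU ≥ τ are TP, leftover predictions FP, unmatched ground truth FN.
Precision and recall use the convention 0/0 → 1. AP sweeps the threshold
over every distinct observed confidence, takes the best precision at each
recall level, enforces a non-increasing envelope from the right, and
integrates rectangles over recall (all-point interpolation — the common
modern choice). The F1-maximizing threshold is selected among observed
confidences, ties broken toward the higher threshold.

## ID-loss analysis

An ID-loss is a track ID present in frame t−1 and absent in frame t,
scanned at full frame rate; an ID lost, re-appearing and lost again counts
once per loss. Frames listed as excluded (e.g. lighting glitches) are
skipped entirely — transitions into or out of them are not counted; the
list is empty by default.

Each event records the track's last box, the ID's total lifetime
(frames present / fps; the lifetime filter keeps IDs that existed ≥ 1 s),
whether the last center lies in the drinker rectangle (closed boundaries),
the nearest-neighbor distance among the other detections of the last frame,
proximity class (close ≤ 59 px = one mean broiler radius = 13.5 cm;
proximate ≤ 128 px ≈ 29 cm), the number of close neighbors, and kinematics.
Velocity uses the positions 1 s apart ending at the frame before the loss;
acceleration uses the two consecutive 1-s velocity vectors before it;
events without enough track history get no kinematics and are counted as
dropped. The drinker region defaults to a 0.30 × 0.30 m square at the
midpoint of one long wall (the simulator's drinker; for real data it is a
config rectangle).

The no-loss comparison group is sampled, by default, from the surviving
tracks of exactly the frames where a loss occurred; neither the lost IDs
nor the record's own track count as neighbor candidates, so only distances
that did *not* lead to a loss enter the baseline. A flag switches to
every-frame sampling for sensitivity analysis — the two readings differ
only in the denominator of the baseline, not in any event.

Heatmaps bin last-loss locations (and, for occupancy, all detections
sampled at 1 fps) into a count grid; cell counts always sum to the number
of points.

## The simulator

The simulator emulates the study conditions: 39 birds in a 1.80 × 2.61 m
pen at 25 fps (scale 437 px/m, i.e. a ~787 × 1141 px floor), bird bounding
boxes fixed squares of two broiler radii (118 px) per side.

Motion is a per-bird two-state Markov process in continuous 2-D:

- idle → moving at 0.02 s⁻¹ (mean idle bout ~50 s — broilers at this age
  are predominantly inactive), moving → idle at 0.5 s⁻¹ (bursts of ~2 s);
- burst speed ~ N(0.15, 0.05²) m/s, clipped positive and capped at
  mean + 3 sd (the cap is also the invariant tests check);
- heading persistence 0.8 (small Gaussian heading increments while moving);
- drinker visits at 0.3 min⁻¹ per bird: the bird walks to the drinker,
  drinks for an exponential dwell (mean 10 s), then resumes. These rates
  put roughly one bird at the drinker at any time for a 10-bird pen —
  enough traffic for the drinker to be the occlusion hotspot without
  crowding the zone;
- bird-bird overlap is allowed (broilers occlude each other); a soft
  repulsion keeps full coincidence rare. `min_separation_px` optionally
  enforces hard separation (used by the clean, occlusion-free scenarios).

The detection corrupter drops each box with probability `p_miss` (default
0.02; `p_miss_drinker` = 0.5 inside the drinker rectangle, where the
hardware occludes birds), jitters survivor centers and sizes with
σ = 2 px, assigns confidences ~ N(0.9, 0.05²) clipped to (0.05, 1], and
injects false positives adjacent to existing birds (leg/part-sized boxes
within one radius, confidence U(0.3, 0.8), geometric lifetime of mean
2 frames — short enough that the tracker's `min_hits` filter is
meaningful). Expected concurrent false positives per frame equal
`fp_rate` (default 0.05). Both generators are deterministic under a fixed
seed.

What the simulator does *not* emulate: appearance, lighting, motion blur,
and — importantly — temporally correlated detector misses. Real occlusion
failures persist for many consecutive frames; here misses are independent
per frame. Consequently the absolute ID-loss rate at a given `p_miss` is
far higher than a real detector with the same average recall would produce
(every isolated miss opens a ≥ 3-frame emission gap), and passing tests
demonstrate the pipeline's bookkeeping and the direction of effects, not
real-world loss rates.

An instructive regime property follows from the lifecycle rules: a loss can
only be recorded where a track was *emitted* the frame before, and emission
requires `min_hits` consecutive detections. The per-bird-frame loss rate
under an IID miss probability p is therefore (1−p)³p — non-monotone, with a
maximum near p = 0.25. Moderate occlusion (the default drinker miss rate of
0.5, rate 0.0625) makes the drinker the clear loss hotspot; severe occlusion
(p = 0.8, rate 0.0064) empties the emitted stream inside the zone so
thoroughly that loss last-locations ring the zone instead of filling it.

Scripted scenarios (`lone_walker`, `crossing_pair`, `drinker_occlusion`,
`nudge`) are deterministic scenes whose expected tracker and metric
behavior is derivable by hand; they anchor the unit tests and illustrate
the canonical failure modes (clean tracking, identity exchange at a
crossing, occlusion death at the drinker, and an abrupt displacement
breaking the motion model's overlap assumption).

## Formats and conventions

MOT-Challenge-style CSV (`frame,id,left,top,width,height,conf`, trailing
−1 placeholders tolerated) for detections (id −1), ground truth, and
tracker output (confidence written as 1.0 — the tracker emits no score).
Frames are 1-based and contiguous; coordinates have the origin at the
image's top-left, y downward, continuous pixels; box intervals are closed,
so boxes sharing only an edge have zero overlap. The pixel→metric factor
defaults to the one printed anchor available for this pen, one mean broiler
radius: 13.5 cm / 59 px ≈ 0.0022881 m/px; for other rigs it is a config
value (a centerline of known length is the natural way to derive it).

## Problem sizes

Tests and the reproduction script run at desk scale, chosen once: clean
runs use 10 birds × 5,000 frames; noisy comparisons 20 seeds × 10 birds ×
1,500 frames (one simulated minute per seed, giving several hundred loss
events per seed at the stressed miss rates); detection metrics sample one
annotated frame per second from 30 s of simulation. Results quoted anywhere
in this repository are produced by those runs, not transcribed from
elsewhere.

## Known limitations

- The tracker is intentionally the plain SORT design: no appearance or
  re-identification features, no buffered-IOU matching, constant-velocity
  motion only. Sudden displacements (the `nudge` scenario) necessarily
  break it.
- Composite MOT scores (MOTA/HOTA) are out of scope; the metrics are the
  study's own (switches, tracklet time/distance, losses and circumstances).
- Simulator motion parameters are plausibility choices, not fitted to data;
  only the pen geometry, frame rate, group size, proximity thresholds and
  pixel scale are anchored to the study's printed values.
- `average_precision` recomputes the matching at every distinct confidence,
  which is exact but quadratic-ish; fine at annotated-set scale.
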