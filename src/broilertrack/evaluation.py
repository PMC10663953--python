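"""Tracking and detection evaluation against ground-truth annotations.

Tracking evaluation matches predicted track IDs to ground-truth trajectories
one-to-one per evaluation frame, weighting each frame's Hungarian assignment
by a trajectory-level (global) Jaccard alignment score so that matching stays
temporally consistent.  From the resulting association table it derives the
study's headline metrics: ID-switches per ground-truth trajectory and, per
tracklet, tracking time in minutes and tracking distance in meters.

Detection evaluation classifies predicted boxes as true/false positives
against ground-truth boxes (one-to-one Hungarian matching on IOU, gated at an
IOU threshold and a confidence threshold) and reports precision, recall,
average precision at a chosen IOU gate, and the confidence threshold that
maximises F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BoundingBox, PixelScale, iou, iou_matrix, px_to_meters

__all__ = [
    "TrajectorySet",
    "Tracklet",
    "overlap_counts",
    "global_alignment",
    "match_frames",
    "count_id_switches",
    "segment_tracklets",
    "FrameDetections",
    "DetectionCounts",
    "detection_outcomes",
    "precision_recall",
    "average_precision",
    "f1_maximizing_threshold",
    "sum_detection_counts",
]

UNMATCHED = None  # sentinel for "gt present but no prediction matched"


@dataclass
class TrajectorySet:
    """Per-frame, per-ID bounding boxes (ground truth or predictions).

    ``boxes`` maps frame → {id: BoundingBox}.  Frames are the evaluation
    frames, in strictly increasing order.
    """

    boxes: dict[int, dict[int, BoundingBox]] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return sorted(self.boxes)

    def ids(self) -> set[int]:
        out: set[int] = set()
        for frame_boxes in self.boxes.values():
            out.update(frame_boxes)
        return out

    def frames_of(self, obj_id: int) -> list[int]:
        return [f for f in self.frames if obj_id in self.boxes[f]]

    def add(self, frame: int, obj_id: int, box: BoundingBox) -> None:
        self.boxes.setdefault(frame, {})
        if obj_id in self.boxes[frame]:
            raise ValueError(f"duplicate (frame={frame}, id={obj_id})")
        self.boxes[frame][obj_id] = box

    def subsample(self, interval: int, offset: int = 0) -> "TrajectorySet":
        """Keep only frames where (frame - offset) % interval == 0."""
        kept = {
            f: dict(b)
            for f, b in self.boxes.items()
            if (f - offset) % interval == 0
        }
        return TrajectorySet(boxes=kept)


def overlap_counts(
    gt: TrajectorySet, pred: TrajectorySet, gate: float = 0.5
) -> dict[tuple[int, int], int]:
    """Count evaluation frames where each (gt_id, track_id) pair overlaps.

    A frame counts for the pair when the IOU of their boxes is >= ``gate``.
    """
    counts: dict[tuple[int, int], int] = {}
    for frame in gt.frames:
        pred_boxes = pred.boxes.get(frame, {})
        for gid, gbox in gt.boxes[frame].items():
            for pid, pbox in pred_boxes.items():
                if iou(gbox, pbox) >= gate:
                    counts[(gid, pid)] = counts.get((gid, pid), 0) + 1
    return counts


def global_alignment(
    gt: TrajectorySet, pred: TrajectorySet, gate: float = 0.5
) -> dict[tuple[int, int], float]:
    """Trajectory-level Jaccard alignment score for every overlapping pair.

    score(g, p) = c / (T_g + T_p - c), where c is the number of evaluation
    frames in which g and p overlap above the gate, and T_g, T_p are the
    numbers of frames in which g and p appear.
    """
    counts = overlap_counts(gt, pred, gate)
    t_g = {gid: len(gt.frames_of(gid)) for gid in gt.ids()}
    t_p = {pid: len(pred.frames_of(pid)) for pid in pred.ids()}
    return {
        (gid, pid): c / (t_g[gid] + t_p[pid] - c)
        for (gid, pid), c in counts.items()
    }


def match_frames(
    gt: TrajectorySet, pred: TrajectorySet, gate: float = 0.5
) -> dict[int, dict[int, int | None]]:
    """One-to-one per-frame matching of gt trajectories to predicted IDs.

    Per evaluation frame, a Hungarian assignment maximises the sum of
    global-alignment-score × frame-IOU over candidate pairs whose frame IOU
    meets the gate; gated-out pairs stay unmatched.  Returns an association
    table frame → {gt_id: track_id or None}.
    """
    scores = global_alignment(gt, pred, gate)
    table: dict[int, dict[int, int | None]] = {}
    for frame in gt.frames:
        gids = sorted(gt.boxes[frame])
        pids = sorted(pred.boxes.get(frame, {}))
        assoc: dict[int, int | None] = {gid: None for gid in gids}
        if gids and pids:
            gboxes = [gt.boxes[frame][g] for g in gids]
            pboxes = [pred.boxes[frame][p] for p in pids]
            ious = iou_matrix(gboxes, pboxes)
            weight = np.zeros_like(ious)
            for i, gid in enumerate(gids):
                for j, pid in enumerate(pids):
                    if ious[i, j] >= gate:
                        weight[i, j] = scores.get((gid, pid), 0.0) * ious[i, j]
            rows, cols = linear_sum_assignment(-weight)
            for r, c in zip(rows, cols):
                if ious[r, c] >= gate:
                    assoc[gids[r]] = pids[c]
        table[frame] = assoc
    return table


def count_id_switches(
    assoc: dict[int, dict[int, int | None]], gt_id: int
) -> int:
    """Number of changes in the predicted ID associated with one gt trajectory.

    Evaluation frames are scanned in order; unmatched frames neither count as
    a switch nor change the remembered ID.
    """
    frames = sorted(f for f in assoc if gt_id in assoc[f])
    if not frames:
        raise KeyError(f"gt_id {gt_id} not present in association table")
    switches = 0
    last: int | None = None
    for f in frames:
        tid = assoc[f][gt_id]
        if tid is None:
            continue
        if last is not None and tid != last:
            switches += 1
        last = tid
    return switches


@dataclass(frozen=True)
class Tracklet:
    """A maximal run of evaluation frames where one broiler keeps one ID."""

    gt_id: int
    track_id: int
    frames: tuple[int, ...]
    duration_min: float
    distance_m: float
    distance_pred_m: float


def segment_tracklets(
    assoc: dict[int, dict[int, int | None]],
    gt: TrajectorySet,
    scale: PixelScale,
    interval_min: float = 1.0,
    pred: TrajectorySet | None = None,
) -> list[Tracklet]:
    """Split each gt trajectory into tracklets at ID changes and gaps.

    A run of k consecutive matched evaluation frames with the same associated
    ID counts k × ``interval_min`` minutes, so a single-frame tracklet lasts
    one minute by definition.  Distance is the summed Euclidean displacement
    of the ground-truth box centers within the run, converted to meters; the
    predicted-center displacement is reported alongside for offset comparison.
    """
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    tracklets: list[Tracklet] = []
    for gid in sorted(gt.ids()):
        frames = [f for f in sorted(assoc) if gid in assoc[f]]
        run: list[int] = []
        run_id: int | None = None

        def flush() -> None:
            if not run:
                return
            dist_px = 0.0
            dist_pred_px = 0.0
            for a, b in zip(run, run[1:]):
                ca = gt.boxes[a][gid].center
                cb = gt.boxes[b][gid].center
                dist_px += math.dist(ca, cb)
                if pred is not None and run_id is not None:
                    pa = pred.boxes.get(a, {}).get(run_id)
                    pb = pred.boxes.get(b, {}).get(run_id)
                    if pa is not None and pb is not None:
                        dist_pred_px += math.dist(pa.center, pb.center)
            tracklets.append(
                Tracklet(
                    gt_id=gid,
                    track_id=run_id,  # type: ignore[arg-type]
                    frames=tuple(run),
                    duration_min=len(run) * interval_min,
                    distance_m=px_to_meters(dist_px, scale),
                    distance_pred_m=px_to_meters(dist_pred_px, scale),
                )
            )

        for f in frames:
            tid = assoc[f][gid]
            if tid is None or tid != run_id:
                flush()
                run, run_id = [], None
            if tid is not None:
                if not run:
                    run_id = tid
                run.append(f)
        flush()
    return tracklets


# ---------------------------------------------------------------------------
# Detection metrics
# ---------------------------------------------------------------------------

# One annotated frame: ground-truth boxes plus predictions with confidences.
FrameDetections = tuple[list[BoundingBox], list[tuple[BoundingBox, float]]]


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int


def detection_outcomes(
    gt_boxes: list[BoundingBox],
    pred_boxes: list[tuple[BoundingBox, float]],
    conf_thresh: float = 0.5,
    iou_thresh: float = 0.5,
) -> DetectionCounts:
    """Classify one frame's predictions as TP/FP and gt boxes as matched/FN.

    Predictions below the confidence threshold are discarded; survivors are
    matched one-to-one to gt by a Hungarian assignment maximising total IOU.
    Assigned pairs at IOU >= ``iou_thresh`` are TP; leftover predictions FP;
    unmatched gt FN.
    """
    kept = [b for b, c in pred_boxes if c >= conf_thresh]
    if not kept or not gt_boxes:
        return DetectionCounts(tp=0, fp=len(kept), fn=len(gt_boxes))
    mat = iou_matrix(gt_boxes, kept)
    rows, cols = linear_sum_assignment(-mat)
    tp = int(sum(mat[r, c] >= iou_thresh for r, c in zip(rows, cols)))
    return DetectionCounts(tp=tp, fp=len(kept) - tp, fn=len(gt_boxes) - tp)


def sum_detection_counts(
    frames: list[FrameDetections], conf_thresh: float, iou_thresh: float
) -> DetectionCounts:
    tp = fp = fn = 0
    for gt_boxes, preds in frames:
        c = detection_outcomes(gt_boxes, preds, conf_thresh, iou_thresh)
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
    return DetectionCounts(tp, fp, fn)


def precision_recall(counts: DetectionCounts) -> tuple[float, float]:
    """Precision and recall; empty denominators default to 1.0."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 1.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 1.0
    return precision, recall


def average_precision(
    frames: list[FrameDetections], iou_thresh: float = 0.5
) -> float:
    """Area under the precision-recall curve over all confidence thresholds.

    The curve is built by re-evaluating TP/FP/FN at every distinct prediction
    confidence; the precision envelope is made non-increasing before all-point
    integration over recall.
    """
    n_gt = sum(len(g) for g, _ in frames)
    if n_gt == 0:
        raise ValueError("average precision undefined without ground-truth boxes")
    confs = sorted({c for _, preds in frames for _, c in preds})
    if not confs:
        return 0.0
    points = []
    for t in confs:
        counts = sum_detection_counts(frames, t, iou_thresh)
        p, r = precision_recall(counts)
        points.append((r, p))
    # best precision attained at each recall level, plus the (0, 1) anchor
    best: dict[float, float] = {}
    for r, p in points:
        best[r] = max(best.get(r, 0.0), p)
    recalls = sorted(best)
    precisions = [best[r] for r in recalls]
    # enforce a non-increasing envelope from the right
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, precisions):
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def f1_maximizing_threshold(
    frames: list[FrameDetections], iou_thresh: float = 0.5
) -> float:
    """Confidence threshold (among observed confidences) maximising F1.

    Ties break toward the higher threshold.
    """
    confs = sorted({c for _, preds in frames for _, c in preds})
    if not confs:
        raise ValueError("no predictions")
    best_t, best_f1 = confs[0], -1.0
    for t in confs:
        p, r = precision_recall(sum_detection_counts(frames, t, iou_thresh))
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 >= best_f1:
            best_t, best_f1 = t, f1
    return best_t
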