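import itertools
import math

import pytest

from broilertrack.evaluation import (
    TrajectorySet,
    average_precision,
    count_id_switches,
    detection_outcomes,
    f1_maximizing_threshold,
    global_alignment,
    match_frames,
    overlap_counts,
    precision_recall,
    segment_tracklets,
    sum_detection_counts,
)
from broilertrack.geometry import BoundingBox, PixelScale


def _traj(entries) -> TrajectorySet:
    """entries: list of (frame, id, cx, cy) with fixed 50x50 boxes."""
    ts = TrajectorySet()
    for frame, obj_id, cx, cy in entries:
        ts.add(frame, obj_id, BoundingBox.from_center(cx, cy, 50, 50))
    return ts


def _pair_fixture():
    """One gt trajectory; one predicted ID overlapping it in 6 of 10 frames."""
    gt = _traj([(f, 1, 100, 100) for f in range(1, 11)])
    pred = TrajectorySet()
    for f in range(1, 11):
        cx = 100 if f <= 6 else 400  # drifts away after frame 6
        pred.add(f, 7, BoundingBox.from_center(cx, 100, 50, 50))
    return gt, pred


class TestGlobalAlignment:
    def test_identical_trajectories_score_one(self):
        gt = _traj([(f, 1, 100, 100) for f in range(1, 11)])
        pred = _traj([(f, 9, 100, 100) for f in range(1, 11)])
        assert overlap_counts(gt, pred)[(1, 9)] == 10
        assert global_alignment(gt, pred)[(1, 9)] == pytest.approx(1.0)

    def test_disjoint_pair_absent(self):
        gt = _traj([(f, 1, 100, 100) for f in range(1, 11)])
        pred = _traj([(f, 9, 900, 900) for f in range(1, 11)])
        assert overlap_counts(gt, pred) == {}
        assert global_alignment(gt, pred) == {}

    def test_partial_overlap_jaccard(self):
        gt, pred = _pair_fixture()
        assert overlap_counts(gt, pred)[(1, 7)] == 6
        # c=6, T_g=10, T_p=10 -> 6 / (10 + 10 - 6)
        assert global_alignment(gt, pred)[(1, 7)] == pytest.approx(6 / 14)


class TestMatchFrames:
    def test_simple_match_and_gate(self):
        gt = _traj([(1, 1, 100, 100)])
        pred_good = _traj([(1, 7, 110, 100)])  # IOU 40/60 = 0.667
        assert match_frames(gt, pred_good)[1][1] == 7
        pred_bad = _traj([(1, 7, 120, 100)])  # IOU 30/70 ~ 0.43 < 0.5
        assert match_frames(gt, pred_bad)[1][1] is None

    def test_global_score_breaks_frame_ties(self):
        # two predicted IDs sit equally on gt at frame 10, but p1 covered the
        # trajectory for frames 1-9: the majority ID wins the ambiguous frame
        gt = _traj([(f, 1, 100, 100) for f in range(1, 11)])
        pred = TrajectorySet()
        for f in range(1, 10):
            pred.add(f, 1, BoundingBox.from_center(100, 100, 50, 50))
        pred.add(10, 1, BoundingBox.from_center(100, 100, 50, 50))
        pred.add(10, 2, BoundingBox.from_center(101, 100, 50, 50))
        assert match_frames(gt, pred)[10][1] == 1

    def test_one_to_one_within_frame(self):
        gt = _traj([(1, 1, 100, 100), (1, 2, 102, 100)])
        pred = _traj([(1, 7, 100, 100), (1, 8, 102, 100)])
        assoc = match_frames(gt, pred)[1]
        matched = [v for v in assoc.values() if v is not None]
        assert len(matched) == len(set(matched))


class TestIdSwitches:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            (["A", "A", "A"], 0),
            (["A", "A", "B", "B", "A"], 2),
            (["A", None, "A"], 0),
            (["A", None, "B"], 1),
            ([None, "A", "A"], 0),
        ],
    )
    def test_scanning_rule(self, seq, expected):
        ids = {s: i for i, s in enumerate({x for x in seq if x}, start=1)}
        assoc = {
            f: {1: (ids[s] if s is not None else None)}
            for f, s in enumerate(seq, start=1)
        }
        assert count_id_switches(assoc, 1) == expected

    def test_unknown_gt_id_errors(self):
        with pytest.raises(KeyError):
            count_id_switches({1: {1: 2}}, 99)


class TestTracklets:
    def test_three_four_five_distances(self):
        scale = PixelScale(0.005)
        gt = _traj([(1, 1, 0, 0), (2, 1, 30, 40), (3, 1, 60, 40)])
        assoc = {1: {1: 10}, 2: {1: 10}, 3: {1: 20}}
        tls = segment_tracklets(assoc, gt, scale)
        assert len(tls) == 2
        a, b = tls
        assert a.track_id == 10 and len(a.frames) == 2
        assert a.duration_min == pytest.approx(2.0)
        assert a.distance_m == pytest.approx(50 * 0.005)  # 3-4-5 triangle
        assert b.track_id == 20 and b.duration_min == pytest.approx(1.0)
        assert b.distance_m == pytest.approx(0.0)

    def test_gap_terminates_run_without_switch(self):
        gt = _traj([(f, 1, 10 * f, 0) for f in range(1, 6)])
        assoc = {1: {1: 5}, 2: {1: 5}, 3: {1: None}, 4: {1: 5}, 5: {1: 5}}
        tls = segment_tracklets(assoc, gt, PixelScale(1.0))
        assert [len(t.frames) for t in tls] == [2, 2]
        assert count_id_switches(assoc, 1) == 0

    def test_switch_count_vs_tracklet_count(self):
        # without unmatched gaps, tracklets = switches + 1
        gt = _traj([(f, 1, 0, 0) for f in range(1, 8)])
        assoc = {f: {1: tid} for f, tid in zip(range(1, 8), [1, 1, 2, 2, 3, 3, 3])}
        assert count_id_switches(assoc, 1) == 2
        assert len(segment_tracklets(assoc, gt, PixelScale(1.0))) == 3

    def test_scripted_renames_recovered(self):
        # predictions are gt with the ID renamed at 3 known evaluation frames
        centers = [(0, 0), (30, 40), (60, 80), (90, 120), (120, 160), (150, 200)]
        gt = _traj([(f, 1, *c) for f, c in enumerate(centers, start=1)])
        pred = TrajectorySet()
        names = [101, 101, 202, 202, 303, 404]  # renames at frames 3, 5, 6
        for f, (c, tid) in enumerate(zip(centers, names), start=1):
            pred.add(f, tid, BoundingBox.from_center(*c, 50, 50))
        assoc = match_frames(gt, pred)
        assert count_id_switches(assoc, 1) == 3
        tls = segment_tracklets(assoc, gt, PixelScale(1.0))
        assert len(tls) == 4
        # each step moves 50 px (3-4-5), so distance = (run length - 1) * 50
        assert [t.distance_m for t in tls] == pytest.approx([50, 50, 0, 0])


class TestDetectionOutcomes:
    def test_perfect_predictions(self):
        gt = [BoundingBox(10 * i, 0, 8, 8) for i in range(10)]
        preds = [(b, 0.9) for b in gt]
        c = detection_outcomes(gt, preds, 0.5, 0.5)
        assert (c.tp, c.fp, c.fn) == (10, 0, 0)
        assert precision_recall(c) == (1.0, 1.0)

    def test_low_iou_is_fp_and_fn(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        preds = [(BoundingBox(6, 0, 10, 10), 0.9)]  # IOU 40/160 = 0.25
        c = detection_outcomes(gt, preds, 0.5, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_double_detection_one_to_one(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(100, 0, 10, 10)]
        preds = [
            (BoundingBox(0, 0, 10, 10), 0.9),
            (BoundingBox(1, 0, 10, 10), 0.8),  # second hit on the same gt
            (BoundingBox(100, 0, 10, 10), 0.7),
        ]
        c = detection_outcomes(gt, preds, 0.5, 0.5)
        assert (c.tp, c.fp, c.fn) == (2, 1, 0)

    def test_confidence_threshold_discards(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        preds = [(BoundingBox(0, 0, 10, 10), 0.3)]
        c = detection_outcomes(gt, preds, conf_thresh=0.5)
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_empty_prediction_conventions(self):
        from broilertrack.evaluation import DetectionCounts

        assert precision_recall(DetectionCounts(0, 0, 5)) == (1.0, 0.0)
        assert precision_recall(DetectionCounts(9, 1, 1)) == (0.9, 0.9)


def _ap_oracle(frames, iou_thresh):
    """Exhaustive PR-curve enumeration: best precision per recall level,
    non-increasing envelope, rectangle integration.  Matching per threshold
    by exhaustive permutation search (instances are tiny)."""
    confs = sorted({c for _, preds in frames for _, c in preds})
    pts = []
    for t in confs:
        tp = fp = fn = 0
        for gt_boxes, preds in frames:
            kept = [b for b, c in preds if c >= t]
            best = 0
            if gt_boxes and kept:
                k = min(len(gt_boxes), len(kept))
                from broilertrack.geometry import iou as _iou

                for gsel in itertools.permutations(range(len(gt_boxes)), k):
                    for psel in itertools.permutations(range(len(kept)), k):
                        n = sum(
                            _iou(gt_boxes[g], kept[p]) >= iou_thresh
                            for g, p in zip(gsel, psel)
                        )
                        best = max(best, n)
            tp += best
            fp += len(kept) - best
            fn += len(gt_boxes) - best
        p = tp / (tp + fp) if tp + fp else 1.0
        r = tp / (tp + fn) if tp + fn else 1.0
        pts.append((r, p))
    best_p = {}
    for r, p in pts:
        best_p[r] = max(best_p.get(r, 0.0), p)
    recalls = sorted(best_p)
    envelope = [best_p[r] for r in recalls]
    for i in range(len(envelope) - 2, -1, -1):
        envelope[i] = max(envelope[i], envelope[i + 1])
    ap, prev = 0.0, 0.0
    for r, p in zip(recalls, envelope):
        ap += (r - prev) * p
        prev = r
    return ap


class TestAveragePrecision:
    def test_perfect_and_hopeless(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 0, 10, 10)]
        perfect = [(gt[0], 0.9), (gt[1], 0.8)]
        assert average_precision([(gt, perfect)]) == pytest.approx(1.0)
        misses = [(BoundingBox(200, 200, 10, 10), 0.9)]
        assert average_precision([(gt, misses)]) == pytest.approx(0.0)

    def test_middle_confidence_fp(self):
        # confidences 0.9 / 0.8 / 0.7, the 0.8 one a false positive, 2 gt
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 0, 10, 10)]
        preds = [
            (gt[0], 0.9),
            (BoundingBox(200, 200, 10, 10), 0.8),
            (gt[1], 0.7),
        ]
        assert average_precision([(gt, preds)]) == pytest.approx(5 / 6)

    def test_matches_enumeration_oracle(self, rng):
        from .conftest import random_int_box

        for _ in range(15):
            n_gt = int(rng.integers(1, 5))
            n_pred = int(rng.integers(1, 6))
            gt = [random_int_box(rng, 20) for _ in range(n_gt)]
            preds = [
                (random_int_box(rng, 20), float(rng.uniform(0.1, 1.0)))
                for _ in range(n_pred)
            ]
            frames = [(gt, preds)]
            assert average_precision(frames, 0.5) == pytest.approx(
                _ap_oracle(frames, 0.5), abs=1e-9
            )

    def test_no_gt_errors(self):
        with pytest.raises(ValueError):
            average_precision([([], [(BoundingBox(0, 0, 1, 1), 0.5)])])


class TestF1Threshold:
    def test_fp_below_tp_confidence(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 0, 10, 10)]
        preds = [(gt[0], 0.9), (BoundingBox(200, 200, 10, 10), 0.2)]
        # at 0.9: P=1, R=0.5, F1=2/3; at 0.2: P=0.5, R=0.5, F1=0.5
        assert f1_maximizing_threshold([(gt, preds)]) == 0.9

    def test_single_perfect_prediction(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        assert f1_maximizing_threshold([(gt, [(gt[0], 0.77)])]) == 0.77

    def test_all_tp_returns_lowest(self):
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(50, 0, 10, 10)]
        preds = [(gt[0], 0.9), (gt[1], 0.4)]
        assert f1_maximizing_threshold([(gt, preds)]) == 0.4

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            f1_maximizing_threshold([([BoundingBox(0, 0, 1, 1)], [])])


def test_trajectory_set_rejects_duplicates():
    ts = TrajectorySet()
    ts.add(1, 1, BoundingBox(0, 0, 10, 10))
    with pytest.raises(ValueError):
        ts.add(1, 1, BoundingBox(5, 5, 10, 10))


def test_subsample_keeps_interval():
    ts = _traj([(f, 1, 0, 0) for f in range(1, 21)])
    sub = ts.subsample(5, offset=1 % 5)
    assert sub.frames == [1, 6, 11, 16]
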