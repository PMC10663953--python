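"""Tracking-by-detection with a constant-velocity Kalman filter.

The tracker follows the SORT recipe: per frame it (1) predicts every live
track forward one frame with a linear constant-velocity model, (2) associates
predictions with the frame's detections by maximising total IOU with the
Hungarian algorithm, gated at a minimum IOU, and (3) updates matched tracks
with the standard Kalman equations.  Unmatched detections seed tentative
tracks (velocities zero, high initial velocity variance); tracks unmatched for
more than ``max_age`` frames are terminated; a track is emitted only once it
has accumulated ``min_hits`` consecutive matches (or during the warm-up window
at the start of a run).

State vector: ``x = [x, y, s, r, vx, vy, vs]`` — box center, area (scale),
aspect ratio, and the velocities of the first three.  The aspect ratio carries
no velocity and is constant under prediction.  Measurements are the
(x, y, s, r) of a detected box; detection confidence is carried as metadata
and plays no role in the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import (
    BoundingBox,
    StateObservation,
    box_to_observation,
    iou_matrix,
    observation_to_box,
)

__all__ = [
    "KalmanModel",
    "TrackState",
    "Track",
    "TrackerConfig",
    "predict",
    "update",
    "associate",
    "SortTracker",
    "run_tracker",
]


def _constant_velocity_F() -> np.ndarray:
    F = np.eye(7)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0
    return F


@dataclass(frozen=True)
class KalmanModel:
    """Matrices of the linear-Gaussian motion/measurement model.

    Defaults follow the widely used reference constants for this tracker
    family: modest measurement noise on position, larger on scale/aspect, and
    very high initial variance on the unobservable velocities.
    """

    F: np.ndarray = field(default_factory=_constant_velocity_F)
    Q: np.ndarray = field(
        default_factory=lambda: np.diag([1.0, 1.0, 1.0, 1.0, 0.01, 0.01, 1e-4])
    )
    H: np.ndarray = field(default_factory=lambda: np.eye(4, 7))
    R: np.ndarray = field(default_factory=lambda: np.diag([1.0, 1.0, 10.0, 10.0]))
    P0: np.ndarray = field(
        default_factory=lambda: np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])
    )


@dataclass
class TrackState:
    """Kalman mean ``x`` (7-vector) and covariance ``P`` (7×7) of one track."""

    x: np.ndarray
    P: np.ndarray

    @classmethod
    def from_observation(cls, z: StateObservation, model: KalmanModel) -> "TrackState":
        x = np.array([z.x, z.y, z.s, z.r, 0.0, 0.0, 0.0])
        return cls(x=x, P=model.P0.copy())

    def to_box(self) -> BoundingBox:
        return observation_to_box(
            StateObservation(self.x[0], self.x[1], self.x[2], self.x[3])
        )


def predict(t: TrackState, m: KalmanModel) -> TrackState:
    """One constant-velocity prediction step.

    If the predicted scale would go non-positive, the scale velocity is zeroed
    first so the state stays a valid box.
    """
    x = t.x.copy()
    if x[2] + x[6] <= 0:
        x[6] = 0.0
    x = m.F @ x
    P = m.F @ t.P @ m.F.T + m.Q
    return TrackState(x=x, P=P)


def update(t: TrackState, z: StateObservation, m: KalmanModel) -> TrackState:
    """Kalman measurement update with observation (x, y, s, r)."""
    zv = np.array([z.x, z.y, z.s, z.r])
    S = m.H @ t.P @ m.H.T + m.R
    K = t.P @ m.H.T @ np.linalg.inv(S)
    x = t.x + K @ (zv - m.H @ t.x)
    P = (np.eye(7) - K @ m.H) @ t.P
    return TrackState(x=x, P=P)


def associate(
    detections: list[BoundingBox],
    predictions: list[BoundingBox],
    iou_min: float = 0.3,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """IOU-gated one-to-one assignment of detections to predicted tracks.

    Returns ``(matches, unmatched_detections, unmatched_predictions)`` where
    matches are (detection_index, prediction_index) pairs.  The assignment
    maximises total IOU; any assigned pair with IOU below ``iou_min`` is
    dissolved into unmatched on both sides.  Detections are sorted by
    (left, top) before solving so tied assignments resolve deterministically.
    """
    if not detections or not predictions:
        return [], list(range(len(detections))), list(range(len(predictions)))

    order = sorted(
        range(len(detections)), key=lambda i: (detections[i].left, detections[i].top)
    )
    dets = [detections[i] for i in order]
    mat = iou_matrix(dets, predictions)
    rows, cols = linear_sum_assignment(-mat)

    matches: list[tuple[int, int]] = []
    matched_d: set[int] = set()
    matched_p: set[int] = set()
    for r, c in zip(rows, cols):
        if mat[r, c] >= iou_min:
            matches.append((order[r], c))
            matched_d.add(order[r])
            matched_p.add(c)
    unmatched_d = [i for i in range(len(detections)) if i not in matched_d]
    unmatched_p = [j for j in range(len(predictions)) if j not in matched_p]
    matches.sort()
    return matches, unmatched_d, unmatched_p


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker hyperparameters (defaults as used for the broiler pen study)."""

    iou_min: float = 0.3
    min_hits: int = 3
    max_age: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.iou_min < 1):
            raise ValueError("iou_min must be in (0, 1)")
        if self.min_hits < 1 or self.max_age < 1:
            raise ValueError("min_hits and max_age must be >= 1")


@dataclass
class Track:
    """One tracked object and its lifecycle counters."""

    track_id: int
    state: TrackState
    hit_streak: int = 0
    time_since_update: int = 0
    age: int = 0


class SortTracker:
    """Stateful frame-by-frame tracker.

    Call :meth:`step` once per frame with that frame's detections; it returns
    the confirmed tracks as ``(track_id, BoundingBox)`` pairs.  Track IDs are
    positive, unique within a run, and never reused.
    """

    def __init__(
        self,
        config: TrackerConfig | None = None,
        model: KalmanModel | None = None,
    ) -> None:
        self.config = config or TrackerConfig()
        self.model = model or KalmanModel()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._frame_count = 0
        self._last_frame: int | None = None

    def step(
        self, frame_index: int, detections: list[BoundingBox]
    ) -> list[tuple[int, BoundingBox]]:
        if self._last_frame is not None and frame_index != self._last_frame + 1:
            raise ValueError(
                f"frame indices must increase by 1: got {frame_index} "
                f"after {self._last_frame}"
            )
        self._last_frame = frame_index
        self._frame_count += 1
        cfg, model = self.config, self.model

        for tr in self.tracks:
            tr.state = predict(tr.state, model)
            if tr.time_since_update > 0:
                tr.hit_streak = 0
            tr.time_since_update += 1
            tr.age += 1

        predicted = [tr.state.to_box() for tr in self.tracks]
        matches, unmatched_d, _ = associate(detections, predicted, cfg.iou_min)

        for d_idx, p_idx in matches:
            tr = self.tracks[p_idx]
            tr.state = update(tr.state, box_to_observation(detections[d_idx]), model)
            tr.time_since_update = 0
            tr.hit_streak += 1

        for d_idx in unmatched_d:
            state = TrackState.from_observation(
                box_to_observation(detections[d_idx]), model
            )
            self.tracks.append(Track(track_id=self._next_id, state=state))
            self._next_id += 1

        self.tracks = [
            tr for tr in self.tracks if tr.time_since_update <= cfg.max_age
        ]

        out: list[tuple[int, BoundingBox]] = []
        for tr in self.tracks:
            if tr.time_since_update == 0 and (
                tr.hit_streak >= cfg.min_hits or self._frame_count <= cfg.min_hits
            ):
                out.append((tr.track_id, tr.state.to_box()))
        out.sort(key=lambda t: t[0])
        return out


def run_tracker(
    detections_by_frame: dict[int, list[BoundingBox]],
    config: TrackerConfig | None = None,
    model: KalmanModel | None = None,
) -> dict[int, dict[int, BoundingBox]]:
    """Run a tracker over an ordered frame → detections mapping.

    Frames must be consecutive.  Returns frame → {track_id: box} for the
    confirmed tracks of every frame.
    """
    tracker = SortTracker(config=config, model=model)
    out: dict[int, dict[int, BoundingBox]] = {}
    for frame in sorted(detections_by_frame):
        emitted = tracker.step(frame, detections_by_frame[frame])
        out[frame] = dict(emitted)
    return out
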