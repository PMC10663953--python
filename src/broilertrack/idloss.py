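"""ID-loss detection and circumstance analysis at full frame rate.

An ID-loss is a track ID present in frame t−1 and absent in frame t.  The
same ID lost, re-appearing and lost again produces one event per loss.  Each
event is characterised by where it happened (last box center, drinker-zone
membership, occupancy heatmaps), how long the ID existed in total (lifetime
filter), how close the nearest other broiler was (proximity classes), and the
kinematics of the track just before the loss (velocity and acceleration
magnitudes over 1-second timesteps).  The same proximity/kinematic records
are collected for tracks that did *not* lose their ID, as the comparison
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import BoundingBox, PixelScale

__all__ = [
    "IdLossEvent",
    "RegionMask",
    "ProximityClasses",
    "detect_id_losses",
    "filter_by_lifetime",
    "filter_by_region",
    "nearest_neighbor",
    "classify_proximity",
    "count_close_neighbors",
    "velocity_magnitude",
    "acceleration_magnitude",
    "occupancy_heatmap",
    "plot_heatmap",
    "CircumstanceRecord",
    "analyze_losses",
    "summarize_circumstances",
]


@dataclass(frozen=True)
class RegionMask:
    """Rectangular exclusion zones (e.g. the drinker), closed boundaries."""

    rectangles: tuple[tuple[float, float, float, float], ...] = ()

    def contains(self, x: float, y: float) -> bool:
        return any(
            l <= x <= l + w and t <= y <= t + h
            for l, t, w, h in self.rectangles
        )


@dataclass(frozen=True)
class ProximityClasses:
    """Nearest-neighbor distance classes.

    Defaults follow the pen study's annotation-derived values: broilers are
    "in proximity" within 128 px (29 cm) and in "close proximity" within one
    mean broiler radius, 59 px (13.5 cm).
    """

    proximity_px: float = 128.0
    close_px: float = 59.0

    def __post_init__(self) -> None:
        if not (0 < self.close_px <= self.proximity_px):
            raise ValueError("require 0 < close_px <= proximity_px")


@dataclass(frozen=True)
class IdLossEvent:
    """One ID-loss: a track ID present at frame−1 and absent at frame."""

    frame: int
    track_id: int
    last_box: BoundingBox | None = None
    lifetime_s: float | None = None
    in_drinker: bool | None = None
    nearest_dist_px: float | None = None
    proximity_class: str | None = None
    n_close_neighbors: int | None = None
    v_mag: float | None = None
    a_mag: float | None = None


def detect_id_losses(
    per_frame_ids: dict[int, set[int]],
    excluded_frames: set[int] | None = None,
) -> list[IdLossEvent]:
    """Scan consecutive frames for IDs that disappear.

    Frames must be consecutive integers.  Excluded frames are skipped
    entirely: transitions into or out of them are not counted.
    """
    frames = sorted(per_frame_ids)
    for a, b in zip(frames, frames[1:]):
        if b != a + 1:
            raise ValueError(f"frames must be consecutive; gap between {a} and {b}")
    excluded = excluded_frames or set()
    events: list[IdLossEvent] = []
    for prev, cur in zip(frames, frames[1:]):
        if prev in excluded or cur in excluded:
            continue
        lost = per_frame_ids[prev] - per_frame_ids[cur]
        events.extend(IdLossEvent(frame=cur, track_id=tid) for tid in sorted(lost))
    return events


def filter_by_lifetime(
    events: list[IdLossEvent],
    per_id_total_frames: dict[int, int],
    fps: float,
    min_s: float = 1.0,
) -> list[IdLossEvent]:
    """Keep events whose ID existed for at least ``min_s`` seconds in total."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    return [
        e
        for e in events
        if per_id_total_frames.get(e.track_id, 0) / fps >= min_s
    ]


def filter_by_region(
    events: list[IdLossEvent], mask: RegionMask
) -> tuple[list[IdLossEvent], list[IdLossEvent]]:
    """Split events into (kept, excluded) by last-box center in the mask.

    Events without a last box are kept.  Boundaries are closed: a center on a
    rectangle edge is excluded.
    """
    kept: list[IdLossEvent] = []
    excluded: list[IdLossEvent] = []
    for e in events:
        if e.last_box is not None and mask.contains(*e.last_box.center):
            excluded.append(e)
        else:
            kept.append(e)
    return kept, excluded


def nearest_neighbor(
    center: tuple[float, float],
    detections: dict[int, BoundingBox],
    exclude_ids: set[int] = frozenset(),
) -> float | None:
    """Minimum center-to-center distance to any other detection, in px.

    Detections with an ID in ``exclude_ids`` (the subject itself, and the
    lost ID when building no-loss comparison records) are not candidates.
    Returns None when no candidates remain.
    """
    dists = [
        math.dist(center, box.center)
        for tid, box in detections.items()
        if tid not in exclude_ids
    ]
    return min(dists) if dists else None


def classify_proximity(
    distance_px: float, classes: ProximityClasses = ProximityClasses()
) -> str:
    """Classify a nearest-neighbor distance: 'close', 'proximate' or 'neither'."""
    if distance_px < 0:
        raise ValueError("distance must be >= 0")
    if distance_px <= classes.close_px:
        return "close"
    if distance_px <= classes.proximity_px:
        return "proximate"
    return "neither"


def count_close_neighbors(
    center: tuple[float, float],
    detections: dict[int, BoundingBox],
    close_px: float = 59.0,
    exclude_ids: set[int] = frozenset(),
) -> int:
    """Number of other detections within ``close_px`` of the center (closed)."""
    return sum(
        math.dist(center, box.center) <= close_px
        for tid, box in detections.items()
        if tid not in exclude_ids
    )


def velocity_magnitude(
    p_t: tuple[float, float],
    p_prev: tuple[float, float],
    dt: float,
    scale: PixelScale,
) -> float:
    """Speed |V| in m/s from two center positions ``dt`` seconds apart."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return math.dist(p_t, p_prev) / dt * scale.meters_per_px


def acceleration_magnitude(
    v_t: tuple[float, float], v_prev: tuple[float, float], dt: float
) -> float:
    """|A| in m/s² from two velocity vectors (m/s) ``dt`` seconds apart."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return math.dist(v_t, v_prev) / dt


def occupancy_heatmap(
    points: list[tuple[float, float]],
    grid: tuple[int, int],
    frame_size: tuple[float, float],
) -> np.ndarray:
    """Bin points into an (n_y, n_x) count grid over the frame.

    Cell counts sum to the number of points; points outside the frame are
    rejected.
    """
    n_x, n_y = grid
    w, h = frame_size
    if n_x < 1 or n_y < 1:
        raise ValueError("grid dimensions must be >= 1")
    for x, y in points:
        if not (0 <= x <= w and 0 <= y <= h):
            raise ValueError(f"point ({x}, {y}) outside frame bounds {frame_size}")
    if not points:
        return np.zeros((n_y, n_x), dtype=int)
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    counts, _, _ = np.histogram2d(
        ys, xs, bins=[n_y, n_x], range=[[0, h], [0, w]]
    )
    return counts.astype(int)


def plot_heatmap(grid: np.ndarray, path, title: str = "ID-loss locations") -> None:
    """Render a count grid as a heatmap image (pen seen from above)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    im = ax.imshow(grid, cmap="inferno")
    ax.set_title(title)
    ax.set_xlabel("pen width (cells)")
    ax.set_ylabel("pen length (cells)")
    fig.colorbar(im, ax=ax, label="count")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


@dataclass(frozen=True)
class CircumstanceRecord:
    """Proximity + kinematics of one detection at one frame, for either group."""

    frame: int
    track_id: int
    nearest_dist_px: float | None
    proximity_class: str | None
    n_close_neighbors: int
    v_mag: float | None
    a_mag: float | None


@dataclass
class LossAnalysis:
    """Everything the ID-loss pipeline computes for one tracked run."""

    events: list[IdLossEvent]
    noloss_records: list[CircumstanceRecord]
    n_dropped_no_history: int


def _track_center(
    tracks: dict[int, dict[int, BoundingBox]], frame: int, tid: int
) -> tuple[float, float] | None:
    box = tracks.get(frame, {}).get(tid)
    return box.center if box is not None else None


def _kinematics(
    tracks: dict[int, dict[int, BoundingBox]],
    frame: int,
    tid: int,
    fps: float,
    scale: PixelScale,
) -> tuple[float | None, float | None]:
    """|V| and |A| at ``frame`` using positions 1 s and 2 s earlier."""
    step = int(round(fps))
    p0 = _track_center(tracks, frame, tid)
    p1 = _track_center(tracks, frame - step, tid)
    p2 = _track_center(tracks, frame - 2 * step, tid)
    if p0 is None or p1 is None:
        return None, None
    mpp = scale.meters_per_px
    v_vec = ((p0[0] - p1[0]) * mpp, (p0[1] - p1[1]) * mpp)
    v = math.hypot(*v_vec)
    if p2 is None:
        return v, None
    v_prev = ((p1[0] - p2[0]) * mpp, (p1[1] - p2[1]) * mpp)
    a = math.dist(v_vec, v_prev)
    return v, a


def analyze_losses(
    tracks: dict[int, dict[int, BoundingBox]],
    fps: float,
    scale: PixelScale,
    drinker: RegionMask = RegionMask(),
    classes: ProximityClasses = ProximityClasses(),
    excluded_frames: set[int] | None = None,
    noloss_every_frame: bool = False,
) -> LossAnalysis:
    """Run the full ID-loss circumstance pipeline on per-frame track output.

    ``tracks`` maps frame → {track_id: box} at full frame rate.  For every
    loss, the event is enriched with the last box, total ID lifetime, drinker
    membership, nearest-neighbor proximity and 1-second kinematics (computed
    for the frame before the loss; events without enough track history get
    None kinematics).  No-loss comparison records are collected from the
    surviving tracks of the frames where losses occurred — or, with
    ``noloss_every_frame``, from every frame — never counting the lost IDs
    among their neighbor candidates.
    """
    per_frame_ids = {f: set(boxes) for f, boxes in tracks.items()}
    raw = detect_id_losses(per_frame_ids, excluded_frames)

    lifetimes: dict[int, int] = {}
    for boxes in tracks.values():
        for tid in boxes:
            lifetimes[tid] = lifetimes.get(tid, 0) + 1

    events: list[IdLossEvent] = []
    n_dropped = 0
    for e in raw:
        ref = e.frame - 1  # the last frame where the ID existed
        last_box = tracks[ref][e.track_id]
        center = last_box.center
        others = tracks[ref]
        nn = nearest_neighbor(center, others, exclude_ids={e.track_id})
        v, a = _kinematics(tracks, ref, e.track_id, fps, scale)
        if v is None:
            n_dropped += 1
        events.append(
            replace(
                e,
                last_box=last_box,
                lifetime_s=lifetimes[e.track_id] / fps,
                in_drinker=drinker.contains(*center),
                nearest_dist_px=nn,
                proximity_class=None if nn is None else classify_proximity(nn, classes),
                n_close_neighbors=count_close_neighbors(
                    center, others, classes.close_px, exclude_ids={e.track_id}
                ),
                v_mag=v,
                a_mag=a,
            )
        )

    loss_frames = sorted({e.frame for e in events})
    lost_at: dict[int, set[int]] = {}
    for e in events:
        lost_at.setdefault(e.frame, set()).add(e.track_id)

    sample_frames = (
        [f for f in sorted(tracks) if f > min(tracks)]
        if noloss_every_frame
        else loss_frames
    )
    noloss: list[CircumstanceRecord] = []
    for f in sample_frames:
        ref = f - 1
        if ref not in tracks:
            continue
        lost_ids = lost_at.get(f, set())
        for tid, box in tracks[ref].items():
            if tid in lost_ids or tid not in tracks.get(f, {}):
                continue
            center = box.center
            # the lost IDs never count as neighbor candidates here
            exclude = lost_ids | {tid}
            nn = nearest_neighbor(center, tracks[ref], exclude_ids=exclude)
            v, a = _kinematics(tracks, ref, tid, fps, scale)
            noloss.append(
                CircumstanceRecord(
                    frame=f,
                    track_id=tid,
                    nearest_dist_px=nn,
                    proximity_class=None
                    if nn is None
                    else classify_proximity(nn, classes),
                    n_close_neighbors=count_close_neighbors(
                        center, tracks[ref], classes.close_px, exclude_ids=exclude
                    ),
                    v_mag=v,
                    a_mag=a,
                )
            )
    return LossAnalysis(events=events, noloss_records=noloss, n_dropped_no_history=n_dropped)


def summarize_circumstances(
    loss_events: list[IdLossEvent],
    noloss_records: list[CircumstanceRecord],
    scale: PixelScale,
    classes: ProximityClasses = ProximityClasses(),
):
    """Per-group summary of proximity and kinematics, as a DataFrame.

    Rows: (group, metric) with mean/min/max; distances reported in cm.
    Also returns normalized histogram tables (fractions within group) of the
    proximity class and the close-neighbor count.
    """
    import pandas as pd

    if not loss_events or not noloss_records:
        raise ValueError("both groups must be non-empty")

    def pull(records, attr):
        vals = [getattr(r, attr) for r in records]
        return [v for v in vals if v is not None]

    cm = scale.meters_per_px * 100.0
    rows = []
    groups = {"id_loss": loss_events, "no_id_loss": noloss_records}
    for name, records in groups.items():
        for metric, values in [
            ("nearest_dist_cm", [v * cm for v in pull(records, "nearest_dist_px")]),
            ("v_mag_mps", pull(records, "v_mag")),
            ("a_mag_mps2", pull(records, "a_mag")),
        ]:
            if values:
                rows.append(
                    {
                        "group": name,
                        "metric": metric,
                        "n": len(values),
                        "mean": float(np.mean(values)),
                        "min": float(np.min(values)),
                        "max": float(np.max(values)),
                    }
                )
    summary = pd.DataFrame(rows)

    hist_rows = []
    for name, records in groups.items():
        classes_seen = pull(records, "proximity_class")
        n = len(classes_seen)
        for cls in ("close", "proximate", "neither"):
            hist_rows.append(
                {
                    "group": name,
                    "table": "proximity_class",
                    "bin": cls,
                    "fraction": classes_seen.count(cls) / n if n else 0.0,
                }
            )
        counts = [r.n_close_neighbors for r in records]
        for k in sorted(set(counts)):
            hist_rows.append(
                {
                    "group": name,
                    "table": "n_close_neighbors",
                    "bin": str(k),
                    "fraction": counts.count(k) / len(counts),
                }
            )
    return summary, pd.DataFrame(hist_rows)
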