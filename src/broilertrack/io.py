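"""MOT-Challenge-style CSV streams, flat key-value configs, and text grids.

One record per line: ``frame,id,left,top,width,height,conf`` with up to three
trailing ``-1`` placeholder columns tolerated (the MOT world-coordinate
slots).  Frames are 1-based and contiguous.  Raw detections carry id −1;
tracker output carries confidence 1.0 (the tracker emits no score).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import TrajectorySet
from .geometry import BoundingBox

__all__ = [
    "StreamRecord",
    "read_stream",
    "write_stream",
    "read_detections",
    "write_detections",
    "read_trajectories",
    "write_trajectories",
    "read_config",
    "write_config",
    "RunConfig",
    "write_heatmap",
]


@dataclass(frozen=True)
class StreamRecord:
    frame: int
    obj_id: int
    box: BoundingBox
    confidence: float


def _parse_line(line: str, lineno: int) -> StreamRecord | None:
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    parts = stripped.split(",")
    if not 7 <= len(parts) <= 10:
        raise ValueError(
            f"line {lineno}: expected 7-10 comma-separated fields, got {len(parts)}"
        )
    try:
        frame = int(float(parts[0]))
        obj_id = int(float(parts[1]))
        left, top, width, height, conf = (float(p) for p in parts[2:7])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
    if frame < 1:
        raise ValueError(f"line {lineno}: frame must be >= 1, got {frame}")
    if width <= 0 or height <= 0:
        raise ValueError(
            f"line {lineno}: non-positive box side (width={width}, height={height})"
        )
    return StreamRecord(frame, obj_id, BoundingBox(left, top, width, height), conf)


def read_stream(path: str | Path) -> list[StreamRecord]:
    """Read a detection/gt/track CSV; returns records sorted by frame."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = _parse_line(line, lineno)
            if rec is not None:
                records.append(rec)
    records.sort(key=lambda r: (r.frame, r.obj_id))
    return records


def write_stream(path: str | Path, records: list[StreamRecord]) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.frame, r.obj_id)):
            b = r.box
            fh.write(
                f"{r.frame},{r.obj_id},{b.left:.2f},{b.top:.2f},"
                f"{b.width:.2f},{b.height:.2f},{r.confidence:.4f},-1,-1,-1\n"
            )


def read_detections(path: str | Path) -> dict[int, list[tuple[BoundingBox, float]]]:
    """Detections grouped by frame, as (box, confidence) lists."""
    out: dict[int, list[tuple[BoundingBox, float]]] = {}
    for r in read_stream(path):
        out.setdefault(r.frame, []).append((r.box, r.confidence))
    return out


def write_detections(
    path: str | Path, dets: dict[int, list[tuple[BoundingBox, float]]]
) -> None:
    records = [
        StreamRecord(frame, -1, box, conf)
        for frame, frame_dets in dets.items()
        for box, conf in frame_dets
    ]
    write_stream(path, records)


def read_trajectories(path: str | Path) -> TrajectorySet:
    """ID-carrying stream (gt or tracks) as a TrajectorySet."""
    ts = TrajectorySet()
    for r in read_stream(path):
        ts.add(r.frame, r.obj_id, r.box)
    return ts


def write_trajectories(
    path: str | Path, ts: TrajectorySet, confidence: float = 1.0
) -> None:
    records = [
        StreamRecord(frame, obj_id, box, confidence)
        for frame in ts.frames
        for obj_id, box in ts.boxes[frame].items()
    ]
    write_stream(path, records)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration shared across pipeline stages."""

    fps: float = 25.0
    eval_interval_frames: int = 1500
    meters_per_px: float = 0.135 / 59.0
    iou_min: float = 0.3
    min_hits: int = 3
    max_age: int = 1
    gate_iou: float = 0.5
    proximity_px: float = 128.0
    close_px: float = 59.0
    min_lifetime_s: float = 1.0
    drinker_left: float = 0.0
    drinker_top: float = 504.74
    drinker_width: float = 131.1
    drinker_height: float = 131.1
    excluded_frames: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eval_interval_frames < 1:
            raise ValueError("eval_interval_frames must be >= 1")
        if not (0 < self.iou_min < 1) or not (0 < self.gate_iou < 1):
            raise ValueError("IOU thresholds must be in (0, 1)")


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file with # comments."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in stripped.split("=", 1))
            if key not in fields:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            ftype = fields[key].type
            if key == "excluded_frames":
                values[key] = tuple(int(v) for v in raw.split()) if raw else ()
            elif ftype == "int":
                values[key] = int(raw)
            else:
                values[key] = float(raw)
    return RunConfig(**values)  # type: ignore[arg-type]


def write_config(path: str | Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write("# broilertrack run configuration\n")
        for f in dataclasses.fields(RunConfig):
            v = getattr(cfg, f.name)
            if f.name == "excluded_frames":
                v = " ".join(str(x) for x in v)
            fh.write(f"{f.name} = {v}\n")


def write_heatmap(path: str | Path, grid: np.ndarray) -> None:
    """Write a count grid as a plain-text integer matrix."""
    np.savetxt(path, grid, fmt="%d")
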