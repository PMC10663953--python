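"""Synthetic pen simulator: ground-truth broiler trajectories plus a
corrupted detection stream with the error structure a top-view detector
produces.

The simulator emulates the study pen: 39 broilers in a 1.80 × 2.61 m pen
filmed top-down at 25 fps.  Birds follow a two-state (idle/move) Markov
process with heading persistence and occasional drinker-directed excursions;
bounding boxes are fixed-size squares (two broiler radii on a side).  The
detection corrupter drops boxes at a per-frame miss rate (elevated inside the
drinker zone, where the drinker occludes birds), jitters survivors, and
injects short-lived false positives adjacent to existing birds — mimicking
detector errors from stretched legs and close proximity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .evaluation import TrajectorySet
from .geometry import BoundingBox
from .idloss import RegionMask

__all__ = [
    "PenConfig",
    "MotionParams",
    "NoiseParams",
    "simulate_trajectories",
    "corrupt_to_detections",
    "scripted_scenarios",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class PenConfig:
    """Pen geometry and recording parameters (defaults: the study pen)."""

    width_m: float = 1.80
    length_m: float = 2.61
    px_per_m: float = 437.0
    fps: float = 25.0
    duration_s: float = 60.0
    n_birds: int = 39
    bird_radius_px: float = 59.0
    drinker_rect: tuple[float, float, float, float] | None = None

    @property
    def width_px(self) -> float:
        return self.width_m * self.px_per_m

    @property
    def length_px(self) -> float:
        return self.length_m * self.px_per_m

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def drinker(self) -> tuple[float, float, float, float]:
        """Drinker zone; default a 0.30 × 0.30 m square at the midpoint of
        the long wall."""
        if self.drinker_rect is not None:
            return self.drinker_rect
        side = 0.30 * self.px_per_m
        return (0.0, self.length_px / 2 - side / 2, side, side)

    def drinker_mask(self) -> RegionMask:
        return RegionMask(rectangles=(self.drinker(),))


@dataclass(frozen=True)
class MotionParams:
    """Two-state Markov motion: mostly idle, occasional movement bursts.

    Probabilities are per second (converted to per-frame internally); speeds
    in m/s.  ``min_separation_px`` optionally enforces a hard center-to-center
    separation (used for clean, occlusion-free scenarios); by default birds
    may overlap, with a soft repulsion keeping full coincidence rare.
    """

    p_start_move: float = 0.02
    p_stop_move: float = 0.5
    speed_mean_mps: float = 0.15
    speed_sd_mps: float = 0.05
    p_drinker_visit: float = 0.3
    drink_dwell_s_mean: float = 10.0
    heading_persistence: float = 0.8
    min_separation_px: float | None = None

    @property
    def p_idle(self) -> float:
        """Per-second probability of remaining idle."""
        return 1.0 - self.p_start_move


@dataclass(frozen=True)
class NoiseParams:
    """Detector error model."""

    p_miss: float = 0.02
    p_miss_drinker: float = 0.5
    fp_rate: float = 0.05
    fp_lifetime_mean_frames: float = 2.0
    jitter_px_sd: float = 2.0
    conf_mean: float = 0.9
    conf_sd: float = 0.05
    fp_conf_low: float = 0.3
    fp_conf_high: float = 0.8


def _place_birds(pen: PenConfig, motion: MotionParams, rng: np.random.Generator):
    """Initial non-overlapping-ish placement; error if the pen cannot fit them."""
    r = pen.bird_radius_px
    sep = motion.min_separation_px if motion.min_separation_px else r
    lo_x, hi_x = r, pen.width_px - r
    lo_y, hi_y = r, pen.length_px - r
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("pen too small for a single bird")
    # crude capacity check: disks of radius sep/2 on the usable area
    usable = (hi_x - lo_x) * (hi_y - lo_y)
    if pen.n_birds * math.pi * (sep / 2) ** 2 > usable:
        raise ValueError(
            f"infeasible packing: {pen.n_birds} birds at separation {sep:.0f}px "
            "cannot fit in the pen"
        )
    centers = np.empty((pen.n_birds, 2))
    for i in range(pen.n_birds):
        for _ in range(10_000):
            c = rng.uniform([lo_x, lo_y], [hi_x, hi_y])
            if i == 0 or np.all(
                np.hypot(*(centers[:i] - c).T) >= sep
            ):
                centers[i] = c
                break
        else:
            raise ValueError("infeasible packing: placement rejection limit hit")
    return centers


def simulate_trajectories(
    pen: PenConfig = PenConfig(),
    motion: MotionParams = MotionParams(),
    seed: int = 0,
) -> TrajectorySet:
    """Simulate per-frame ground-truth boxes for every bird.

    Deterministic under a fixed seed.  Centers stay inside the pen; per-frame
    displacement never exceeds the speed cap (mean + 3 sd).
    """
    rng = np.random.default_rng(seed)
    n, fps = pen.n_birds, pen.fps
    side = 2 * pen.bird_radius_px
    r = pen.bird_radius_px
    lo = np.array([r, r])
    hi = np.array([pen.width_px - r, pen.length_px - r])

    centers = _place_birds(pen, motion, rng)
    moving = np.zeros(n, dtype=bool)
    headings = rng.uniform(0, 2 * math.pi, n)
    speeds = np.zeros(n)  # px/frame
    to_drinker = np.zeros(n, dtype=bool)
    dwell_left = np.zeros(n, dtype=int)  # frames left drinking at the drinker
    dl, dt_, dw, dh = pen.drinker()
    drinker_center = np.array([dl + dw / 2, dt_ + dh / 2])

    p_start = motion.p_start_move / fps
    p_stop = motion.p_stop_move / fps
    p_drink = motion.p_drinker_visit / (60.0 * fps)
    speed_cap = (motion.speed_mean_mps + 3 * motion.speed_sd_mps) * pen.px_per_m / fps

    out = TrajectorySet()
    for frame in range(1, pen.n_frames + 1):
        # state transitions
        dwell_left = np.maximum(dwell_left - 1, 0)
        dwelling = dwell_left > 0
        start = (~moving) & ~dwelling & (rng.random(n) < p_start)
        stop = moving & (rng.random(n) < p_stop)
        drink = ~dwelling & ~to_drinker & (rng.random(n) < p_drink)
        for i in np.flatnonzero(start | drink):
            moving[i] = True
            to_drinker[i] = to_drinker[i] or drink[i]
            speeds[i] = np.clip(
                rng.normal(motion.speed_mean_mps, motion.speed_sd_mps),
                0.01,
                motion.speed_mean_mps + 3 * motion.speed_sd_mps,
            ) * pen.px_per_m / fps
            if not to_drinker[i]:
                headings[i] = rng.uniform(0, 2 * math.pi)
        for i in np.flatnonzero(stop & ~to_drinker):
            moving[i] = False
            speeds[i] = 0.0

        # heading update
        for i in np.flatnonzero(moving):
            if to_drinker[i]:
                d = drinker_center - centers[i]
                dist = np.hypot(*d)
                if dist < side / 4:  # arrived: drink for a while, then resume
                    to_drinker[i] = False
                    moving[i] = False
                    speeds[i] = 0.0
                    dwell_left[i] = max(
                        int(rng.exponential(motion.drink_dwell_s_mean) * fps), 1
                    )
                else:
                    headings[i] = math.atan2(d[1], d[0])
            else:
                headings[i] += (1 - motion.heading_persistence) * rng.normal(0, 1.0)

        # displacement, walls, separation
        for i in range(n):
            if not moving[i]:
                continue
            step = min(speeds[i], speed_cap)
            cand = centers[i] + step * np.array(
                [math.cos(headings[i]), math.sin(headings[i])]
            )
            cand = np.clip(cand, lo, hi)
            if motion.min_separation_px is not None:
                others = np.delete(centers, i, axis=0)
                if np.any(np.hypot(*(others - cand).T) < motion.min_separation_px):
                    headings[i] = rng.uniform(0, 2 * math.pi)  # blocked: turn
                    continue
            else:
                # soft repulsion: nudge away from any bird closer than one radius
                others = np.delete(centers, i, axis=0)
                d = others - cand
                dist = np.hypot(*d.T)
                too_close = dist < r
                if np.any(too_close):
                    push = -(d[too_close] / dist[too_close, None]).sum(axis=0)
                    norm = np.hypot(*push)
                    if norm > 0:
                        cand = np.clip(cand + push / norm * 0.5 * step, lo, hi)
            centers[i] = cand

        for i in range(n):
            out.add(
                frame,
                i + 1,
                BoundingBox.from_center(centers[i][0], centers[i][1], side, side),
            )
    return out


def corrupt_to_detections(
    gt: TrajectorySet,
    noise: NoiseParams = NoiseParams(),
    pen: PenConfig = PenConfig(),
    seed: int = 0,
) -> dict[int, list[tuple[BoundingBox, float]]]:
    """Turn ground truth into a detector-like stream of (box, confidence).

    Per frame, each gt box is dropped with ``p_miss`` (``p_miss_drinker``
    inside the drinker rectangle); survivors get Gaussian center/size jitter;
    false positives spawn next to random birds with geometric lifetimes.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    drinker = pen.drinker_mask()
    r = pen.bird_radius_px
    lam = noise.fp_rate / max(noise.fp_lifetime_mean_frames, 1e-9)
    active_fps: list[dict] = []  # each: {"box", "frames_left", "conf"}

    out: dict[int, list[tuple[BoundingBox, float]]] = {}
    for frame in gt.frames:
        dets: list[tuple[BoundingBox, float]] = []
        for _, box in sorted(gt.boxes[frame].items()):
            p = noise.p_miss_drinker if drinker.contains(*box.center) else noise.p_miss
            if rng.random() < p:
                continue
            jit = rng.normal(0, noise.jitter_px_sd, 4) if noise.jitter_px_sd > 0 else np.zeros(4)
            w = max(box.width + jit[2], 1.0)
            h = max(box.height + jit[3], 1.0)
            cx, cy = box.center
            conf = float(np.clip(rng.normal(noise.conf_mean, noise.conf_sd), 0.05, 1.0))
            dets.append((BoundingBox.from_center(cx + jit[0], cy + jit[1], w, h), conf))

        # spawn false positives adjacent to existing birds
        n_new = rng.poisson(lam) if lam > 0 else 0
        birds = [b for _, b in sorted(gt.boxes[frame].items())]
        for _ in range(n_new):
            host = birds[rng.integers(len(birds))]
            ang = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(0, r)
            cx, cy = host.center
            side = rng.uniform(0.3, 0.6) * 2 * r  # leg/part-sized spurious box
            fp_box = BoundingBox.from_center(
                cx + dist * math.cos(ang), cy + dist * math.sin(ang), side, side
            )
            lifetime = rng.geometric(1.0 / max(noise.fp_lifetime_mean_frames, 1.0))
            conf = float(rng.uniform(noise.fp_conf_low, noise.fp_conf_high))
            active_fps.append({"box": fp_box, "frames_left": int(lifetime), "conf": conf})

        for fp in active_fps:
            dets.append((fp["box"], fp["conf"]))
            fp["frames_left"] -= 1
        active_fps = [fp for fp in active_fps if fp["frames_left"] > 0]
        out[frame] = dets
    return out


# ---------------------------------------------------------------------------
# Scripted deterministic scenarios with hand-traceable expected metrics
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("lone_walker", "crossing_pair", "drinker_occlusion", "nudge")


def scripted_scenarios(name: str):
    """Small deterministic scenes with known expected tracker/metric behavior.

    Returns ``(gt, detections_by_frame, expected)`` where ``gt`` is a
    TrajectorySet, detections a frame → [(box, conf)] mapping, and
    ``expected`` a dict of hand-derived outcomes the scene is built to
    produce under the default tracker configuration.
    """
    if name == "lone_walker":
        # one bird drifting right 2 px/frame for 50 frames, perfect detections
        gt = TrajectorySet()
        dets: dict[int, list[tuple[BoundingBox, float]]] = {}
        for f in range(1, 51):
            box = BoundingBox.from_center(100 + 2 * f, 200, 118, 118)
            gt.add(f, 1, box)
            dets[f] = [(box, 0.95)]
        return gt, dets, {"n_ids": 1, "id_switches": 0, "id_losses": 0}

    if name == "crossing_pair":
        # two birds walk toward each other along y=200 and y=600 (no overlap);
        # detections follow gt exactly, but the evaluation fixture swaps the
        # predicted IDs from frame 26 onward, emulating an ID exchange.
        gt = TrajectorySet()
        pred = TrajectorySet()
        dets: dict[int, list[tuple[BoundingBox, float]]] = {}
        for f in range(1, 51):
            b1 = BoundingBox.from_center(100 + 5 * f, 200, 118, 118)
            b2 = BoundingBox.from_center(500 - 5 * f, 600, 118, 118)
            gt.add(f, 1, b1)
            gt.add(f, 2, b2)
            dets[f] = [(b1, 0.95), (b2, 0.95)]
            if f < 26:
                pred.add(f, 101, b1)
                pred.add(f, 102, b2)
            else:
                pred.add(f, 102, b1)
                pred.add(f, 101, b2)
        return (
            gt,
            dets,
            {
                "swapped_pred": pred,
                "id_switches_total": 2,
                "n_tracklets": 4,
            },
        )

    if name == "drinker_occlusion":
        # one bird walks through the drinker zone at the left wall midpoint;
        # detections vanish for 2 consecutive frames inside the zone, so with
        # max_age=1 the ID dies there (one ID-loss inside the drinker rect)
        # and a new ID is born on reappearance.
        pen = PenConfig(n_birds=1, duration_s=4.0)
        dl, dt_, dw, dh = pen.drinker()
        cy = dt_ + dh / 2
        gt = TrajectorySet()
        dets = {}
        for f in range(1, 101):
            cx = 200 - 1.5 * (f - 1)  # drifts left into the drinker zone
            box = BoundingBox.from_center(max(cx, 60), cy, 118, 118)
            gt.add(f, 1, box)
            in_gap = f in (61, 62)  # occluded by the drinker for 2 frames
            dets[f] = [] if in_gap else [(box, 0.95)]
        return gt, dets, {"id_losses": 1, "loss_in_drinker": True, "pen": pen}

    if name == "nudge":
        # a walking bird is abruptly displaced by a full box width between two
        # frames (nudged by a pen-mate): prediction and detection no longer
        # overlap, the old ID dies, a new one starts — one ID-loss.
        gt = TrajectorySet()
        dets = {}
        for f in range(1, 61):
            if f < 30:
                cx, cy = 300.0 + 2 * f, 300.0
            else:
                cx, cy = 600.0, 500.0  # displaced far beyond any overlap
            box = BoundingBox.from_center(cx, cy, 118, 118)
            gt.add(f, 1, box)
            dets[f] = [(box, 0.95)]
        return gt, dets, {"id_losses": 1}

    raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
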