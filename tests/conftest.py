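import numpy as np
import pytest

from broilertrack.geometry import BoundingBox, PixelScale


@pytest.fixture
def study_scale() -> PixelScale:
    """The pen's printed scale anchor: one broiler radius, 59 px = 13.5 cm."""
    return PixelScale(0.135 / 59.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_int_box(rng: np.random.Generator, max_side: int = 50) -> BoundingBox:
    """Integer-coordinate box for pixel-counting oracles."""
    left = int(rng.integers(0, 60))
    top = int(rng.integers(0, 60))
    w = int(rng.integers(1, max_side + 1))
    h = int(rng.integers(1, max_side + 1))
    return BoundingBox(left, top, w, h)


def pixel_count_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Brute-force IOU oracle: count integer pixel cells inside each box.

    A unit pixel cell (i, j) lies in box (l, t, w, h) iff l <= i < l + w and
    t <= j < t + h; intersection and union are set counts.
    """
    cells_a = {
        (i, j)
        for i in range(int(a.left), int(a.left + a.width))
        for j in range(int(a.top), int(a.top + a.height))
    }
    cells_b = {
        (i, j)
        for i in range(int(b.left), int(b.left + b.width))
        for j in range(int(b.top), int(b.top + b.height))
    }
    inter = len(cells_a & cells_b)
    union = len(cells_a | cells_b)
    return inter / union


def brute_force_assignment(iou_mat, iou_min: float):
    """Best one-to-one assignment by exhaustive permutation search.

    Returns the set of (row, col) pairs of a maximum-total-IOU assignment
    after dissolving pairs below the gate.  Independent oracle for the
    Hungarian-based association.
    """
    import itertools

    n_r, n_c = iou_mat.shape
    best_total, best_pairs = -1.0, []
    k = min(n_r, n_c)
    for rows in itertools.permutations(range(n_r), k):
        for cols in itertools.permutations(range(n_c), k):
            total = sum(iou_mat[r, c] for r, c in zip(rows, cols))
            if total > best_total:
                best_total = total
                best_pairs = list(zip(rows, cols))
    return {(r, c) for r, c in best_pairs if iou_mat[r, c] >= iou_min}
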