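"""Independent exhaustive-scan reference implementations.

These deliberately avoid the production code paths (no distance transforms,
no morphology, no vectorised side partitions): centroids are explicit sums,
adjacency is an all-pairs distance scan, grasp points come from a per-pixel
loop.  The synthetic-scene generator derives its ground truth from these so
that generator and detector cross-validate instead of testing each other's
bugs; the test suite uses them as oracles.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

_EPS = 1e-9


def bf_centroid(raster: np.ndarray) -> Tuple[float, float]:
    rows = 0.0
    cols = 0.0
    n = 0
    for r, c in np.argwhere(np.asarray(raster, bool)):
        rows += float(r)
        cols += float(c)
        n += 1
    if n == 0:
        raise ValueError("empty mask")
    return rows / n, cols / n


def bf_boundary(raster: np.ndarray) -> List[Tuple[int, int]]:
    """Set pixels with an unset 4-neighbour (image border counts as unset)."""
    m = np.asarray(raster, bool)
    h, w = m.shape
    out = []
    for r, c in np.argwhere(m):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                out.append((int(r), int(c)))
                break
    return out


def bf_adjacency_count(fruit: np.ndarray, stem: np.ndarray, dis_thr: float) -> int:
    """All-pairs scan: stem boundary pixels with min distance to any fruit
    pixel strictly below dis_thr."""
    fpix = np.argwhere(np.asarray(fruit, bool)).astype(float)
    count = 0
    for r, c in bf_boundary(stem):
        d2 = (fpix[:, 0] - r) ** 2 + (fpix[:, 1] - c) ** 2
        if math.sqrt(float(d2.min())) < dis_thr:
            count += 1
    return count


def bf_degree(centroid_f: Tuple[float, float], centroid_s: Tuple[float, float]) -> float:
    drow = abs(centroid_f[0] - centroid_s[0])
    dcol = abs(centroid_f[1] - centroid_s[1])
    if drow == 0.0:
        return math.pi / 2
    return math.atan(dcol / drow)


def bf_grasp_points(fruit: np.ndarray, centroid_f: Tuple[float, float],
                    centroid_s: Tuple[float, float]
                    ) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Per-pixel loop over the fruit mask: on each side of the centroid line
    keep the pixel of maximum distance (strictly-greater update preserves the
    smallest-row-then-col tie-break)."""
    vertical = abs(centroid_f[1] - centroid_s[1]) <= _EPS
    if vertical:
        c_const = centroid_f[1]
    else:
        k = (centroid_f[0] - centroid_s[0]) / (centroid_f[1] - centroid_s[1])
        b = centroid_f[0] - k * centroid_f[1]
        norm = math.sqrt(1.0 + k * k)

    best_neg: Optional[Tuple[int, int]] = None
    best_pos: Optional[Tuple[int, int]] = None
    best_neg_d = best_pos_d = -1.0
    for r, c in np.argwhere(np.asarray(fruit, bool)):
        if vertical:
            s = c - c_const
            d = abs(s)
        else:
            s = r - (k * c + b)
            d = abs(s) / norm
        if s < -_EPS:
            if d > best_neg_d:
                best_neg_d = d
                best_neg = (int(r), int(c))
        elif s > _EPS:
            if d > best_pos_d:
                best_pos_d = d
                best_pos = (int(r), int(c))
    if best_neg is None or best_pos is None:
        raise ValueError("a side of the centroid line holds no fruit pixel")
    return best_neg, best_pos


def bf_cut_point(stem: np.ndarray) -> Tuple[Tuple[float, float], bool, float]:
    """Stem centroid, snapped to the nearest set pixel when off-mask."""
    m = np.asarray(stem, bool)
    cent = bf_centroid(m)
    r, c = int(round(cent[0])), int(round(cent[1]))
    h, w = m.shape
    if 0 <= r < h and 0 <= c < w and m[r, c]:
        return cent, False, 0.0
    best = None
    best_d = math.inf
    for pr, pc in np.argwhere(m):
        d = math.hypot(pr - cent[0], pc - cent[1])
        if d < best_d:
            best_d = d
            best = (float(pr), float(pc))
    return best, True, best_d
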