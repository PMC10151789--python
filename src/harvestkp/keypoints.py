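"""Grasping- and cutting-point geometry for matched fruit–stem pairs.

For a matched pair, the line l_p through the fruit centroid C_F and the stem
centroid C_S splits the fruit mask into two sides; on each side the fruit
pixel farthest from l_p is a grasping point, so a two-finger effector grips
the fruit at its widest extent perpendicular to the hanging axis.  The cutting
point is the stem mask's center of mass (optionally snapped to the nearest
stem pixel when a bent stem puts its centroid off-mask).

Lines are represented in (row, col) coordinates: an image-vertical line has
constant col (``col = c``); otherwise ``row = k * col + b``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from .exceptions import GeometryError, ValidationError
from .matching import MatchPair, centroid
from .scene_io import InstanceMask, Scene

logger = logging.getLogger(__name__)

_LINE_EPS = 1e-9


@dataclass
class CentroidLine:
    """The line l_p through a fruit centroid and its stem centroid."""

    point_f: Tuple[float, float]
    point_s: Tuple[float, float]
    form: str  # "vertical" | "sloped"
    k: Optional[float] = None  # row = k * col + b   (sloped)
    b: Optional[float] = None
    c: Optional[float] = None  # col = c             (vertical)

    def signed_eval(self, points: np.ndarray) -> np.ndarray:
        """Signed line evaluation for (n, 2) points; sign picks the side."""
        pts = np.asarray(points, dtype=float)
        if self.form == "vertical":
            return pts[:, 1] - self.c
        return pts[:, 0] - (self.k * pts[:, 1] + self.b)

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance from points to the line, in pixels."""
        s = self.signed_eval(points)
        if self.form == "vertical":
            return np.abs(s)
        return np.abs(s) / math.sqrt(1.0 + self.k * self.k)


class CutPoint(NamedTuple):
    point: Tuple[float, float]
    snapped: bool
    snap_distance: float


@dataclass
class KeypointSet:
    """Two grasping points, one cutting point, and the pair they attach to."""

    grasp_1: Tuple[int, int]
    grasp_2: Tuple[int, int]
    cut: Tuple[float, float]
    pair: Optional[MatchPair] = None
    cut_snapped: bool = False
    cut_snap_distance: float = 0.0


def centroid_line(fruit: InstanceMask, stem: InstanceMask) -> CentroidLine:
    """Exact two-point line through the fruit and stem centers of mass."""
    cf = centroid(fruit)
    cs = centroid(stem)
    if abs(cf[0] - cs[0]) <= _LINE_EPS and abs(cf[1] - cs[1]) <= _LINE_EPS:
        raise GeometryError("coincident centroids: centroid line undefined")
    if abs(cf[1] - cs[1]) <= _LINE_EPS:
        return CentroidLine(cf, cs, "vertical", c=cf[1])
    k = (cf[0] - cs[0]) / (cf[1] - cs[1])
    b = cf[0] - k * cf[1]
    return CentroidLine(cf, cs, "sloped", k=k, b=b)


def grasp_points(fruit: InstanceMask, line: CentroidLine) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Per side of the line, the fruit pixel at maximum distance from it.

    Sides are the sign of the signed line evaluation; pixels exactly on the
    line (|signed value| <= 1e-9) belong to neither side.  Ties on a side are
    broken toward the smallest row, then smallest col (row-major first
    maximiser).  Returns (negative-side point, positive-side point).
    """
    pix = fruit.pixels()  # row-major order
    s = line.signed_eval(pix)
    dist = line.distance(pix)

    points: list[Tuple[int, int]] = []
    for name, side in (("negative", s < -_LINE_EPS), ("positive", s > _LINE_EPS)):
        if not side.any():
            raise GeometryError(f"no fruit pixel on the {name} side of the centroid line")
        d = dist[side]
        best = int(np.argmax(d))  # first max in row-major order = tie-break
        points.append(tuple(int(v) for v in pix[side][best]))
    return points[0], points[1]


def cutting_point(stem: InstanceMask, snap: bool = True) -> CutPoint:
    """The stem's center of mass, the point where the cutter severs the stem.

    A curved stem can place its centroid outside the mask, which is physically
    uncuttable; with ``snap=True`` (default) such a centroid is moved to the
    nearest set pixel (ties: smallest row, then col) and the snap distance is
    reported so callers can disable or audit the adjustment.
    """
    cent = centroid(stem)
    r, c = int(round(cent[0])), int(round(cent[1]))
    h, w = stem.raster.shape
    on_mask = 0 <= r < h and 0 <= c < w and bool(stem.raster[r, c])
    if on_mask or not snap:
        return CutPoint(cent, False, 0.0)
    pix = stem.pixels().astype(float)
    d = np.hypot(pix[:, 0] - cent[0], pix[:, 1] - cent[1])
    best = int(np.argmin(d))  # first min in row-major order = tie-break
    target = (float(pix[best, 0]), float(pix[best, 1]))
    return CutPoint(target, True, float(d[best]))


def keypoints_for_pair(scene: Scene, pair: MatchPair, snap_cut: bool = True) -> KeypointSet:
    fruit = scene.fruits[pair.fruit_index]
    stem = scene.stems[pair.stem_index]
    line = centroid_line(fruit, stem)
    g1, g2 = grasp_points(fruit, line)
    cut = cutting_point(stem, snap=snap_cut)
    return KeypointSet(g1, g2, cut.point, pair=pair,
                       cut_snapped=cut.snapped, cut_snap_distance=cut.snap_distance)


def keypoints_for_scene(scene: Scene, pairs: List[MatchPair], snap_cut: bool = True) -> List[KeypointSet]:
    """One keypoint set per pair, in pair order; degenerate pairs are skipped
    with a logged warning.  Unmatched instances yield no keypoints, which is
    exactly the occlusion filter: a pumpkin showing only its fruit or only its
    stem never reaches this stage."""
    out: List[KeypointSet] = []
    for pair in pairs:
        try:
            out.append(keypoints_for_pair(scene, pair, snap_cut=snap_cut))
        except (GeometryError, ValidationError) as exc:
            logger.warning("scene %s pair %s skipped: %s", scene.image_id, pair.identity, exc)
    return out


def draw_overlay(scene: Scene, keypoint_sets: List[KeypointSet], path) -> None:
    """Annotated overlay: red cutting points, blue grasping points, yellow
    lines connecting the three points of each pumpkin."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    canvas = np.zeros((scene.height, scene.width, 3), dtype=float)
    for f in scene.fruits:
        canvas[f.raster] = (0.85, 0.55, 0.15)
    for s in scene.stems:
        canvas[s.raster] = (0.2, 0.6, 0.2)
    fig, ax = plt.subplots(figsize=(scene.width / 60, scene.height / 60))
    ax.imshow(canvas, interpolation="nearest")
    for ks in keypoint_sets:
        for g in (ks.grasp_1, ks.grasp_2):
            ax.plot([ks.cut[1], g[1]], [ks.cut[0], g[0]], color="yellow", lw=1.2)
        ax.plot(ks.grasp_1[1], ks.grasp_1[0], "o", color="blue", ms=5)
        ax.plot(ks.grasp_2[1], ks.grasp_2[0], "o", color="blue", ms=5)
        ax.plot(ks.cut[1], ks.cut[0], "o", color="red", ms=5)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
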