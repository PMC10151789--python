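"""One-to-one fruit–stem correspondence matching.

A stem belongs to a fruit when three a-priori constraints of dome-type
(trellis) cultivation hold: the two masks are adjacent, the stem's center of
mass sits above the fruit's (gravity), and each fruit takes at most one stem.
Candidate pairs that pass the adjacency and gravity gates are ranked by the
matching degree

    D = arctan(|Δcol| / |Δrow|)

of the centroid offset — 0 when the stem hangs directly above the fruit,
approaching π/2 as the offset turns horizontal — and resolved to a globally
one-to-one assignment by ascending-degree greedy selection.  The result always
satisfies K ≤ min(M, N) for M fruits and N stems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .scene_io import InstanceMask, Scene

logger = logging.getLogger(__name__)

_4CONN = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class MatchConfig:
    """Matching thresholds.

    dis_thr : float
        Adjacency distance threshold in pixels; a stem boundary pixel closer
        than this to the fruit counts as a contact point.  Default 2.0 px so a
        one-pixel gap (including diagonal contact at sqrt(2)) still counts.
    num_thr : int
        Minimum number of contact points, exclusive; a candidate needs
        ``adjacency_count > num_thr``.  Default 5: a contact segment of at
        least 6 boundary pixels is required.
    """

    dis_thr: float = 2.0
    num_thr: int = 5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dis_thr) and self.dis_thr > 0):
            raise ValidationError(f"dis_thr must be finite and > 0, got {self.dis_thr}")
        if not (isinstance(self.num_thr, (int, np.integer)) and self.num_thr >= 0):
            raise ValidationError(f"num_thr must be a non-negative integer, got {self.num_thr}")


@dataclass
class MatchPair:
    """One matched fruit–stem pair (indices into the scene's lists)."""

    fruit_index: int
    stem_index: int
    adjacency_count: int = 0
    degree: float = 0.0

    def __post_init__(self) -> None:
        if self.fruit_index < 0 or self.stem_index < 0:
            raise ValidationError("pair indices must be non-negative")
        if self.adjacency_count < 0:
            raise ValidationError("adjacency_count must be >= 0")
        if not (-1e-12 <= self.degree <= math.pi / 2 + 1e-12):
            raise ValidationError(f"degree {self.degree} outside [0, pi/2]")

    @property
    def identity(self) -> Tuple[int, int]:
        return (self.fruit_index, self.stem_index)


@dataclass
class MatchResult:
    """Pairs plus the unmatched instances (occlusion-filter report)."""

    pairs: List[MatchPair] = field(default_factory=list)
    unmatched_fruits: List[int] = field(default_factory=list)
    unmatched_stems: List[int] = field(default_factory=list)

    def __iter__(self) -> Iterator[MatchPair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


def centroid(mask: InstanceMask) -> Tuple[float, float]:
    """Center of mass of the set pixels, as subpixel (row, col).

    The arithmetic mean of the pixel coordinates; it always lies inside the
    mask's bounding box but not necessarily inside the mask itself.
    """
    raster = mask.raster if isinstance(mask, InstanceMask) else np.asarray(mask, bool)
    pix = np.argwhere(raster)
    if pix.size == 0:
        raise ValidationError("centroid of an empty mask is undefined")
    r, c = pix.mean(axis=0)
    return float(r), float(c)


def boundary_pixels(raster: np.ndarray) -> np.ndarray:
    """Set pixels with at least one unset 4-neighbour (image border counts as
    unset), in row-major order, shape (k, 2)."""
    raster = np.asarray(raster, bool)
    eroded = ndimage.binary_erosion(raster, structure=_4CONN, border_value=0)
    return np.argwhere(raster & ~eroded)


def adjacency_count(fruit: InstanceMask, stem: InstanceMask, dis_thr: float) -> int:
    """Number of stem *boundary* pixels whose Euclidean distance to the nearest
    fruit pixel is strictly below ``dis_thr``.

    The roles are asymmetric by design: the stem boundary is scanned against a
    distance transform of the fruit, which makes the count a resolution-stable
    measure of the contact zone at O(perimeter) cost.
    """
    f = fruit.raster if isinstance(fruit, InstanceMask) else np.asarray(fruit, bool)
    s = stem.raster if isinstance(stem, InstanceMask) else np.asarray(stem, bool)
    if f.shape != s.shape:
        raise ValidationError(f"canvas mismatch: fruit {f.shape} vs stem {s.shape}")
    if not f.any() or not s.any():
        raise ValidationError("adjacency_count requires two non-empty masks")
    dist_to_fruit = ndimage.distance_transform_edt(~f)
    sb = boundary_pixels(s)
    return int(np.count_nonzero(dist_to_fruit[sb[:, 0], sb[:, 1]] < dis_thr))


def matching_degree(fruit_centroid: Tuple[float, float],
                    stem_centroid: Tuple[float, float]) -> float:
    """arctan(|Δcol| / |Δrow|) between the two centroids, in [0, π/2].

    0 means the stem hangs directly above (or below) the fruit.  A zero row
    offset is a degenerate horizontal configuration; the limit value π/2 is
    returned and a warning logged.
    """
    drow = abs(fruit_centroid[0] - stem_centroid[0])
    dcol = abs(fruit_centroid[1] - stem_centroid[1])
    if drow == 0.0:
        logger.warning("matching_degree: zero row offset, returning limit pi/2")
        return math.pi / 2
    return math.atan(dcol / drow)


def match_scene(scene: Scene, config: Optional[MatchConfig] = None) -> MatchResult:
    """Match fruits to stems one-to-one.

    Two phases: (1) every (fruit, stem) pair whose stem centroid lies strictly
    above the fruit centroid (smaller row) and whose adjacency count exceeds
    ``num_thr`` becomes a candidate with its degree D; (2) candidates are
    sorted by ascending D (ties: larger adjacency count, then smaller indices)
    and accepted greedily while both instances are still free.  Unmatched
    instances — severely occluded pumpkins showing only a fruit or only a stem
    — are reported in the result so callers can filter them.
    """
    if config is None:
        config = MatchConfig()

    fruit_cents = [centroid(f) for f in scene.fruits]
    stem_cents = [centroid(s) for s in scene.stems]

    # one distance transform per fruit, shared across stems
    candidates = []
    for i, fruit in enumerate(scene.fruits):
        dist_to_fruit = ndimage.distance_transform_edt(~fruit.raster)
        for j, stem in enumerate(scene.stems):
            if not stem_cents[j][0] < fruit_cents[i][0]:  # gravity: stem above
                continue
            sb = boundary_pixels(stem.raster)
            count = int(np.count_nonzero(
                dist_to_fruit[sb[:, 0], sb[:, 1]] < config.dis_thr))
            if count > config.num_thr:
                deg = matching_degree(fruit_cents[i], stem_cents[j])
                candidates.append((deg, -count, i, j))

    candidates.sort()
    used_fruits: set[int] = set()
    used_stems: set[int] = set()
    pairs: List[MatchPair] = []
    for deg, neg_count, i, j in candidates:
        if i in used_fruits or j in used_stems:
            continue
        used_fruits.add(i)
        used_stems.add(j)
        pairs.append(MatchPair(i, j, adjacency_count=-neg_count, degree=deg))

    assert len(pairs) <= min(scene.n_fruits, scene.n_stems)
    return MatchResult(
        pairs=pairs,
        unmatched_fruits=[i for i in range(scene.n_fruits) if i not in used_fruits],
        unmatched_stems=[j for j in range(scene.n_stems) if j not in used_stems],
    )
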