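"""Synthetic harvest-scene generator with exact ground truth.

No public dataset accompanies the method, so every other module is exercised
on generated scenes that emulate the mask-level phenomena of unstructured
trellis ("dome-type") pumpkin fields: several fruits per image with stems
attached above them, unattached distractor fruits and stems, partial
occlusion by foliage (eroded masks), and optional instance overlap.

A pumpkin is an ellipse flattened in the row direction (the dome-grown fruit
is wider than tall) plus a ribbon-shaped stem whose base hugs the fruit's top
arc within a configurable angular jitter of vertical.  Occluders are disks
that bite into an instance's boundary without splitting it, degrading masks
the way leaves and branches do while the instance identity survives.

Ground-truth pairs and keypoints are derived with the independent brute-force
implementations in :mod:`harvestkp._bruteforce` (exhaustive pixel scans), not
with the production modules, so generator and detector cross-validate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from . import _bruteforce as bf
from .exceptions import PlacementError, ValidationError
from .keypoints import KeypointSet
from .matching import MatchPair
from .scene_io import ClassLabel, InstanceMask, Scene, save_scene

_MAX_TRIES = 200
#: minimum clearance (px) between distractors and everything else; well above
#: the default adjacency gate of 2 px
_SEPARATION = 8.0
#: adjacency gate the generator guarantees for attached stems (matches the
#: MatchConfig defaults dis_thr=2, num_thr=5)
_ATTACH_DIS = 2.0
_ATTACH_NUM = 5


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for one generated scene."""

    canvas: Tuple[int, int] = (192, 256)
    n_pumpkins: int = 3
    n_lone_fruits: int = 1
    n_lone_stems: int = 1
    occluder_prob: float = 0.0
    fruit_radius_range: Tuple[int, int] = (12, 22)
    stem_size_range: Tuple[int, int] = (9, 16)
    stem_angle_jitter: float = 0.15
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.canvas) < 32:
            raise ValidationError("canvas must be at least 32x32")
        if min(self.n_pumpkins, self.n_lone_fruits, self.n_lone_stems) < 0:
            raise ValidationError("instance counts must be >= 0")
        if not (0.0 <= self.occluder_prob <= 1.0):
            raise ValidationError("occluder_prob must lie in [0, 1]")
        for lo, hi in (self.fruit_radius_range, self.stem_size_range):
            if lo < 1 or hi < lo:
                raise ValidationError("size ranges must be positive and ordered")
        if self.stem_angle_jitter < 0:
            raise ValidationError("stem_angle_jitter must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth for one generated scene."""

    pairs: List[MatchPair] = field(default_factory=list)
    keypoints: List[KeypointSet] = field(default_factory=list)
    fruit_occluded: List[bool] = field(default_factory=list)
    stem_occluded: List[bool] = field(default_factory=list)


def _ellipse_mask(shape, center, r_semi, c_semi) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center[0], center[1], r_semi, c_semi, shape=shape)
    out[rr, cc] = True
    return out


def _ribbon_mask(shape, base, angle, length, width) -> np.ndarray:
    """Axis-aligned-ish ribbon: rectangle of ``length x width`` extending from
    ``base`` in direction ``angle`` off vertical-up, rasterised per pixel."""
    h, w = shape
    ur, uc = -math.cos(angle), math.sin(angle)  # along the stem, pointing up
    vr, vc = math.sin(angle), math.cos(angle)  # across the stem
    out = np.zeros(shape, dtype=bool)
    r0 = max(int(base[0] - length - width), 0)
    r1 = min(int(base[0] + length + width), h - 1)
    c0 = max(int(base[1] - length - width), 0)
    c1 = min(int(base[1] + length + width), w - 1)
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            dr, dc = r - base[0], c - base[1]
            along = dr * ur + dc * uc
            across = dr * vr + dc * vc
            if -0.5 <= along <= length and abs(across) <= width / 2.0:
                out[r, c] = True
    return out


def _far_enough(mask: np.ndarray, occupancy: np.ndarray, min_sep: float) -> bool:
    if not occupancy.any():
        return True
    dist = ndimage.distance_transform_edt(~occupancy)
    return bool(dist[mask].min() >= min_sep)


def _single_component(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask)
    return n == 1


def _apply_occluder(mask: np.ndarray, rng: np.random.Generator,
                    partner: Optional[np.ndarray] = None,
                    mask_is_fruit: bool = True) -> Optional[np.ndarray]:
    """Erode the mask with a boundary-centred disk, emulating a leaf covering
    part of the instance.

    A bite is admissible if the instance keeps at least 40% of its pixels and
    stays a single component, and — for an instance that belongs to a pair —
    if the contact zone with ``partner`` survives above the attachment gate:
    occlusion degrades mask shape (centroids, areas, keypoints all move) but
    never deletes the pair's identity.  A leaf that blots out the junction
    would turn the pumpkin into two unrelated objects; like instance-splitting
    bites, that harder phenomenon is excluded at default settings.
    Returns None when no admissible bite is found.
    """
    boundary = bf.bf_boundary(mask)
    n_before = int(mask.sum())
    eq_radius = math.sqrt(n_before / math.pi)  # bite scales with the instance
    for _ in range(10):
        r, c = boundary[rng.integers(len(boundary))]
        radius = max(2, int(round(rng.uniform(0.2, 0.45) * eq_radius)))
        bite = np.zeros_like(mask)
        rr, cc = draw_disk((r, c), radius, shape=mask.shape)
        bite[rr, cc] = True
        eroded = mask & ~bite
        if eroded.sum() < 0.4 * n_before or not _single_component(eroded):
            continue
        if partner is not None:
            fruit, stem = (eroded, partner) if mask_is_fruit else (partner, eroded)
            if bf.bf_adjacency_count(fruit, stem, _ATTACH_DIS) <= _ATTACH_NUM:
                continue
        return eroded
    return None


def _place_pumpkin(spec: SceneSpec, rng: np.random.Generator,
                   occupancy: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One fruit ellipse plus its attached stem ribbon; raises PlacementError
    after bounded retries."""
    h, w = spec.canvas
    for _ in range(_MAX_TRIES):
        a = int(rng.integers(spec.fruit_radius_range[0], spec.fruit_radius_range[1] + 1))
        b = max(6, int(round(0.72 * a)))  # flattened dome shape
        length = int(rng.integers(spec.stem_size_range[0], spec.stem_size_range[1] + 1))
        width = int(rng.integers(4, 7))
        margin_top = b + length + width + 2
        c_lo, c_hi = a + length + 2, w - a - length - 2
        if margin_top + b + 2 >= h or c_lo >= c_hi:
            continue
        r0 = int(rng.integers(margin_top, h - b - 1))
        c0 = int(rng.integers(c_lo, c_hi))
        theta = float(rng.uniform(-spec.stem_angle_jitter, spec.stem_angle_jitter))

        fruit = _ellipse_mask(spec.canvas, (r0, c0), b, a)
        # stem base 2 px inside the top arc, carved back against the fruit so
        # its lower boundary hugs the arc (a real stem base meets the rind)
        base = (r0 - b + 2.0, c0)
        stem = _ribbon_mask(spec.canvas, base, theta, length + 2, width) & ~fruit
        if not stem.any() or not _single_component(stem):
            continue
        both = fruit | stem
        if not spec.overlap_allowed and (occupancy & both).any():
            continue
        if not _far_enough(both, occupancy, 3.0):
            continue
        # guarantees: attachment passes the default gate, stem centroid above
        if bf.bf_adjacency_count(fruit, stem, _ATTACH_DIS) <= _ATTACH_NUM:
            continue
        if not bf.bf_centroid(stem)[0] < bf.bf_centroid(fruit)[0]:
            continue
        return fruit, stem
    raise PlacementError("could not place a pumpkin; canvas too small for the spec")


def _place_lone(spec: SceneSpec, rng: np.random.Generator, occupancy: np.ndarray,
                kind: ClassLabel) -> np.ndarray:
    h, w = spec.canvas
    for _ in range(_MAX_TRIES):
        if kind is ClassLabel.FRUIT:
            a = int(rng.integers(spec.fruit_radius_range[0], spec.fruit_radius_range[1] + 1))
            b = max(6, int(round(0.72 * a)))
            if 2 * b + 4 >= h or 2 * a + 4 >= w:
                continue
            r0 = int(rng.integers(b + 2, h - b - 1))
            c0 = int(rng.integers(a + 2, w - a - 1))
            mask = _ellipse_mask(spec.canvas, (r0, c0), b, a)
        else:
            length = int(rng.integers(spec.stem_size_range[0], spec.stem_size_range[1] + 1))
            width = int(rng.integers(4, 7))
            pad = length + width + 2
            if 2 * pad >= h or 2 * pad >= w:
                continue
            r0 = int(rng.integers(pad, h - pad))
            c0 = int(rng.integers(pad, w - pad))
            angle = float(rng.uniform(-0.5, 0.5))
            mask = _ribbon_mask(spec.canvas, (float(r0), float(c0)), angle, length, width)
        if not mask.any():
            continue
        if (occupancy & mask).any() or not _far_enough(mask, occupancy, _SEPARATION):
            continue
        return mask
    raise PlacementError(f"could not place a lone {kind.value}; canvas too crowded")


def _truth_keypoints(fruit: np.ndarray, stem: np.ndarray,
                     pair: MatchPair) -> Optional[KeypointSet]:
    cf = bf.bf_centroid(fruit)
    cs = bf.bf_centroid(stem)
    try:
        g1, g2 = bf.bf_grasp_points(fruit, cf, cs)
    except ValueError:
        return None
    cut, snapped, snap_d = bf.bf_cut_point(stem)
    return KeypointSet(g1, g2, cut, pair=pair, cut_snapped=snapped,
                       cut_snap_distance=snap_d)


def generate_scene(spec: SceneSpec) -> Tuple[Scene, GroundTruth]:
    """Generate one scene and its exact ground truth, reproducibly from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    occupancy = np.zeros(spec.canvas, dtype=bool)

    fruit_masks: List[np.ndarray] = []
    stem_masks: List[np.ndarray] = []
    for _ in range(spec.n_pumpkins):
        fruit, stem = _place_pumpkin(spec, rng, occupancy)
        occupancy |= fruit | stem
        fruit_masks.append(fruit)
        stem_masks.append(stem)
    for _ in range(spec.n_lone_fruits):
        mask = _place_lone(spec, rng, occupancy, ClassLabel.FRUIT)
        occupancy |= mask
        fruit_masks.append(mask)
    for _ in range(spec.n_lone_stems):
        mask = _place_lone(spec, rng, occupancy, ClassLabel.STEM)
        occupancy |= mask
        stem_masks.append(mask)

    fruit_occluded = [False] * len(fruit_masks)
    stem_occluded = [False] * len(stem_masks)
    if spec.occluder_prob > 0:
        for idx in range(len(fruit_masks)):
            if rng.random() < spec.occluder_prob:
                partner = stem_masks[idx] if idx < spec.n_pumpkins else None
                eroded = _apply_occluder(fruit_masks[idx], rng, partner=partner,
                                         mask_is_fruit=True)
                if eroded is not None:
                    fruit_masks[idx] = eroded
                    fruit_occluded[idx] = True
        for idx in range(len(stem_masks)):
            if rng.random() < spec.occluder_prob:
                partner = fruit_masks[idx] if idx < spec.n_pumpkins else None
                eroded = _apply_occluder(stem_masks[idx], rng, partner=partner,
                                         mask_is_fruit=False)
                if eroded is not None:
                    stem_masks[idx] = eroded
                    stem_occluded[idx] = True

    scene = Scene(
        spec.canvas[0], spec.canvas[1],
        fruits=[InstanceMask(ClassLabel.FRUIT, m) for m in fruit_masks],
        stems=[InstanceMask(ClassLabel.STEM, m) for m in stem_masks],
        image_id=f"synth_{spec.seed:010d}",
    )

    truth = GroundTruth(fruit_occluded=fruit_occluded, stem_occluded=stem_occluded)
    for k in range(spec.n_pumpkins):
        fruit, stem = fruit_masks[k], stem_masks[k]
        pair = MatchPair(
            k, k,
            adjacency_count=bf.bf_adjacency_count(fruit, stem, _ATTACH_DIS),
            degree=bf.bf_degree(bf.bf_centroid(fruit), bf.bf_centroid(stem)),
        )
        truth.pairs.append(pair)
        ks = _truth_keypoints(fruit, stem, pair)
        if ks is not None:
            truth.keypoints.append(ks)
    return scene, truth


# ---------------------------------------------------------------------------
# dataset emission and study conditions
# ---------------------------------------------------------------------------

def _pair_record(image_id: str, pair: MatchPair) -> dict:
    return {"image_id": image_id, "fruit_index": pair.fruit_index,
            "stem_index": pair.stem_index, "adjacency_count": pair.adjacency_count,
            "degree": pair.degree}


def _keypoint_record(image_id: str, ks: KeypointSet) -> dict:
    return {
        "image_id": image_id,
        "pair": [ks.pair.fruit_index, ks.pair.stem_index] if ks.pair else None,
        "grasp_1": [int(ks.grasp_1[0]), int(ks.grasp_1[1])],
        "grasp_2": [int(ks.grasp_2[0]), int(ks.grasp_2[1])],
        "cut": [float(ks.cut[0]), float(ks.cut[1])],
        "cut_snapped": ks.cut_snapped,
    }


def generate_dataset(spec_list: List[SceneSpec], out_dir, dialect: str = "labelme") -> dict:
    """Write one annotation file per spec plus a ground-truth manifest.

    The manifest records every file with the seed that regenerates it; the
    DERIVED regeneration contract is that re-running the seeds reproduces the
    dataset bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "json"
    manifest = {"dialect": dialect, "scenes": []}
    for spec in spec_list:
        scene, truth = generate_scene(spec)
        fname = f"{scene.image_id}.{ext}"
        save_scene(scene, out_dir / fname, dialect=dialect)
        manifest["scenes"].append({
            "file": fname,
            "image_id": scene.image_id,
            "seed": spec.seed,
            "spec": {
                "canvas": list(spec.canvas),
                "n_pumpkins": spec.n_pumpkins,
                "n_lone_fruits": spec.n_lone_fruits,
                "n_lone_stems": spec.n_lone_stems,
                "occluder_prob": spec.occluder_prob,
                "fruit_radius_range": list(spec.fruit_radius_range),
                "stem_size_range": list(spec.stem_size_range),
                "stem_angle_jitter": spec.stem_angle_jitter,
                "overlap_allowed": spec.overlap_allowed,
            },
            "pairs": [_pair_record(scene.image_id, p) for p in truth.pairs],
            "keypoints": [_keypoint_record(scene.image_id, ks) for ks in truth.keypoints],
            "fruit_occluded": truth.fruit_occluded,
            "stem_occluded": truth.stem_occluded,
        })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def study_specs(n_scenes: int, seed: int, occluder_prob: float = 0.0,
                stem_angle_jitter: float = 0.0) -> List[SceneSpec]:
    """The matching-study conditions: 1–4 pumpkins per scene plus 0–2 lone
    distractor fruits and stems, per-scene seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_scenes):
        specs.append(SceneSpec(
            n_pumpkins=int(rng.integers(1, 5)),
            n_lone_fruits=int(rng.integers(0, 3)),
            n_lone_stems=int(rng.integers(0, 3)),
            occluder_prob=occluder_prob,
            stem_angle_jitter=stem_angle_jitter,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs


def run_matching_study(n_scenes: int, seed: int, occluder_prob: float = 0.0,
                       config=None):
    """Generate the study scenes, run the matcher, and return
    (ConfusionCounts, PRResult)."""
    from .matching import match_scene
    from .metrics import match_confusion, precision_recall

    predicted = []
    truths = []
    for spec in study_specs(n_scenes, seed, occluder_prob=occluder_prob):
        scene, truth = generate_scene(spec)
        predicted.append(list(match_scene(scene, config)))
        truths.append(truth.pairs)
    counts = match_confusion(predicted, truths)
    return counts, precision_recall(counts)
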