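"""Reading, writing and rasterising fruit/stem instance annotations.

Two annotation dialects are supported: Labelme-style JSON (one polygon per
shape) and single-image COCO-style instance JSON (polygon or uncompressed
run-length segmentation).  An 8-bit indexed label-map PNG import path is
provided as an auxiliary format (0 = background, odd ids = fruit, even ids =
stem).

Coordinate convention
---------------------
All public APIs use ``(row, col)`` with row 0 at the image top and row
increasing downward.  Labelme and COCO store ``(x, y) = (col, row)``; the
conversion happens at the file boundary and nowhere else.

Rasterisation rule
------------------
A pixel belongs to a polygon iff its center (integer coordinates) is inside
under the even-odd rule or lies exactly on the polygon boundary.  The rule is
deterministic, orientation-independent and brute-force checkable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import MaskTopologyError, SceneParseError, ValidationError

logger = logging.getLogger(__name__)

_BOUNDARY_EPS = 1e-9

#: default class-name mapping applied case-insensitively on load
DEFAULT_LABEL_MAP: Mapping[str, str] = {"fruit": "fruit", "stem": "stem"}


class ClassLabel(str, Enum):
    FRUIT = "fruit"
    STEM = "stem"


@dataclass
class InstanceMask:
    """One labelled instance: a binary raster plus optional polygon and score.

    Invariants: the raster has at least one set pixel; if a polygon is stored,
    rasterising it reproduces the raster exactly; a score lies in [0, 1].
    """

    class_label: ClassLabel
    raster: np.ndarray
    polygon: Optional[np.ndarray] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.class_label = ClassLabel(self.class_label)
        raster = np.asarray(self.raster)
        if raster.ndim != 2:
            raise ValidationError(f"raster must be 2-D, got shape {raster.shape}")
        self.raster = raster.astype(bool)
        if not self.raster.any():
            raise ValidationError("instance raster has no set pixel")
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValidationError(
                    f"polygon must be an (n>=3, 2) vertex array, got {poly.shape}"
                )
            self.polygon = poly
        if self.score is not None:
            if not (0.0 <= float(self.score) <= 1.0):
                raise ValidationError(f"score {self.score} outside [0, 1]")
            self.score = float(self.score)

    @property
    def n_pixels(self) -> int:
        return int(self.raster.sum())

    def pixels(self) -> np.ndarray:
        """Set-pixel coordinates, row-major order, shape (n, 2) as (row, col)."""
        return np.argwhere(self.raster)


@dataclass
class Scene:
    """All fruit and stem instances of one image."""

    height: int
    width: int
    fruits: list = field(default_factory=list)
    stems: list = field(default_factory=list)
    image_id: str = "scene"

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("scene dimensions must be positive")
        for inst in list(self.fruits) + list(self.stems):
            if inst.raster.shape != (self.height, self.width):
                raise ValidationError(
                    f"instance raster shape {inst.raster.shape} != scene "
                    f"({self.height}, {self.width})"
                )

    @property
    def n_fruits(self) -> int:
        return len(self.fruits)

    @property
    def n_stems(self) -> int:
        return len(self.stems)


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _polygon_area(vertices: np.ndarray) -> float:
    r = vertices[:, 0]
    c = vertices[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def rasterize(polygon: Sequence[Sequence[float]], height: int, width: int) -> np.ndarray:
    """Fill a polygon onto a ``height x width`` canvas.

    A pixel is set iff its center is strictly inside the polygon under the
    even-odd rule, or lies on the boundary within 1e-9 px.  Vertices may lie
    outside the canvas; the fill is clipped.  The result is independent of the
    vertex starting index and orientation.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError(f"polygon needs >= 3 (row, col) vertices, got {verts.shape}")
    if _polygon_area(verts) < 1e-12:
        raise ValidationError("degenerate polygon with zero area")

    out = np.zeros((height, width), dtype=bool)
    r_lo = max(int(np.floor(verts[:, 0].min() - 1)), 0)
    r_hi = min(int(np.ceil(verts[:, 0].max() + 1)), height - 1)
    c_lo = max(int(np.floor(verts[:, 1].min() - 1)), 0)
    c_hi = min(int(np.ceil(verts[:, 1].max() + 1)), width - 1)
    if r_lo > r_hi or c_lo > c_hi:
        return out

    rows = np.arange(r_lo, r_hi + 1, dtype=float)
    cols = np.arange(c_lo, c_hi + 1, dtype=float)
    pr, pc = np.meshgrid(rows, cols, indexing="ij")
    pr = pr.ravel()
    pc = pc.ravel()

    a = verts
    b = np.roll(verts, -1, axis=0)
    inside = np.zeros(pr.shape, dtype=bool)
    on_edge = np.zeros(pr.shape, dtype=bool)
    for (ar, ac), (br, bc) in zip(a, b):
        # even-odd: ray cast along +col; half-open row rule avoids double
        # counting at vertices
        crosses = (ar > pr) != (br > pr)
        if crosses.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                c_int = ac + (pr - ar) * (bc - ac) / (br - ar)
            inside ^= crosses & (pc < c_int)
        # boundary inclusion: point-to-segment distance
        dr, dc = br - ar, bc - ac
        seg2 = dr * dr + dc * dc
        if seg2 < 1e-24:
            d2 = (pr - ar) ** 2 + (pc - ac) ** 2
        else:
            t = np.clip(((pr - ar) * dr + (pc - ac) * dc) / seg2, 0.0, 1.0)
            d2 = (pr - (ar + t * dr)) ** 2 + (pc - (ac + t * dc)) ** 2
        on_edge |= d2 <= _BOUNDARY_EPS**2

    grid = (inside | on_edge).reshape(len(rows), len(cols))
    out[r_lo : r_hi + 1, c_lo : c_hi + 1] = grid
    return out


def polygon_from_mask(raster: np.ndarray) -> np.ndarray:
    """Exact boundary polygon of a raster: vertices at pixel-corner half-integers.

    Rasterising the result (pixel-center rule) reproduces ``raster`` exactly.
    Raises :class:`MaskTopologyError` for multi-component or holey masks, which
    cannot be a single simple polygon.
    """
    import shapely
    from shapely.geometry import box
    from shapely.ops import unary_union

    pix = np.argwhere(np.asarray(raster, dtype=bool))
    if pix.size == 0:
        raise ValidationError("empty raster has no boundary polygon")
    squares = [box(r - 0.5, c - 0.5, r + 0.5, c + 0.5) for r, c in pix]
    union = unary_union(squares)
    if union.geom_type != "Polygon" or len(union.interiors) > 0:
        raise MaskTopologyError(
            "mask is multi-component or has holes; save it in the COCO dialect"
        )
    coords = np.asarray(union.exterior.coords)[:-1]  # drop closing duplicate
    return coords  # already (row, col)


# ---------------------------------------------------------------------------
# COCO uncompressed RLE (column-major, leading zero-run), hand-rolled since no
# pycocotools dependency is taken
# ---------------------------------------------------------------------------

def rle_encode(raster: np.ndarray) -> dict:
    flat = np.asarray(raster, dtype=bool).flatten(order="F").astype(np.int8)
    # run-length boundaries
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flat.size]))
    counts = (ends - starts).tolist()
    if flat.size and flat[0] == 1:  # counts must start with a zero-run
        counts = [0] + counts
    return {"size": [int(raster.shape[0]), int(raster.shape[1])], "counts": counts}


def rle_decode(rle: Mapping) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != h * w:
        raise SceneParseError(f"RLE 'counts' sums to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _normalize_label_map(label_map) -> Mapping[str, ClassLabel]:
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    elif isinstance(label_map, (str, Path)):
        with open(label_map) as fh:
            label_map = json.load(fh)
    return {str(k).lower(): ClassLabel(str(v).lower()) for k, v in label_map.items()}


def _read_json(path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise SceneParseError(f"{path}: malformed JSON ({exc})") from exc


def _require(doc: Mapping, key: str, path) -> object:
    if key not in doc:
        raise SceneParseError(f"{path}: missing required key '{key}'")
    return doc[key]


def load_labelme(path, label_map=None) -> Scene:
    """Load a Labelme-dialect JSON file into a :class:`Scene`.

    Labels are mapped case-insensitively through ``label_map`` (a mapping or a
    JSON file of name -> fruit|stem); shapes with unmapped labels are skipped
    with a warning.  Instance order in the file is preserved per class.
    """
    mapping = _normalize_label_map(label_map)
    doc = _read_json(path)
    height = int(_require(doc, "imageHeight", path))
    width = int(_require(doc, "imageWidth", path))
    shapes = _require(doc, "shapes", path)

    fruits: list[InstanceMask] = []
    stems: list[InstanceMask] = []
    for i, shape in enumerate(shapes):
        label = str(_require(shape, "label", path))
        points = _require(shape, "points", path)
        if shape.get("shape_type", "polygon") != "polygon":
            logger.warning("%s: shape %d is not a polygon; skipped", path, i)
            continue
        cls = mapping.get(label.lower())
        if cls is None:
            logger.warning("%s: unknown label %r on shape %d; skipped", path, label, i)
            continue
        if len(points) < 3:
            raise ValidationError(f"{path}: shape {i} polygon has < 3 vertices")
        poly = np.asarray(points, dtype=float)[:, ::-1]  # (x, y) -> (row, col)
        inst = InstanceMask(cls, rasterize(poly, height, width), polygon=poly)
        (fruits if cls is ClassLabel.FRUIT else stems).append(inst)

    image_id = str(doc.get("imagePath", Path(str(path)).stem)) or Path(str(path)).stem
    return Scene(height, width, fruits, stems, image_id=image_id)


def load_coco(path, image_id: str, label_map=None) -> Scene:
    """Load one image's instances from a COCO-style instance JSON file.

    ``image_id`` matches either the numeric id (as a string) or the image's
    ``file_name``.  Both polygon and uncompressed-RLE segmentations are
    understood; a polygon segmentation is rasterised with the package rule and
    the source polygon is retained on the instance.
    """
    mapping = _normalize_label_map(label_map)
    doc = _read_json(path)
    images = _require(doc, "images", path)
    categories = _require(doc, "categories", path)
    annotations = _require(doc, "annotations", path)

    img = None
    for entry in images:
        if str(entry.get("id")) == str(image_id) or entry.get("file_name") == image_id:
            img = entry
            break
    if img is None:
        raise KeyError(f"{path}: no image with id or file_name {image_id!r}")
    height, width = int(img["height"]), int(img["width"])

    cat_to_cls: dict[int, ClassLabel] = {}
    for cat in categories:
        cls = mapping.get(str(cat.get("name", "")).lower())
        if cls is not None:
            cat_to_cls[int(cat["id"])] = cls

    fruits: list[InstanceMask] = []
    stems: list[InstanceMask] = []
    for ann in annotations:
        if str(ann.get("image_id")) != str(img["id"]):
            continue
        cat_id = int(_require(ann, "category_id", path))
        if cat_id not in cat_to_cls:
            raise ValidationError(
                f"{path}: annotation {ann.get('id')} category {cat_id} not mapped to fruit/stem"
            )
        cls = cat_to_cls[cat_id]
        seg = _require(ann, "segmentation", path)
        polygon = None
        if isinstance(seg, Mapping):  # uncompressed RLE
            raster = rle_decode(seg)
            if raster.shape != (height, width):
                raise ValidationError(f"{path}: RLE size {seg['size']} != image size")
        else:  # list of flat [x0, y0, x1, y1, ...] rings; single ring supported
            if len(seg) != 1:
                raise ValidationError(
                    f"{path}: multi-ring polygon segmentation unsupported (annotation {ann.get('id')})"
                )
            xy = np.asarray(seg[0], dtype=float).reshape(-1, 2)
            if xy.shape[0] < 3:
                raise ValidationError(f"{path}: polygon with < 3 vertices")
            polygon = xy[:, ::-1]
            raster = rasterize(polygon, height, width)
        inst = InstanceMask(cls, raster, polygon=polygon, score=ann.get("score"))
        (fruits if cls is ClassLabel.FRUIT else stems).append(inst)

    return Scene(height, width, fruits, stems, image_id=str(image_id))


def load_labelmap_png(path, image_id: Optional[str] = None) -> Scene:
    """Auxiliary import: 8-bit indexed PNG, 0 = background, odd ids = fruit,
    even ids = stem; each distinct id is one instance."""
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValidationError(f"{path}: label map must be single-channel")
    fruits: list[InstanceMask] = []
    stems: list[InstanceMask] = []
    for value in np.unique(arr):
        if value == 0:
            continue
        cls = ClassLabel.FRUIT if value % 2 == 1 else ClassLabel.STEM
        inst = InstanceMask(cls, arr == value)
        (fruits if cls is ClassLabel.FRUIT else stems).append(inst)
    return Scene(arr.shape[0], arr.shape[1], fruits, stems,
                 image_id=image_id or Path(str(path)).stem)


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def _instance_polygon(inst: InstanceMask) -> np.ndarray:
    if inst.polygon is not None:
        return inst.polygon
    return polygon_from_mask(inst.raster)


def save_scene(scene: Scene, path, dialect: str = "labelme") -> None:
    """Write a scene so that loading it back reproduces all rasters exactly."""
    path = Path(path)
    if dialect == "labelme":
        shapes = []
        for inst in list(scene.fruits) + list(scene.stems):
            poly = _instance_polygon(inst)
            shapes.append({
                "label": inst.class_label.value,
                "points": [[float(c), float(r)] for r, c in poly],
                "shape_type": "polygon",
                "group_id": None,
                "flags": {},
            })
        doc = {
            "version": "5.2.1",
            "flags": {},
            "shapes": shapes,
            "imagePath": scene.image_id,
            "imageData": None,
            "imageHeight": scene.height,
            "imageWidth": scene.width,
        }
    elif dialect == "coco":
        annotations = []
        for k, inst in enumerate(list(scene.fruits) + list(scene.stems)):
            if inst.polygon is not None:
                seg = [np.asarray(inst.polygon)[:, ::-1].ravel().tolist()]
            else:
                seg = rle_encode(inst.raster)
            ann = {
                "id": k + 1,
                "image_id": 1,
                "category_id": 1 if inst.class_label is ClassLabel.FRUIT else 2,
                "segmentation": seg,
                "iscrowd": 0,
                "area": inst.n_pixels,
            }
            if inst.score is not None:
                ann["score"] = inst.score
            annotations.append(ann)
        doc = {
            "images": [{"id": 1, "file_name": scene.image_id,
                        "height": scene.height, "width": scene.width}],
            "annotations": annotations,
            "categories": [{"id": 1, "name": "fruit"}, {"id": 2, "name": "stem"}],
        }
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_scene(path, dialect: str = "labelme", image_id: str = "1", label_map=None) -> Scene:
    """Dialect-dispatching loader mirroring :func:`save_scene`."""
    if dialect == "labelme":
        return load_labelme(path, label_map=label_map)
    if dialect == "coco":
        return load_coco(path, image_id, label_map=label_map)
    if dialect == "labelmap_png":
        return load_labelmap_png(path)
    raise ValidationError(f"unknown dialect {dialect!r}")
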