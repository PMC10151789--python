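"""scene_io: rasterisation rule, annotation dialects, round trips."""

import itertools
import json

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

from harvestkp import (
    ClassLabel,
    InstanceMask,
    MaskTopologyError,
    Scene,
    SceneParseError,
    ValidationError,
    load_coco,
    load_labelme,
    load_labelmap_png,
    load_scene,
    polygon_from_mask,
    rasterize,
    save_scene,
)
from harvestkp.scene_io import rle_decode, rle_encode

from conftest import block_mask, disk_mask, fruit, stem


def shapely_covers_oracle(polygon, height, width):
    """Independent fill oracle: shapely 'covers' on every pixel center
    (boundary-inclusive; identical to even-odd for simple polygons)."""
    poly = ShapelyPolygon([(r, c) for r, c in polygon])
    out = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            out[r, c] = shapely.covers(poly, shapely.points(r, c))
    return out


# ---------------------------------------------------------------------------
# rasterize
# ---------------------------------------------------------------------------

def test_rasterize_triangle_matches_brute_force_oracle():
    tri = [(0, 0), (0, 4), (4, 0)]
    raster = rasterize(tri, 5, 5)
    assert raster.sum() == 15
    np.testing.assert_array_equal(raster, shapely_covers_oracle(tri, 5, 5))


def test_rasterize_full_cover_and_orientation_invariance():
    square = [(-0.5, -0.5), (-0.5, 7.5), (7.5, 7.5), (7.5, -0.5)]
    raster = rasterize(square, 8, 8)
    assert raster.all()
    np.testing.assert_array_equal(raster, rasterize(square[::-1], 8, 8))
    # starting-index invariance
    rolled = square[2:] + square[:2]
    np.testing.assert_array_equal(raster, rasterize(rolled, 8, 8))


@pytest.mark.parametrize("seed", range(6))
def test_rasterize_random_polygons_match_shapely_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 8)
    # convex-ish polygon: random points sorted by angle (simple, non-degenerate)
    pts = rng.uniform(1, 15, size=(n, 2))
    center = pts.mean(axis=0)
    order = np.argsort(np.arctan2(*(pts - center).T))
    poly = [tuple(p) for p in pts[order]]
    got = rasterize(poly, 16, 16)
    np.testing.assert_array_equal(got, shapely_covers_oracle(poly, 16, 16))


def test_rasterize_clips_out_of_canvas_vertices():
    raster = rasterize([(-10, -10), (-10, 30), (30, 30), (30, -10)], 5, 5)
    assert raster.all()


def test_rasterize_rejects_degenerate_inputs():
    with pytest.raises(ValidationError):
        rasterize([(0, 0), (1, 1)], 5, 5)
    with pytest.raises(ValidationError):
        rasterize([(0, 0), (2, 2), (4, 4)], 5, 5)  # zero area


def test_polygon_raster_round_trip_is_idempotent():
    raster = disk_mask((20, 20), (10, 9), 6)
    poly = polygon_from_mask(raster)
    re_raster = rasterize(poly, 20, 20)
    np.testing.assert_array_equal(re_raster, raster)
    # second trip is the identity
    np.testing.assert_array_equal(rasterize(polygon_from_mask(re_raster), 20, 20), raster)


def test_polygon_from_mask_rejects_multi_component():
    raster = np.zeros((10, 10), dtype=bool)
    raster[1, 1] = raster[8, 8] = True
    with pytest.raises(MaskTopologyError):
        polygon_from_mask(raster)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def test_instance_mask_validation():
    with pytest.raises(ValidationError):
        InstanceMask(ClassLabel.FRUIT, np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValidationError):
        InstanceMask(ClassLabel.FRUIT, np.ones((4, 4), dtype=bool), score=1.5)
    with pytest.raises(ValidationError):
        Scene(8, 8, fruits=[fruit(np.ones((4, 4), dtype=bool))])


# ---------------------------------------------------------------------------
# labelme
# ---------------------------------------------------------------------------

def _labelme_doc(shapes, h=20, w=20):
    return {"version": "5.2.1", "flags": {}, "shapes": shapes,
            "imagePath": "img", "imageData": None,
            "imageHeight": h, "imageWidth": w}


def _poly_shape(label, points_xy):
    return {"label": label, "points": points_xy, "shape_type": "polygon",
            "group_id": None, "flags": {}}


def test_load_labelme_counts_and_case_insensitive_labels(tmp_path):
    doc = _labelme_doc([
        _poly_shape("Fruit", [[2, 2], [8, 2], [8, 8], [2, 8]]),
        _poly_shape("STEM", [[10, 10], [14, 10], [14, 14], [10, 14]]),
    ])
    path = tmp_path / "a.json"
    path.write_text(json.dumps(doc))
    scene = load_labelme(path)
    assert (scene.n_fruits, scene.n_stems) == (1, 1)


def test_load_labelme_empty_and_unknown_labels(tmp_path, caplog):
    path = tmp_path / "b.json"
    path.write_text(json.dumps(_labelme_doc([])))
    scene = load_labelme(path)
    assert (scene.n_fruits, scene.n_stems) == (0, 0)

    doc = _labelme_doc([_poly_shape("pumpkin_box", [[0, 0], [5, 0], [5, 5]])])
    path.write_text(json.dumps(doc))
    with caplog.at_level("WARNING"):
        scene = load_labelme(path)
    assert (scene.n_fruits, scene.n_stems) == (0, 0)
    assert "pumpkin_box" in caplog.text


def test_load_labelme_axis_square_pixel_count(tmp_path):
    # 10x10 axis-aligned square: all 100 covered pixel centers under the
    # boundary-inclusive center rule (vertices ON centers add the border rows)
    doc = _labelme_doc([_poly_shape("fruit", [[3, 3], [12, 3], [12, 12], [3, 12]])])
    path = tmp_path / "c.json"
    path.write_text(json.dumps(doc))
    scene = load_labelme(path)
    assert scene.fruits[0].n_pixels == 100


def test_load_labelme_errors(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text("{not json")
    with pytest.raises(SceneParseError, match="malformed"):
        load_labelme(path)

    path.write_text(json.dumps({"imageHeight": 5, "shapes": []}))
    with pytest.raises(SceneParseError, match="imageWidth"):
        load_labelme(path)

    doc = _labelme_doc([_poly_shape("fruit", [[0, 0], [5, 5]])])
    path.write_text(json.dumps(doc))
    with pytest.raises(ValidationError, match="< 3 vertices"):
        load_labelme(path)


def test_load_labelme_is_order_stable(tmp_path):
    shapes = [_poly_shape("fruit", [[float(2 + 3 * k), 2.0], [float(4 + 3 * k), 2.0],
                                    [float(4 + 3 * k), 6.0], [float(2 + 3 * k), 6.0]])
              for k in range(4)]
    path = tmp_path / "d.json"
    path.write_text(json.dumps(_labelme_doc(shapes)))
    scene = load_labelme(path)
    first_cols = [np.argwhere(f.raster)[0, 1] for f in scene.fruits]
    assert first_cols == sorted(first_cols)


# ---------------------------------------------------------------------------
# COCO
# ---------------------------------------------------------------------------

def _coco_doc(annotations, h=20, w=20):
    return {
        "images": [{"id": 1, "file_name": "img1", "height": h, "width": w}],
        "annotations": annotations,
        "categories": [{"id": 1, "name": "fruit"}, {"id": 2, "name": "stem"}],
    }


def groupby_rle_oracle(raster):
    """Independent uncompressed-RLE encoder: itertools.groupby on the
    column-major flattening, leading zero-run."""
    flat = raster.flatten(order="F")
    counts = []
    val = False
    for key, group in itertools.groupby(flat):
        if not counts and key:
            counts.append(0)
        counts.append(len(list(group)))
        val = key
    return {"size": [raster.shape[0], raster.shape[1]], "counts": counts}


def test_load_coco_counts(tmp_path):
    sq = [[2.0, 2.0, 8.0, 2.0, 8.0, 8.0, 2.0, 8.0]]
    anns = [
        {"id": 1, "image_id": 1, "category_id": 1, "segmentation": sq},
        {"id": 2, "image_id": 1, "category_id": 1,
         "segmentation": [[10.0, 2.0, 16.0, 2.0, 16.0, 8.0, 10.0, 8.0]]},
        {"id": 3, "image_id": 1, "category_id": 2,
         "segmentation": [[2.0, 12.0, 8.0, 12.0, 8.0, 16.0, 2.0, 16.0]]},
    ]
    path = tmp_path / "coco.json"
    path.write_text(json.dumps(_coco_doc(anns)))
    scene = load_coco(path, "1")
    assert (scene.n_fruits, scene.n_stems) == (2, 1)
    # file_name lookup works too
    assert load_coco(path, "img1").n_fruits == 2


def test_coco_rle_and_polygon_encodings_agree(tmp_path):
    blob = disk_mask((20, 20), (9, 10), 5)
    poly = polygon_from_mask(blob)
    poly_xy = poly[:, ::-1].ravel().tolist()
    anns = [
        {"id": 1, "image_id": 1, "category_id": 1, "segmentation": [poly_xy]},
        {"id": 2, "image_id": 1, "category_id": 1,
         "segmentation": groupby_rle_oracle(blob)},
    ]
    path = tmp_path / "both.json"
    path.write_text(json.dumps(_coco_doc(anns)))
    scene = load_coco(path, "1")
    np.testing.assert_array_equal(scene.fruits[0].raster, blob)
    np.testing.assert_array_equal(scene.fruits[1].raster, blob)


def test_rle_codec_round_trip_matches_oracle(rng):
    for _ in range(5):
        raster = rng.random((13, 17)) < 0.4
        enc = rle_encode(raster)
        assert enc == groupby_rle_oracle(raster)
        np.testing.assert_array_equal(rle_decode(enc), raster)


def test_load_coco_errors(tmp_path):
    path = tmp_path / "coco.json"
    path.write_text(json.dumps(_coco_doc([])))
    scene = load_coco(path, "1")
    assert (scene.n_fruits, scene.n_stems) == (0, 0)
    with pytest.raises(KeyError):
        load_coco(path, "no_such_image")

    anns = [{"id": 1, "image_id": 1, "category_id": 99,
             "segmentation": [[0.0, 0.0, 5.0, 0.0, 5.0, 5.0]]}]
    path.write_text(json.dumps(_coco_doc(anns)))
    with pytest.raises(ValidationError, match="not mapped"):
        load_coco(path, "1")


# ---------------------------------------------------------------------------
# save / load round trips
# ---------------------------------------------------------------------------

def _two_by_two_scene():
    shape = (30, 30)
    return Scene(30, 30,
                 fruits=[fruit(disk_mask(shape, (20, 8), 5)),
                         fruit(disk_mask(shape, (20, 22), 5))],
                 stems=[stem(block_mask(shape, 8, 13, 6, 10)),
                        stem(block_mask(shape, 8, 13, 20, 24))],
                 image_id="rt")


@pytest.mark.parametrize("dialect", ["labelme", "coco"])
def test_save_load_round_trip_bit_identical(tmp_path, dialect):
    scene = _two_by_two_scene()
    path = tmp_path / f"scene_{dialect}.json"
    save_scene(scene, path, dialect=dialect)
    loaded = load_scene(path, dialect=dialect, image_id="rt")
    assert (loaded.n_fruits, loaded.n_stems) == (2, 2)
    for a, b in zip(scene.fruits + scene.stems, loaded.fruits + loaded.stems):
        np.testing.assert_array_equal(a.raster, b.raster)


def test_cross_dialect_round_trip(tmp_path):
    scene = _two_by_two_scene()
    p1 = tmp_path / "a.json"
    p2 = tmp_path / "b.json"
    save_scene(scene, p1, dialect="labelme")
    mid = load_scene(p1, dialect="labelme")
    save_scene(mid, p2, dialect="coco")
    final = load_scene(p2, dialect="coco", image_id="rt")
    for a, b in zip(scene.fruits + scene.stems, final.fruits + final.stems):
        np.testing.assert_array_equal(a.raster, b.raster)


def test_save_empty_scene(tmp_path):
    path = tmp_path / "empty.json"
    save_scene(Scene(10, 10, image_id="e"), path, dialect="labelme")
    scene = load_labelme(path)
    assert (scene.n_fruits, scene.n_stems) == (0, 0)


def test_labelmap_png_import(tmp_path):
    from PIL import Image

    arr = np.zeros((12, 12), dtype=np.uint8)
    arr[2:5, 2:5] = 1   # odd id -> fruit
    arr[7:10, 7:10] = 2  # even id -> stem
    path = tmp_path / "labels.png"
    Image.fromarray(arr).save(path)
    scene = load_labelmap_png(path)
    assert (scene.n_fruits, scene.n_stems) == (1, 1)
    assert scene.fruits[0].n_pixels == 9
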