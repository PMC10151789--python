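"""Shared fixtures and mask-building helpers."""

import numpy as np
import pytest

from harvestkp import ClassLabel, InstanceMask, Scene


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def block_mask(shape, r0, r1, c0, c1):
    out = np.zeros(shape, dtype=bool)
    out[r0 : r1 + 1, c0 : c1 + 1] = True
    return out


def fruit(raster, score=None):
    return InstanceMask(ClassLabel.FRUIT, raster, score=score)


def stem(raster, score=None):
    return InstanceMask(ClassLabel.STEM, raster, score=score)


def random_blob(rng, shape=(64, 64), n_seeds=4, radius_range=(4, 10)):
    """Union of a few random disks, guaranteed non-empty."""
    out = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        r = rng.integers(radius_range[1], shape[0] - radius_range[1])
        c = rng.integers(radius_range[1], shape[1] - radius_range[1])
        out |= disk_mask(shape, (r, c), rng.integers(*radius_range))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def simple_pumpkin_scene():
    """One disk fruit with a bar stem hugging its top arc, nothing else."""
    shape = (60, 60)
    f = disk_mask(shape, (40, 30), 10)
    s = block_mask(shape, 22, 31, 27, 33) & ~f  # carved against the arc
    return Scene(60, 60, [fruit(f)], [stem(s)], image_id="simple")
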