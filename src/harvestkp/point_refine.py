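"""Point-rendering inference: uncertainty-guided mask refinement.

A coarse per-instance probability map is repeatedly upsampled 2x; after each
upsampling the N grid cells whose predictions are least confident (smallest
|p - 0.5|) are re-predicted by a caller-supplied point classifier, while all
other cells keep their interpolated values.  With the defaults (7x7 start,
5 steps, N = 28*28 = 784) the map reaches 224x224.  When an intermediate level
has fewer than N cells — the 14x14 level has 196 — every cell is re-predicted.

The trained point head (an MLP over concatenated coarse- and fine-feature
vectors) is deliberately not part of this module: the predictor is a pluggable
contract, and an identity predictor plus a ground-truth oracle predictor are
shipped for testing and experimentation.

Predictor contract::

    predictor(coords, current) -> probabilities

where ``coords`` is an (n, 2) array of normalized (row, col) cell centers in
[0, 1]^2, ``current`` the (n,) interpolated probabilities at those cells, and
the return an (n,) array of probabilities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .exceptions import PredictorContractError, ValidationError

Predictor = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class ProbMap:
    """A 2-D grid of foreground probabilities for one instance."""

    values: np.ndarray
    instance_ref: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or min(vals.shape) < 1:
            raise ValidationError(f"probability map must be 2-D, got shape {vals.shape}")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValidationError("probability map values outside [0, 1]")
        self.values = vals

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class RefineSchedule:
    """Refinement schedule: start_size * upsample_factor**steps = final size.

    Defaults (7, 5 steps of x2, N = 784 points) take a 7x7 coarse prediction
    to 224x224.
    """

    start_size: int = 7
    steps: int = 5
    n_points: int = 784
    upsample_factor: int = 2

    def __post_init__(self) -> None:
        if self.start_size < 1 or self.steps < 1 or self.n_points < 1:
            raise ValidationError("schedule fields must be positive")
        if self.upsample_factor < 2:
            raise ValidationError("upsample_factor must be >= 2")

    @property
    def final_size(self) -> int:
        return self.start_size * self.upsample_factor**self.steps


def select_uncertain_points(pmap, n: int) -> np.ndarray:
    """The n grid cells with smallest |p - 0.5|, most uncertain first.

    Ties are broken by row-major scan order (stable sort on the flattened
    array).  If the map has fewer than n cells, all cells are returned.
    Returns an (k, 2) int array of (row, col) indices.
    """
    values = pmap.values if isinstance(pmap, ProbMap) else np.asarray(pmap, dtype=float)
    if n < 1:
        raise ValidationError("n must be >= 1")
    flat = np.abs(values.ravel() - 0.5)
    order = np.argsort(flat, kind="stable")[: min(n, flat.size)]
    return np.stack(np.unravel_index(order, values.shape), axis=1)


def bilinear_upsample(pmap, factor: int) -> ProbMap:
    """Bilinear upsampling with the align-corners-false convention.

    Output cell (i, j) samples the source at ((i + 0.5)/factor - 0.5,
    (j + 0.5)/factor - 0.5), clamped to the source extent; interpolation is
    separable, keeps values in [0, 1] and leaves constant maps constant.
    """
    if factor < 2:
        raise ValidationError("factor must be >= 2")
    src = pmap.values if isinstance(pmap, ProbMap) else np.asarray(pmap, dtype=np.float64)
    out = _interp_axis(src, factor, axis=0)
    out = _interp_axis(out, factor, axis=1)
    return ProbMap(np.clip(out, 0.0, 1.0),
                   instance_ref=pmap.instance_ref if isinstance(pmap, ProbMap) else "")


def _interp_axis(arr: np.ndarray, factor: int, axis: int) -> np.ndarray:
    n = arr.shape[axis]
    pos = (np.arange(n * factor) + 0.5) / factor - 0.5
    pos = np.clip(pos, 0.0, n - 1.0)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    w = pos - i0
    a0 = np.take(arr, i0, axis=axis)
    a1 = np.take(arr, i1, axis=axis)
    shape = [1, 1]
    shape[axis] = w.size
    w = w.reshape(shape)
    return a0 * (1.0 - w) + a1 * w


def identity_predictor(coords: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Returns the interpolated values unchanged; refine() with this predictor
    is bit-identical to pure repeated bilinear upsampling."""
    return current


def make_oracle_predictor(truth: np.ndarray) -> Predictor:
    """A ground-truth predictor: 1 where the normalized query falls on a set
    pixel of ``truth``, else 0.  Used to test that refinement sharpens masks."""
    truth = np.asarray(truth, dtype=bool)
    h, w = truth.shape

    def predictor(coords: np.ndarray, current: np.ndarray) -> np.ndarray:
        rows = np.clip((coords[:, 0] * h).astype(int), 0, h - 1)
        cols = np.clip((coords[:, 1] * w).astype(int), 0, w - 1)
        return truth[rows, cols].astype(np.float64)

    return predictor


def refine(coarse, predictor: Predictor, schedule: Optional[RefineSchedule] = None) -> ProbMap:
    """Iterative uncertainty-guided refinement of a coarse probability map.

    Each of ``schedule.steps`` iterations upsamples the current map by
    ``upsample_factor``, selects the ``n_points`` most uncertain cells (all
    cells when the level is smaller than that) and overwrites them with the
    predictor's outputs; untouched cells carry their interpolated values.
    """
    if schedule is None:
        schedule = RefineSchedule()
    current = coarse if isinstance(coarse, ProbMap) else ProbMap(np.asarray(coarse, dtype=float))
    expect = (schedule.start_size, schedule.start_size)
    if current.shape != expect:
        raise ValidationError(f"coarse map shape {current.shape} != schedule start {expect}")

    for _ in range(schedule.steps):
        current = bilinear_upsample(current, schedule.upsample_factor)
        pts = select_uncertain_points(current, schedule.n_points)
        h, w = current.shape
        coords = (pts + 0.5) / np.array([h, w], dtype=np.float64)
        queried = np.asarray(
            predictor(coords, current.values[pts[:, 0], pts[:, 1]]), dtype=np.float64
        )
        if queried.shape != (pts.shape[0],):
            raise PredictorContractError(
                f"predictor returned shape {queried.shape}, expected ({pts.shape[0]},)"
            )
        if queried.min() < 0.0 or queried.max() > 1.0:
            raise PredictorContractError("predictor returned probabilities outside [0, 1]")
        current.values[pts[:, 0], pts[:, 1]] = queried
    return current


def save_probmap(pmap: ProbMap, path) -> None:
    """32-bit float NPY export."""
    np.save(path, pmap.values.astype(np.float32))


def load_probmap(path, instance_ref: str = "") -> ProbMap:
    return ProbMap(np.load(path).astype(np.float64), instance_ref=instance_ref)


def threshold_to_png(pmap: ProbMap, path, threshold: float = 0.5) -> None:
    """Export the binarised map (p > threshold) as an 8-bit PNG."""
    from PIL import Image

    Image.fromarray(((pmap.values > threshold) * 255).astype(np.uint8)).save(path)
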