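"""Sliding-window completion scoring across whole images.

A window of ``fov`` pixels slides over the image with a fixed stride
(8 px at paper scale); at each position the center ``mask_side`` square is
removed, inpainted, and scored.  Scores are written over the mask footprint
— either last-writer-wins (the plain heatmap) or accumulated and divided by
coverage (the averaged heatmap).  Border bands never covered by any mask
placement, and background pixels, are marked invalid.

Metrics:

* ``MSE`` — mean squared difference between the blended completion and the
  truth over the mask, in [0, 1] intensity units;
* ``DISCR`` — softplus of the negated global-critic score of the blended
  patch (a strictly positive unrealism measure that preserves the critic's
  ranking);
* ``DMSE`` — their product, the combined abnormality metric.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import softplus
from .io_core import GrayImage
from .model import CompletionResult
from .sampler import place_mask

METRICS = ("MSE", "DISCR", "DMSE")


@dataclasses.dataclass
class Heatmap:
    values: np.ndarray            # image-aligned float grid
    valid: np.ndarray             # bool grid; False on border band / background
    metric: str
    fov: int
    mask_side: int
    stride: int


def _window_origins(extent: int, fov: int, stride: int) -> range:
    return range(0, extent - fov + 1, stride)


def _metric_values(result: CompletionResult, truth_net: np.ndarray,
                   mask: np.ndarray, global_score: float) -> dict[str, float]:
    # network domain spans [-1,1] = 2x the [0,1] intensity range, hence /4
    diff = result.blended[mask].astype(np.float64) - truth_net[mask]
    mse = float((diff ** 2).mean()) / 4.0
    discr = float(softplus(-global_score))
    return {"MSE": mse, "DISCR": discr, "DMSE": mse * discr}


def score_patch(model, masked, metric: str) -> float:
    """Inpaint one center-masked patch and score it with ``metric``."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    result = model.complete(masked)
    scores = model.criticize(result.blended,
                             result.blended[masked.spec.mask_slices()])
    vals = _metric_values(result, masked.truth_network(), masked.mask, scores.global_)
    return vals[metric]


def _sweep(model, image: GrayImage, fov: int, mask_side: int, stride: int,
           metrics: tuple[str, ...]):
    """Yield (oy, ox, mask-footprint slices, {metric: score}) per window."""
    h, w = image.height, image.width
    if h < fov or w < fov:
        raise ValueError(f"image {h}x{w} smaller than fov {fov}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    for metric in metrics:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}")
    for oy in _window_origins(h, fov, stride):
        for ox in _window_origins(w, fov, stride):
            masked = place_mask(image, (oy, ox), fov, mask_side, position="center")
            result = model.complete(masked)
            scores = model.criticize(result.blended,
                                     result.blended[masked.spec.mask_slices()])
            vals = _metric_values(result, masked.truth_network(), masked.mask, scores.global_)
            my, mx = masked.spec.mask_slices()
            foot = (slice(oy + my.start, oy + my.stop),
                    slice(ox + mx.start, ox + mx.stop))
            yield foot, {m: vals[m] for m in metrics}


def sliding_heatmaps(model, image: GrayImage, fov: int, mask_side: int,
                     stride: int = 8, metrics: tuple[str, ...] = METRICS,
                     averaged: bool = False) -> dict[str, Heatmap]:
    """Compute heatmaps for several metrics in a single sliding-window sweep.

    ``averaged=False``: each window writes its score over the mask footprint,
    later windows overwriting earlier ones.  ``averaged=True``: scores are
    accumulated on the footprint and divided per-pixel by coverage.
    """
    h, w = image.height, image.width
    values = {m: np.zeros((h, w), dtype=np.float64) for m in metrics}
    coverage = np.zeros((h, w), dtype=np.int64)
    for foot, vals in _sweep(model, image, fov, mask_side, stride, tuple(metrics)):
        coverage[foot] += 1
        for m in metrics:
            if averaged:
                values[m][foot] += vals[m]
            else:
                values[m][foot] = vals[m]
    covered = coverage > 0
    if averaged:
        for m in metrics:
            np.divide(values[m], coverage, out=values[m], where=covered)
    valid = covered & image.tissue_mask()
    return {m: Heatmap(values=values[m], valid=valid, metric=m, fov=fov,
                       mask_side=mask_side, stride=stride) for m in metrics}


def sliding_heatmap(model, image: GrayImage, fov: int, mask_side: int,
                    stride: int = 8, metric: str = "DMSE") -> Heatmap:
    """Non-averaged heatmap for one metric (footprint write, overwrite on overlap)."""
    return sliding_heatmaps(model, image, fov, mask_side, stride,
                            metrics=(metric,), averaged=False)[metric]


def averaged_heatmap(model, image: GrayImage, fov: int, mask_side: int,
                     stride: int = 8, metric: str = "DMSE") -> Heatmap:
    """Coverage-averaged heatmap for one metric."""
    return sliding_heatmaps(model, image, fov, mask_side, stride,
                            metrics=(metric,), averaged=True)[metric]
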