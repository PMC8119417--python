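"""Inside/outside error-ratio evaluation against ground-truth boxes.

For each test image the mean heatmap value over the union of its bounding
boxes (intersected with valid tissue) is divided by the mean over the
remaining valid tissue.  A mean ratio above 1 across images indicates that
completion error localizes abnormalities.  Images whose box lies within a
margin (128 px by default) of an image edge are excluded from aggregation,
as are images where either region is empty or the outside mean is zero.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .heatmap import Heatmap
from .io_core import BoundingBox, GrayImage

EDGE_EXCLUSION_MARGIN = 128


@dataclasses.dataclass
class ImageRatio:
    image_id: str
    inside_mean: float
    outside_mean: float
    ratio: float | None
    excluded: str | None = None   # reason, when the image does not aggregate


@dataclasses.dataclass
class RatioReport:
    per_image: list[ImageRatio]
    mean_ratio: float
    std_ratio: float
    metric: str
    fov: int
    mask_side: int
    n_used: int
    std_mode: str = "population"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def to_csv(self) -> str:
        lines = ["image,inside_mean,outside_mean,ratio,excluded"]
        for r in self.per_image:
            ratio = "" if r.ratio is None else f"{r.ratio:.6g}"
            lines.append(f"{r.image_id},{r.inside_mean:.6g},{r.outside_mean:.6g},"
                         f"{ratio},{r.excluded or ''}")
        return "\n".join(lines) + "\n"


def valid_region(image: GrayImage, heatmap: Heatmap) -> np.ndarray:
    """Heatmap validity restricted to strictly-positive (tissue) pixels."""
    if heatmap.values.shape != image.pixels.shape:
        raise ValueError("heatmap and image shapes disagree")
    return np.asarray(heatmap.valid, dtype=bool) & (image.pixels > 0)


def inside_outside_ratio(heatmap: Heatmap, boxes: list[BoundingBox],
                         valid: np.ndarray) -> tuple[float, float, float | None]:
    """Mean heatmap value inside the box union vs. outside, over valid pixels.

    Overlapping boxes count once (set union).  Returns
    ``(inside_mean, outside_mean, ratio)``; the ratio is None when either
    region is empty or the outside mean is zero (degenerate heatmap).
    """
    if not boxes:
        raise ValueError("need at least one bounding box")
    inside_mask = np.zeros(heatmap.values.shape, dtype=bool)
    for box in boxes:
        inside_mask[box.slices()] = True
    inside_mask &= valid
    outside_mask = valid & ~inside_mask
    n_in, n_out = int(inside_mask.sum()), int(outside_mask.sum())
    inside_mean = float(heatmap.values[inside_mask].mean()) if n_in else float("nan")
    outside_mean = float(heatmap.values[outside_mask].mean()) if n_out else float("nan")
    if n_in == 0 or n_out == 0 or outside_mean == 0.0:
        return inside_mean, outside_mean, None
    return inside_mean, outside_mean, inside_mean / outside_mean


def evaluate_image(image_id: str, image: GrayImage, heatmap: Heatmap,
                   boxes: list[BoundingBox],
                   edge_margin: int = EDGE_EXCLUSION_MARGIN) -> ImageRatio:
    """Per-image ratio with the edge-proximity exclusion applied."""
    h, w = image.height, image.width
    if any(b.min_edge_distance(h, w) < edge_margin for b in boxes):
        return ImageRatio(image_id, float("nan"), float("nan"), None,
                          excluded=f"box within {edge_margin} px of image edge")
    valid = valid_region(image, heatmap)
    inside, outside, ratio = inside_outside_ratio(heatmap, boxes, valid)
    excluded = None if ratio is not None else "degenerate region or zero outside mean"
    return ImageRatio(image_id, inside, outside, ratio, excluded=excluded)


def aggregate(results: list[ImageRatio], metric: str = "DMSE", fov: int = 0,
              mask_side: int = 0, std_mode: str = "population") -> RatioReport:
    """Mean and standard deviation of per-image ratios (excluded images skipped).

    ``std_mode`` selects the population (ddof 0, default) or sample (ddof 1)
    standard deviation.
    """
    ratios = [r.ratio for r in results if r.ratio is not None]
    if not ratios:
        raise ValueError("no image produced a defined ratio")
    ddof = 0 if std_mode == "population" else 1
    arr = np.asarray(ratios, dtype=np.float64)
    std = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
    return RatioReport(per_image=results, mean_ratio=float(arr.mean()),
                       std_ratio=std, metric=metric, fov=fov,
                       mask_side=mask_side, n_used=len(ratios), std_mode=std_mode)
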