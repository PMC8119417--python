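"""Synthetic tomosynthesis-like phantom slices.

Real reconstructed breast slices show a smooth, band-limited fibroglandular
texture inside a roughly half-elliptic tissue region, brighter curvilinear
vessels, a thin bright skin edge, and exact-zero background outside the
breast.  The phantoms here emulate exactly that statistical structure — the
premise the detector relies on is that normal tissue is abundant and
predictable while anomalies are rare, localized and texturally distinct.
Inserted anomalies are spiculated blobs of elevated intensity with a tight
bounding box, standing in for masses and architectural distortions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_core import (BoundingBox, GrayImage, Manifest, ManifestRecord,
                      write_boxes, write_image)


@dataclasses.dataclass
class PhantomParams:
    """Geometry and texture parameters of a generated slice.

    Defaults describe the desk-scale study conditions used throughout the
    package's experiments: slices large enough to train a 64-px field of
    view and to host one anomaly at least 128 px from every edge.
    """

    height: int = 352
    width: int = 352
    texture_sigma: float = 6.0       # Gaussian blur of white noise, px
    texture_low: float = 0.2
    texture_high: float = 0.8
    n_vessels: int = 4
    vessel_width: float = 2.5        # px
    vessel_contrast: float = 0.12
    skin_width: float = 3.0          # px
    anomaly_radius: tuple[float, float] = (10.0, 16.0)
    anomaly_contrast: float = 0.2
    edge_margin: int = 128           # min distance of anomaly box to image edge

    def __post_init__(self):
        if min(self.anomaly_radius) < 2:
            raise ValueError("anomaly radii must be >= 2 px")
        if self.anomaly_contrast < 0:
            raise ValueError("anomaly contrast must be >= 0")
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")


def _breast_mask(h: int, w: int) -> np.ndarray:
    """Half-ellipse tissue region flush against the left image edge."""
    yy, xx = np.mgrid[0:h, 0:w]
    a = 0.92 * w                     # horizontal semi-axis
    b = 0.46 * h                     # vertical semi-axis
    cy = h / 2.0
    return (xx / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _vessel_layer(mask: np.ndarray, params: PhantomParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Smoothed random-walk strokes rendered with a fixed-width profile."""
    h, w = mask.shape
    canvas = np.zeros((h, w), dtype=np.float64)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0 or params.n_vessels == 0:
        return canvas
    for _ in range(params.n_vessels):
        i = rng.integers(len(ys))
        y, x = float(ys[i]), float(xs[i])
        theta = rng.uniform(0, 2 * np.pi)
        n_steps = int(0.8 * max(h, w))
        for _ in range(n_steps):
            theta += rng.normal(0.0, 0.15)
            y += np.sin(theta)
            x += np.cos(theta)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w) or not mask[iy, ix]:
                break
            canvas[iy, ix] = 1.0
    # dilate to vessel width, then soften the profile
    r = max(1, int(round(params.vessel_width / 2)))
    canvas = ndimage.grey_dilation(canvas, size=(2 * r + 1, 2 * r + 1))
    canvas = ndimage.gaussian_filter(canvas, sigma=0.8)
    return np.clip(canvas, 0.0, 1.0) * params.vessel_contrast


def generate_phantom(params: PhantomParams, rng: np.random.Generator
                     ) -> tuple[GrayImage, np.ndarray]:
    """Generate one normal phantom slice and its tissue mask.

    Deterministic given the generator state.  Background is exactly zero;
    tissue intensities are strictly positive and lie in (0, 1].
    """
    h, w = params.height, params.width
    mask = _breast_mask(h, w)
    noise = rng.standard_normal((h, w))
    texture = ndimage.gaussian_filter(noise, sigma=params.texture_sigma)
    t_min, t_max = texture.min(), texture.max()
    span = params.texture_high - params.texture_low
    texture = params.texture_low + span * (texture - t_min) / max(t_max - t_min, 1e-12)

    img = texture + _vessel_layer(mask, params, rng)

    # thin bright band just inside the tissue boundary (skin edge)
    dist_in = ndimage.distance_transform_edt(mask)
    band = np.clip(1.0 - dist_in / max(params.skin_width, 1e-9), 0.0, 1.0)
    img += 0.15 * band * mask

    img = np.clip(img, 0.02, 1.0) * mask
    return GrayImage(img), mask


def _spiculated_blob(h: int, w: int, cy: float, cx: float, radius: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean blob whose radius is sinusoidally perturbed around ``radius``."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    wobble = np.zeros_like(theta)
    for k, amp in ((3, 0.18), (5, 0.12), (8, 0.08)):
        wobble += amp * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return r <= radius * (1.0 + wobble)


def insert_anomaly(image: GrayImage, tissue_mask: np.ndarray,
                   params: PhantomParams, rng: np.random.Generator
                   ) -> tuple[GrayImage, BoundingBox]:
    """Insert one spiculated high-intensity blob; return image and tight box.

    The blob center is chosen uniformly among tissue positions whose worst-case
    bounding box stays at least ``params.edge_margin`` px from every image edge
    and fully inside tissue.  Pixels outside the returned box are unchanged.
    """
    h, w = image.height, image.width
    r_lo, r_hi = params.anomaly_radius
    radius = float(rng.uniform(r_lo, r_hi))
    reach = int(np.ceil(radius * 1.4)) + 1          # max wobble amplitude 0.38

    margin = params.edge_margin + reach
    eroded = ndimage.binary_erosion(tissue_mask, iterations=reach) \
        if reach > 0 else tissue_mask
    admissible = np.zeros((h, w), dtype=bool)
    if h > 2 * margin and w > 2 * margin:
        admissible[margin:h - margin, margin:w - margin] = True
    admissible &= eroded
    ys, xs = np.nonzero(admissible)
    if len(ys) == 0:
        raise ValueError("no admissible anomaly placement for these parameters")
    i = rng.integers(len(ys))
    cy, cx = float(ys[i]), float(xs[i])

    blob = _spiculated_blob(h, w, cy, cx, radius, rng)
    blob &= tissue_mask
    pixels = image.pixels.copy()
    # distinct texture: fine-grained speckle on top of the contrast offset
    speckle = 0.25 * params.anomaly_contrast * rng.standard_normal((h, w))
    speckle = ndimage.gaussian_filter(speckle, sigma=1.0)
    pixels[blob] = np.clip(pixels[blob] + params.anomaly_contrast + speckle[blob],
                           0.0, 1.0)

    ys_b, xs_b = np.nonzero(blob)
    box = BoundingBox(x0=int(xs_b.min()), y0=int(ys_b.min()),
                      x1=int(xs_b.max()) + 1, y1=int(ys_b.max()) + 1)
    return GrayImage(pixels), box


def generate_dataset(n_normal: int, n_abnormal: int, params: PhantomParams,
                     out_dir, seed: int = 0) -> Manifest:
    """Write ``n_normal`` normal and ``n_abnormal`` single-anomaly phantoms.

    Produces 16-bit PNGs, a ``boxes.csv`` (one row per abnormal image) and a
    ``manifest.json``; byte-identical across runs with the same seed.
    """
    if n_normal < 1:
        raise ValueError("need at least one normal phantom")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    records: list[ManifestRecord] = []
    box_rows: list[tuple[str, BoundingBox]] = []
    for i in range(n_normal):
        img, _ = generate_phantom(params, rng)
        name = f"normal_{i:04d}.png"
        write_image(img, out_dir / name)
        records.append(ManifestRecord(name, "train"))
    for i in range(n_abnormal):
        img, mask = generate_phantom(params, rng)
        img, box = insert_anomaly(img, mask, params, rng)
        name = f"abnormal_{i:04d}.png"
        write_image(img, out_dir / name)
        records.append(ManifestRecord(name, "test", [box]))
        box_rows.append((name, box))
    write_boxes(box_rows, out_dir / "boxes.csv")
    manifest = Manifest(
        counts={"train": {"volumes": n_normal, "slices": n_normal},
                "test": {"volumes": n_abnormal, "slices": n_abnormal}},
        records=records)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
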