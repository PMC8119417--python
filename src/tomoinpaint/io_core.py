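"""Image, annotation, heatmap and manifest I/O.

Conventions shared by every module in the package:

* coordinates are 0-based, half-open, ``(row=y, col=x)`` indexed;
* stored image intensities live in ``[0, 1]`` with non-tissue background
  exactly 0 (the networks use ``[-1, 1]`` internally, see ``model``);
* heatmaps round-trip bit-exactly through 32-bit float TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


class ImageIOError(Exception):
    """Base class for image reading problems."""


class MultiChannelImageError(ImageIOError):
    """Raised for images with more than one channel."""


class UnsupportedBitDepthError(ImageIOError):
    """Raised for images that are not 8- or 16-bit unsigned integers."""


class DegenerateBoxError(ValueError):
    """Raised when a bounding box is empty or inverted."""


class OutOfBoundsBoxError(ValueError):
    """Raised when a bounding box exceeds the image it annotates."""


@dataclasses.dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 1] and exact-zero background."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("GrayImage requires a non-empty 2-D array")
        if px.size and (float(px.min()) < 0.0 or float(px.max()) > 1.0):
            raise ValueError("GrayImage intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def tissue_mask(self) -> np.ndarray:
        return self.pixels > 0


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open: [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise DegenerateBoxError(f"degenerate box {self}")

    def validate_within(self, height: int, width: int) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.x1 > width or self.y1 > height:
            raise OutOfBoundsBoxError(f"box {self} exceeds {height}x{width} image")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def min_edge_distance(self, height: int, width: int) -> int:
        return min(self.x0, self.y0, width - self.x1, height - self.y1)


@dataclasses.dataclass
class ManifestRecord:
    image_path: str
    split: str
    boxes: list[BoundingBox] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class Manifest:
    """Per-split accounting of patients/studies/volumes/slices plus file records."""

    counts: dict[str, dict[str, int]]
    records: list[ManifestRecord] = dataclasses.field(default_factory=list)

    @property
    def total_slices(self) -> int:
        return sum(c["slices"] for c in self.counts.values())

    @property
    def total_volumes(self) -> int:
        return sum(c["volumes"] for c in self.counts.values())

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "records": [
                {"image_path": r.image_path, "split": r.split,
                 "boxes": [dataclasses.astuple(b) for b in r.boxes]}
                for r in self.records
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        payload = json.loads(text)
        records = [
            ManifestRecord(r["image_path"], r["split"],
                           [BoundingBox(*b) for b in r["boxes"]])
            for r in payload["records"]
        ]
        return cls(counts=payload["counts"], records=records)


# Test-split volumes contribute one annotated slice each; normal splits
# contribute `slices_per_volume` random slices per volume.
_SINGLE_SLICE_SPLITS = frozenset({"test"})


def build_manifest(volume_counts: dict[str, int], slices_per_volume: int,
                   extra_counts: dict[str, dict[str, int]] | None = None) -> Manifest:
    """Compute per-split slice totals from volume counts.

    ``volume_counts`` maps split name (``train``/``validation``/``test``) to the
    number of reconstruction volumes; normal splits yield
    ``volumes * slices_per_volume`` slices while the annotated test split
    yields one slice per volume.
    """
    if slices_per_volume < 0:
        raise ValueError("slices_per_volume must be >= 0")
    counts: dict[str, dict[str, int]] = {}
    for split, n_vol in volume_counts.items():
        if n_vol < 0:
            raise ValueError(f"negative volume count for split {split!r}")
        per = 1 if split in _SINGLE_SLICE_SPLITS else slices_per_volume
        entry = {"volumes": int(n_vol), "slices": int(n_vol) * per}
        if extra_counts and split in extra_counts:
            entry.update({k: int(v) for k, v in extra_counts[split].items()})
        counts[split] = entry
    return Manifest(counts=counts)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path) -> GrayImage:
    """Read an 8- or 16-bit single-channel PNG/TIFF, rescaled to [0, 1].

    Integer value v maps to v / (2**depth - 1); zeros are preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise MultiChannelImageError(f"{path}: expected one channel, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise UnsupportedBitDepthError(f"{path}: unsupported dtype {arr.dtype}")
    return GrayImage(arr.astype(np.float64) / scale)


def write_image(image: GrayImage, path, bit_depth: int = 16) -> None:
    """Quantize [0,1] intensities to the given unsigned depth and save."""
    path = Path(path)
    if bit_depth == 16:
        arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(image.pixels * 255.0).astype(np.uint8)
    else:
        raise UnsupportedBitDepthError(f"bit depth {bit_depth} not supported")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# bounding boxes
# ---------------------------------------------------------------------------

_BOX_HEADER = ["image", "x0", "y0", "x1", "y1"]


def read_boxes(path, image_sizes: dict[str, tuple[int, int]] | None = None
               ) -> list[tuple[str, BoundingBox]]:
    """Read (image-id, box) rows from a header CSV ``image,x0,y0,x1,y1``.

    ``image_sizes`` optionally maps image id to (height, width) for bounds
    validation.  Row order is preserved.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or [c.strip() for c in lines[0].split(",")] != _BOX_HEADER:
        raise ValueError(f"{path}: expected header {','.join(_BOX_HEADER)}")
    out: list[tuple[str, BoundingBox]] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        image_id = cells[0]
        box = BoundingBox(*(int(c) for c in cells[1:5]))
        if image_sizes is not None and image_id in image_sizes:
            h, w = image_sizes[image_id]
            box.validate_within(h, w)
        out.append((image_id, box))
    return out


def write_boxes(rows, path) -> None:
    lines = [",".join(_BOX_HEADER)]
    for image_id, box in rows:
        lines.append(f"{image_id},{box.x0},{box.y0},{box.x1},{box.y1}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------

def write_heatmap(heatmap, path) -> None:
    """Save a heatmap losslessly: float32 TIFF + PNG validity mask + JSON meta."""
    path = Path(path)
    values = np.asarray(heatmap.values, dtype=np.float32)
    valid = np.asarray(heatmap.valid, dtype=bool)
    if not np.all(np.isfinite(values[valid])):
        raise ValueError("heatmap has non-finite values inside its valid region")
    tifffile.imwrite(path, values)
    Image.fromarray((valid.astype(np.uint8)) * 255).save(path.with_suffix(path.suffix + ".valid.png"))
    meta = {"metric": heatmap.metric, "fov": heatmap.fov,
            "mask_side": heatmap.mask_side, "stride": heatmap.stride}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_heatmap(path):
    from .heatmap import Heatmap  # local import: avoid cycle

    path = Path(path)
    values = tifffile.imread(path)
    valid = np.asarray(Image.open(path.with_suffix(path.suffix + ".valid.png"))) > 0
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return Heatmap(values=values, valid=valid, metric=meta["metric"],
                   fov=meta["fov"], mask_side=meta["mask_side"], stride=meta["stride"])
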