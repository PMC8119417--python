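"""Training-patch extraction and square-mask placement.

Patches are sampled uniformly over all origins whose crop overlaps breast
tissue by at least ``min_tissue`` (rejection sampling with an exhaustive
fallback so the guarantee is absolute).  Masks are solid axis-aligned
squares placed either uniformly at random inside the field of view
(training) or centered (sliding-window scoring).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_core import GrayImage

#: Mask fill value in the [-1, 1] network domain (mid-gray).
MASK_FILL = 0.0

_REJECTION_TRIES = 64


@dataclasses.dataclass(frozen=True)
class PatchSpec:
    """Location of a crop in its source image plus mask geometry."""

    origin: tuple[int, int]            # (y, x) of crop top-left in source image
    fov: int                           # square side of the crop
    mask_side: int
    mask_offset: tuple[int, int]       # (y, x) of mask top-left within the crop

    def __post_init__(self):
        oy, ox = self.mask_offset
        if not (0 < self.mask_side <= self.fov):
            raise ValueError("mask must be non-empty and fit inside the patch")
        if oy < 0 or ox < 0 or oy + self.mask_side > self.fov or ox + self.mask_side > self.fov:
            raise ValueError("mask exceeds the patch field of view")

    def mask_slices(self) -> tuple[slice, slice]:
        oy, ox = self.mask_offset
        return (slice(oy, oy + self.mask_side), slice(ox, ox + self.mask_side))


@dataclasses.dataclass(frozen=True)
class MaskedPatch:
    """A crop in [0,1] plus the binary square mask marking the removed region."""

    pixels: np.ndarray                 # fov x fov, [0, 1], ground truth
    mask: np.ndarray                   # fov x fov, bool, True = removed
    spec: PatchSpec

    def network_input(self) -> np.ndarray:
        """2-channel [-1,1] input: masked image (fill = mid-gray) and mask."""
        img = self.truth_network()
        img = np.where(self.mask, np.float32(MASK_FILL), img)
        return np.stack([img, self.mask.astype(np.float32)], axis=0)

    def truth_network(self) -> np.ndarray:
        """Ground truth in the [-1, 1] float32 network domain."""
        return (self.pixels * 2.0 - 1.0).astype(np.float32)


def tissue_fraction(patch_pixels: np.ndarray) -> float:
    """Fraction of pixels strictly greater than zero."""
    patch_pixels = np.asarray(patch_pixels)
    return float(np.count_nonzero(patch_pixels > 0)) / patch_pixels.size


class NoAdmissibleOriginError(RuntimeError):
    """No crop origin satisfies the tissue-overlap requirement."""


def _tissue_integral(image: GrayImage) -> np.ndarray:
    t = (image.pixels > 0).astype(np.int64)
    return np.pad(t, ((1, 0), (1, 0))).cumsum(0).cumsum(1)


def _fraction_grid(image: GrayImage, fov: int) -> np.ndarray:
    """tissue_fraction of every fov-crop, indexed by origin, via integral image."""
    ii = _tissue_integral(image)
    h, w = image.height, image.width
    ny, nx = h - fov + 1, w - fov + 1
    counts = (ii[fov:fov + ny, fov:fov + nx] - ii[fov:fov + ny, :nx]
              - ii[:ny, fov:fov + nx] + ii[:ny, :nx])
    return counts / float(fov * fov)


def sample_patch(image: GrayImage, fov: int, min_tissue: float,
                 rng: np.random.Generator) -> PatchSpec:
    """Uniformly sample a crop origin with tissue_fraction >= min_tissue.

    Rejection sampling over all in-bounds origins; after a bounded number of
    misses the admissible set is enumerated exactly and sampled directly, so
    a valid origin is always found when one exists.
    """
    h, w = image.height, image.width
    if h < fov or w < fov:
        raise ValueError(f"image {h}x{w} smaller than fov {fov}")
    ny, nx = h - fov + 1, w - fov + 1
    for _ in range(_REJECTION_TRIES):
        oy = int(rng.integers(ny))
        ox = int(rng.integers(nx))
        crop = image.pixels[oy:oy + fov, ox:ox + fov]
        if tissue_fraction(crop) >= min_tissue:
            return PatchSpec(origin=(oy, ox), fov=fov, mask_side=1, mask_offset=(0, 0))
    fractions = _fraction_grid(image, fov)
    ys, xs = np.nonzero(fractions >= min_tissue)
    if len(ys) == 0:
        raise NoAdmissibleOriginError(
            f"no {fov}x{fov} crop reaches tissue fraction {min_tissue}")
    i = int(rng.integers(len(ys)))
    return PatchSpec(origin=(int(ys[i]), int(xs[i])), fov=fov,
                     mask_side=1, mask_offset=(0, 0))


def place_mask(image: GrayImage, origin: tuple[int, int], fov: int,
               mask_side: int, rng: np.random.Generator | None = None,
               position: str = "random") -> MaskedPatch:
    """Crop the patch at ``origin`` and place a square mask inside it.

    ``position='random'`` draws the mask offset uniformly over all placements
    keeping the square inside the field of view; ``'center'`` uses the
    centered offset ``(fov - mask_side) // 2`` on both axes.
    """
    if mask_side > fov:
        raise ValueError(f"mask side {mask_side} exceeds fov {fov}")
    oy, ox = origin
    crop = np.asarray(image.pixels[oy:oy + fov, ox:ox + fov], dtype=np.float64)
    if crop.shape != (fov, fov):
        raise ValueError("patch exceeds image bounds")
    if position == "center":
        off = ((fov - mask_side) // 2, (fov - mask_side) // 2)
    elif position == "random":
        if rng is None:
            raise ValueError("random placement needs an rng")
        span = fov - mask_side + 1
        off = (int(rng.integers(span)), int(rng.integers(span)))
    else:
        raise ValueError(f"unknown mask position {position!r}")
    spec = PatchSpec(origin=(oy, ox), fov=fov, mask_side=mask_side, mask_offset=off)
    mask = np.zeros((fov, fov), dtype=bool)
    mask[spec.mask_slices()] = True
    return MaskedPatch(pixels=crop, mask=mask, spec=spec)


def sample_training_batch(images: list[GrayImage], fov: int,
                          mask_range: tuple[int, int], min_tissue: float,
                          batch_size: int, rng: np.random.Generator
                          ) -> list[MaskedPatch]:
    """One training batch: random image, random tissue crop, random mask.

    The mask side is drawn uniformly from the integer interval
    ``mask_range`` (inclusive) per batch element.
    """
    lo, hi = mask_range
    batch = []
    for _ in range(batch_size):
        img = images[int(rng.integers(len(images)))]
        spec = sample_patch(img, fov, min_tissue, rng)
        side = int(rng.integers(lo, hi + 1))
        batch.append(place_mask(img, spec.origin, fov, side, rng, "random"))
    return batch
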