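"""Final clean-up chain for the refined liver mask.

The refiner's raw liver (+ optional tumor) mask is polished in a fixed
order, mirroring the sequence in which each rule is motivated:

1. truncate to the slice range that contains liver foreground,
2. drop voxels with HU strictly below 0 (aerated lung near the dome),
3. keep the largest 3-D connected component,
4. per-slice closing with a disk of radius 2,
5. merge the tumor mask into the liver (tumors are liver tissue here),
6. fill enclosed holes (3-D, face connectivity),
7. whole-volume closing with a sphere of radius 3.

The result is a single connected component with no enclosed cavities
(or an empty mask, with a warning, if the input was empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import morphology
from .volume_io import BinaryMask, CTVolume, ValidationError

__all__ = [
    "PostprocessConfig",
    "merge_liver_tumor",
    "exclude_lung",
    "truncate_to_liver_slices",
    "finalize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostprocessConfig:
    lung_hu_threshold: float = 0.0  # HU, strict <
    slice_closing_radius: int = 2  # pixels, per-slice disk
    volume_closing_radius: int = 3  # voxels, 3-D sphere

    def __post_init__(self):
        if self.slice_closing_radius < 1 or self.volume_closing_radius < 1:
            raise ValidationError("closing radii must be >= 1")


def merge_liver_tumor(liver: BinaryMask, tumor: BinaryMask | None) -> BinaryMask:
    """Voxelwise union of liver and tumor masks; absent tumor is a no-op."""
    if tumor is None:
        return liver
    if tumor.shape != liver.shape:
        raise ValidationError(
            f"tumor mask shape {tumor.shape} does not match liver {liver.shape}"
        )
    return BinaryMask(liver.mask | tumor.mask, liver.spacing)


def exclude_lung(mask: BinaryMask, vol: CTVolume,
                 cfg: PostprocessConfig | None = None) -> BinaryMask:
    """Remove mask voxels whose HU is strictly below the lung threshold.

    A voxel at exactly the threshold (0 HU) is retained. Idempotent.
    """
    cfg = cfg or PostprocessConfig()
    if vol.shape != mask.shape:
        raise ValidationError(
            f"volume shape {vol.shape} does not match mask {mask.shape}"
        )
    return BinaryMask(mask.mask & ~(vol.voxels < cfg.lung_hu_threshold), mask.spacing)


def truncate_to_liver_slices(mask: BinaryMask) -> tuple[BinaryMask, tuple[int, int] | None]:
    """Zero slices outside [first, last] slice containing foreground.

    Returns the truncated mask and the inclusive slice range (None if the
    mask is empty, with a warning).
    """
    per_slice = np.any(mask.mask, axis=(0, 1))
    idx = np.flatnonzero(per_slice)
    if idx.size == 0:
        log.warning("truncate_to_liver_slices: empty mask, empty slice range")
        return BinaryMask(mask.mask.copy(), mask.spacing), None
    first, last = int(idx[0]), int(idx[-1])
    out = np.zeros_like(mask.mask)
    out[:, :, first:last + 1] = mask.mask[:, :, first:last + 1]
    return BinaryMask(out, mask.spacing), (first, last)


def finalize(mask: BinaryMask, vol: CTVolume, cfg: PostprocessConfig | None = None,
             tumor: BinaryMask | None = None,
             collect: dict | None = None) -> BinaryMask:
    """Run the full clean-up chain; see module docstring for stage order.

    ``collect``, when given a dict, receives every intermediate mask keyed by
    stage name for auditing.
    """
    cfg = cfg or PostprocessConfig()
    if vol.shape != mask.shape:
        raise ValidationError(
            f"volume shape {vol.shape} does not match mask {mask.shape}"
        )
    if not mask.mask.any():
        log.warning("finalize: empty input mask, returning empty output")
        if collect is not None:
            collect["input"] = mask
        return BinaryMask(mask.mask.copy(), mask.spacing)

    def keep(name, m):
        if collect is not None:
            collect[name] = m
        return m

    m, _slice_range = truncate_to_liver_slices(mask)
    m = keep("truncate", m)
    m = keep("exclude_lung", exclude_lung(m, vol, cfg))
    m = keep("keep_largest", BinaryMask(morphology.keep_largest(m.mask), m.spacing))
    m = keep("slice_closing", BinaryMask(
        morphology.close_mask(m.mask, morphology.disk(cfg.slice_closing_radius)),
        m.spacing))
    m = keep("merge_tumor", merge_liver_tumor(m, tumor))
    m = keep("fill_holes", BinaryMask(morphology.fill_holes(m.mask), m.spacing))
    m = keep("volume_closing", BinaryMask(
        morphology.close_mask(m.mask, morphology.sphere(cfg.volume_closing_radius)),
        m.spacing))
    return m
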