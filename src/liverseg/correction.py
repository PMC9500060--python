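"""Pre-refinement oversegmentation corrections.

Three knowledge-based edits are applied to the CT volume before it is handed
to the liver-refinement segmenter:

1. **Organ knock-out** — voxels labelled spleen or stomach by the initial
   multi-organ segmentation are replaced with -100 HU, so the refiner cannot
   bleed into organs of similar attenuation.
2. **Ascites removal** — a 3-D mask of all voxels strictly below 15 HU
   (inclusive of ascites and peritoneal fat) is opened per axial slice with
   a disk of radius 2 and filtered to components strictly larger than
   1500 pixels per slice; masked voxels are set to -100 HU.
3. **Bounding box** — the tightest axis-aligned box around the initial liver
   label (optionally expanded by a margin and clipped to the grid) defines
   the crop handed to the refiner.

The knockout value (-100 HU) sits below the fluid threshold, so corrections
are idempotent: re-applying them changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import morphology
from .volume_io import BinaryMask, CTVolume, LabelMask, ValidationError

__all__ = [
    "CorrectionConfig",
    "BoundingBox",
    "remove_organs",
    "build_ascites_mask",
    "apply_ascites_correction",
    "liver_bounding_box",
]


@dataclass(frozen=True)
class CorrectionConfig:
    """Tunable constants of the correction stage (defaults are the method's)."""

    ascites_threshold: float = 15.0  # HU, strict <
    opening_radius: int = 2  # pixels, per-slice disk
    min_fluid_area: int = 1500  # pixels, strict >, per slice
    knockout_value: float = -100.0  # HU
    organs_to_remove: tuple[str, ...] = ("spleen", "stomach")
    bbox_margin: int = 0  # voxels per side

    def __post_init__(self):
        if self.opening_radius < 1:
            raise ValidationError("opening_radius must be >= 1")
        if self.min_fluid_area < 0:
            raise ValidationError("min_fluid_area must be >= 0")
        if self.bbox_margin < 0:
            raise ValidationError("bbox_margin must be >= 0")
        if not self.knockout_value < self.ascites_threshold:
            raise ValidationError(
                "knockout_value must lie below ascites_threshold so removed "
                "voxels cannot re-enter the fluid mask"
            )
        object.__setattr__(self, "organs_to_remove", tuple(self.organs_to_remove))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with inclusive per-axis index bounds."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(h < l for l, h in zip(self.lo, self.hi)):
            raise ValidationError(f"degenerate bounding box {self.lo}..{self.hi}")
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))


def _check_aligned(vol: CTVolume, seg) -> None:
    if seg.shape != vol.shape:
        raise ValidationError(
            f"segmentation shape {seg.shape} does not match volume shape {vol.shape}"
        )


def remove_organs(vol: CTVolume, initial_seg: LabelMask,
                  cfg: CorrectionConfig | None = None) -> CTVolume:
    """Replace voxels of the listed organ labels with the knockout HU value.

    All other voxels are bit-identical to the input.
    """
    cfg = cfg or CorrectionConfig()
    _check_aligned(vol, initial_seg)
    for organ in cfg.organs_to_remove:
        if organ not in initial_seg.label_map:
            raise ValidationError(
                f"organ {organ!r} not present in label_map "
                f"(has {sorted(initial_seg.label_map)})"
            )
    out = vol.voxels.astype(np.float64, copy=True)
    for organ in cfg.organs_to_remove:
        out[initial_seg.labels == initial_seg.label_map[organ]] = cfg.knockout_value
    return CTVolume(out, vol.spacing, vol.origin)


def build_ascites_mask(vol: CTVolume, cfg: CorrectionConfig | None = None) -> BinaryMask:
    """Fluid mask: strict HU threshold, per-slice opening, per-slice area filter.

    ``mask = area_filter(open_per_slice(HU < threshold, disk(r)), min_area)``.
    The mask is inclusive of any low-attenuation tissue (peritoneal fat, gut
    fluid, aerated lung); this is intentional — those voxels are never liver.
    """
    cfg = cfg or CorrectionConfig()
    thresholded = vol.voxels < cfg.ascites_threshold
    opened = morphology.open_mask(thresholded, morphology.disk(cfg.opening_radius))
    filtered = morphology.filter_by_area(opened, cfg.min_fluid_area, per_slice=True)
    return BinaryMask(filtered, vol.spacing)


def apply_ascites_correction(vol: CTVolume, cfg: CorrectionConfig | None = None
                             ) -> tuple[CTVolume, BinaryMask]:
    """Set every fluid-mask voxel to the knockout value; return volume and mask.

    Idempotent: the knockout value is itself below the fluid threshold, so a
    second application reproduces the same mask and changes zero voxels.
    """
    cfg = cfg or CorrectionConfig()
    mask = build_ascites_mask(vol, cfg)
    out = vol.voxels.astype(np.float64, copy=True)
    out[mask.mask] = cfg.knockout_value
    return CTVolume(out, vol.spacing, vol.origin), mask


def liver_bounding_box(initial_seg: LabelMask, margin: int = 0) -> BoundingBox:
    """Tightest box around the liver label, expanded by ``margin``, clipped."""
    liver = initial_seg.mask_for("liver").mask
    if not liver.any():
        raise ValidationError("no liver found by initial segmenter")
    lo, hi = [], []
    for axis in range(3):
        proj = np.any(liver, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo.append(max(0, int(idx[0]) - margin))
        hi.append(min(liver.shape[axis] - 1, int(idx[-1]) + margin))
    return BoundingBox(tuple(lo), tuple(hi))
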