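"""Binary morphological primitives for mask clean-up.

These are lattice operations: spacing is deliberately ignored, structuring
element radii are in pixels/voxels (isotropic in index space). A 2-D disk
element is applied slice-by-slice along the slice (last) axis; a 3-D sphere
element acts on the whole grid. Out-of-bounds is background everywhere.

Digital disks/spheres use the Euclidean rasterization ``||p||_2 <= r`` on
integer offsets: a disk of radius 2 has 13 pixels, a sphere of radius 3 has
123 voxels.

The heavy lifting is delegated to ``scipy.ndimage``; this module pins the
conventions (element shape, connectivity, tie-breaking, border handling)
that the correction and post-processing stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, ValidationError

__all__ = [
    "StructuringElement",
    "disk",
    "sphere",
    "erode",
    "dilate",
    "open_mask",
    "close_mask",
    "connected_components",
    "filter_by_area",
    "keep_largest",
    "fill_holes",
]

Connectivity = Literal["face", "full"]


@dataclass(frozen=True)
class StructuringElement:
    """A digital disk (2-D, per-slice) or sphere (3-D) of integer radius."""

    kind: Literal["disk2d", "sphere3d"]
    radius: int

    def __post_init__(self):
        if self.kind not in ("disk2d", "sphere3d"):
            raise ValidationError(f"unknown structuring element kind {self.kind!r}")
        if int(self.radius) < 1 or self.radius != int(self.radius):
            raise ValidationError(f"radius must be a positive integer, got {self.radius!r}")
        object.__setattr__(self, "radius", int(self.radius))

    @property
    def ndim(self) -> int:
        return 2 if self.kind == "disk2d" else 3

    @property
    def offsets(self) -> np.ndarray:
        """Integer offsets from the center with ``||p||_2 <= radius``; symmetric."""
        r = self.radius
        axes = np.meshgrid(*([np.arange(-r, r + 1)] * self.ndim), indexing="ij")
        keep = sum(a**2 for a in axes) <= r * r
        return np.stack([a[keep] for a in axes], axis=1)

    def footprint(self, grid_ndim: int) -> np.ndarray:
        """Boolean footprint embedded for a ``grid_ndim``-dimensional grid."""
        r = self.radius
        axes = np.meshgrid(*([np.arange(-r, r + 1)] * self.ndim), indexing="ij")
        fp = sum(a**2 for a in axes) <= r * r
        if self.kind == "disk2d" and grid_ndim == 3:
            return fp[:, :, None]  # per-slice: no reach along the slice axis
        if self.kind == "sphere3d" and grid_ndim == 2:
            raise ValidationError("a 3-D sphere element cannot act on a 2-D grid")
        if grid_ndim != fp.ndim:
            raise ValidationError(
                f"{self.kind} element cannot act on a {grid_ndim}-D grid"
            )
        return fp


def disk(radius: int) -> StructuringElement:
    """Per-slice digital disk; radius 2 covers 13 pixels."""
    return StructuringElement("disk2d", radius)


def sphere(radius: int) -> StructuringElement:
    """Whole-grid digital sphere; radius 3 covers 123 voxels."""
    return StructuringElement("sphere3d", radius)


def _unwrap(mask):
    if isinstance(mask, BinaryMask):
        return mask.mask, mask
    return np.asarray(mask, dtype=bool), None


def _wrap(arr: np.ndarray, src):
    if src is not None:
        return replace(src, mask=arr)
    return arr


def erode(mask, se: StructuringElement):
    """Voxel kept iff the element translated there fits inside the foreground."""
    arr, src = _unwrap(mask)
    out = ndimage.binary_erosion(arr, structure=se.footprint(arr.ndim), border_value=0)
    return _wrap(out, src)


def dilate(mask, se: StructuringElement):
    """Voxel set iff any element offset from it hits the input foreground."""
    arr, src = _unwrap(mask)
    out = ndimage.binary_dilation(arr, structure=se.footprint(arr.ndim), border_value=0)
    return _wrap(out, src)


def open_mask(mask, se: StructuringElement):
    """Morphological opening (erode then dilate): removes small objects."""
    arr, src = _unwrap(mask)
    fp = se.footprint(arr.ndim)
    out = ndimage.binary_dilation(
        ndimage.binary_erosion(arr, structure=fp, border_value=0),
        structure=fp,
        border_value=0,
    )
    return _wrap(out, src)


def close_mask(mask, se: StructuringElement):
    """Morphological closing (dilate then erode): fills small holes.

    The composition is evaluated on the background-padded (infinite) domain:
    the intermediate dilation may extend past the grid, and discarding that
    overhang before eroding would clip a border band and break extensivity.
    Padding by the radius keeps the out-of-bounds-is-background convention
    while making closing extensive and idempotent everywhere.
    """
    arr, src = _unwrap(mask)
    fp = se.footprint(arr.ndim)
    r = se.radius
    pad = tuple((0, 0) if fp.shape[a] == 1 else (r, r) for a in range(arr.ndim))
    padded = np.pad(arr, pad, constant_values=False)
    out = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=fp, border_value=0),
        structure=fp,
        border_value=0,
    )
    crop = tuple(slice(p[0], out.shape[a] - p[1] if p[1] else None)
                 for a, p in enumerate(pad))
    return _wrap(np.ascontiguousarray(out[crop]), src)


def _structure(ndim: int, connectivity: Connectivity) -> np.ndarray:
    if connectivity not in ("face", "full"):
        raise ValidationError(f"unknown connectivity {connectivity!r}")
    return ndimage.generate_binary_structure(ndim, ndim if connectivity == "full" else 1)


def connected_components(mask, connectivity: Connectivity = "full"):
    """Label connected components, largest first.

    Returns ``(labels, counts)`` where labels run 1..K by decreasing voxel
    count; ties are broken by the smallest lexicographic (flat-index) seed
    voxel. ``connectivity="full"`` is the 26-neighbourhood in 3-D (8 in 2-D),
    ``"face"`` the 6-neighbourhood (4 in 2-D).
    """
    arr, _ = _unwrap(mask)
    lab, n = ndimage.label(arr, structure=_structure(arr.ndim, connectivity))
    if n == 0:
        return lab, np.zeros(0, dtype=np.int64)
    flat = lab.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(flat.size))
    order = sorted(range(1, n + 1), key=lambda l: (-counts[l - 1], first[l]))
    remap = np.zeros(n + 1, dtype=lab.dtype)
    for rank, l in enumerate(order, start=1):
        remap[l] = rank
    return remap[lab], counts[[l - 1 for l in order]]


def filter_by_area(mask, min_area: int, per_slice: bool = True,
                   connectivity: Connectivity = "full"):
    """Keep only components strictly larger than ``min_area``.

    With ``per_slice=True`` components are computed on each axial slice
    independently (2-D, 8-neighbourhood by default), matching a per-image
    area filter; otherwise components are 3-D.
    """
    if min_area < 0:
        raise ValidationError(f"min_area must be >= 0, got {min_area}")
    arr, src = _unwrap(mask)
    if per_slice and arr.ndim == 3:
        s2 = _structure(2, connectivity)
        s3 = np.zeros((3, 3, 3), dtype=bool)
        s3[:, :, 1] = s2  # in-plane adjacency only: slices stay independent
        lab, n = ndimage.label(arr, structure=s3)
    else:
        lab, n = ndimage.label(arr, structure=_structure(arr.ndim, connectivity))
    if n == 0:
        return _wrap(arr.copy(), src)
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    keep = counts > min_area
    keep[0] = False
    return _wrap(keep[lab], src)


def keep_largest(mask, connectivity: Connectivity = "full"):
    """Retain only the largest component (ties: smallest lexicographic seed)."""
    arr, src = _unwrap(mask)
    lab, counts = connected_components(arr, connectivity)
    if counts.size == 0:
        return _wrap(arr.copy(), src)
    return _wrap(lab == 1, src)


def fill_holes(mask):
    """Fill background cavities not face-connected to the grid boundary (3-D)."""
    arr, src = _unwrap(mask)
    out = ndimage.binary_fill_holes(arr)
    return _wrap(out, src)
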