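"""Reading, writing and orientation standardization of CT volumes and masks.

Canonical in-memory layout
--------------------------
All 3-D grids in this package are indexed ``[row, col, slice]`` with the
slice axis along physical z, slices ordered by ascending z. Spacing is
``(d_row, d_col, d_slice)`` in millimetres and coordinates are 0-based.
Voxel values are Hounsfield Units (HU); DICOM rescale slope/intercept is
always applied on load, MHD and NIfTI data are assumed to already be in HU.

Supported input formats: DICOM series directories, MHD/RAW pairs and NIfTI
(``.nii`` / ``.nii.gz``). Output is NIfTI only. Label masks are written with
a JSON sidecar (``<path>.labels.json``) holding the name-to-integer map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "LabelMask",
    "BinaryMask",
    "VolumeIOError",
    "ValidationError",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "standardize_orientation",
    "destandardize_orientation",
]

Spacing = tuple[float, float, float]
Triple = tuple[float, float, float]


class VolumeIOError(IOError):
    """Raised when a volume or mask cannot be read or written."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def _checked_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValidationError(f"spacing must have 3 components, got {spacing!r}")
    if any((not math.isfinite(s)) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing components must be finite and > 0, got {spacing!r}")
    return spacing


def _checked_grid(arr: np.ndarray, what: str) -> np.ndarray:
    if arr.ndim != 3 or min(arr.shape) < 1:
        raise ValidationError(f"{what} must be a non-empty 3-D array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT grid in HU with per-axis spacing (mm) and a world origin (mm)."""

    voxels: np.ndarray
    spacing: Spacing
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = _checked_grid(np.asarray(self.voxels), "voxels")
        if not np.issubdtype(vox.dtype, np.number):
            raise ValidationError(f"voxels must be numeric, got dtype {vox.dtype}")
        if np.issubdtype(vox.dtype, np.floating) and not np.all(np.isfinite(vox)):
            raise ValidationError("voxels contain non-finite HU values")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", _checked_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A boolean 3-D grid aligned to a companion :class:`CTVolume`."""

    mask: np.ndarray
    spacing: Spacing

    def __post_init__(self):
        arr = _checked_grid(np.asarray(self.mask), "mask")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError(f"mask values must be in {{0, 1}}, got {vals[:10]}")
            arr = arr.astype(bool)
        object.__setattr__(self, "mask", arr)
        object.__setattr__(self, "spacing", _checked_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled 3-D grid (multi-organ segmentation) with a name map."""

    labels: np.ndarray
    label_map: Mapping[str, int]
    spacing: Spacing

    def __post_init__(self):
        arr = _checked_grid(np.asarray(self.labels), "labels")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"labels must be integer-valued, got dtype {arr.dtype}")
        lm = dict(self.label_map)
        present = set(np.unique(arr).tolist()) - {0}
        known = set(lm.values())
        if not present <= known:
            raise ValidationError(
                f"label values {sorted(present - known)} not present in label_map {lm}"
            )
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "label_map", lm)
        object.__setattr__(self, "spacing", _checked_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask_for(self, name: str) -> BinaryMask:
        """Binary mask of one named structure."""
        if name not in self.label_map:
            raise ValidationError(
                f"organ {name!r} not in label_map (has {sorted(self.label_map)})"
            )
        return BinaryMask(self.labels == self.label_map[name], self.spacing)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_volume(path, format_hint: str = "auto") -> CTVolume:
    """Load a CT volume from a DICOM series directory, an MHD/RAW pair or NIfTI.

    Returns HU values (DICOM rescale slope/intercept applied), spacing from
    the file header (never assumed), slices ordered by ascending physical z.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    fmt = format_hint
    if fmt == "auto":
        if path.is_dir():
            fmt = "dicom"
        elif path.suffix.lower() in (".mhd", ".mha"):
            fmt = "mhd"
        elif path.name.lower().endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise VolumeIOError(f"cannot infer format of {path}")
    if fmt == "dicom":
        return _load_dicom_series(path)
    if fmt == "mhd":
        return _load_mhd(path)
    if fmt == "nifti":
        return _load_nifti(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(data, _checked_spacing(zooms), origin)


def _load_mhd(path: Path) -> CTVolume:
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot read MHD file {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D image, got {arr.ndim}-D")
    vox = np.ascontiguousarray(np.transpose(arr, (1, 2, 0)))  # -> (row=y, col=x, slice=z)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return CTVolume(vox, (sy, sx, sz), (oy, ox, oz))


def _load_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.name != "DICOMDIR")
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except pydicom.errors.InvalidDicomError:
            continue
        except Exception as exc:
            raise VolumeIOError(f"cannot read DICOM file {p}: {exc}") from exc
    if not datasets:
        raise VolumeIOError(f"no readable DICOM files in {path}")
    uids = sorted({str(getattr(ds, "SeriesInstanceUID", "<missing>")) for ds in datasets})
    if len(uids) > 1:
        raise VolumeIOError(
            f"directory {path} contains more than one DICOM series: {uids}"
        )

    def z_of(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        loc = getattr(ds, "SliceLocation", None)
        if loc is not None:
            return float(loc)
        raise VolumeIOError(
            f"DICOM slice in {path} has neither ImagePositionPatient nor SliceLocation"
        )

    datasets.sort(key=z_of)
    zs = [z_of(ds) for ds in datasets]

    first = datasets[0]
    ps = getattr(first, "PixelSpacing", None)
    if ps is None or len(ps) != 2:
        raise VolumeIOError(f"DICOM series in {path} is missing PixelSpacing")
    d_row, d_col = float(ps[0]), float(ps[1])
    if len(datasets) > 1:
        diffs = np.diff(zs)
        if np.any(diffs <= 0):
            raise VolumeIOError(f"DICOM series in {path} has duplicate slice positions")
        d_slice = float(np.mean(diffs))
    else:
        thick = getattr(first, "SpacingBetweenSlices", None) or getattr(
            first, "SliceThickness", None
        )
        if thick is None:
            raise VolumeIOError(
                f"single-slice DICOM series in {path} has no SliceThickness/"
                "SpacingBetweenSlices; cannot determine slice spacing"
            )
        d_slice = float(thick)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise VolumeIOError(f"DICOM series in {path} has inconsistent slice shapes {shapes}")
    vox = np.stack(slices, axis=2)
    origin = (0.0, 0.0, float(zs[0]))
    ipp = getattr(first, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        origin = (float(ipp[1]), float(ipp[0]), float(ipp[2]))
    return CTVolume(vox, (d_row, d_col, d_slice), origin)


def load_mask(path) -> BinaryMask | LabelMask:
    """Load a mask written by :func:`save_mask`.

    Returns a :class:`LabelMask` when the JSON label sidecar exists next to
    the file, otherwise a :class:`BinaryMask`.
    """
    path = Path(path)
    vol = _load_nifti(path)
    arr = np.rint(vol.voxels).astype(np.int32)
    sidecar = Path(str(path) + ".labels.json")
    if sidecar.exists():
        label_map = {k: int(v) for k, v in json.loads(sidecar.read_text()).items()}
        return LabelMask(arr, label_map, vol.spacing)
    return BinaryMask(arr, vol.spacing)


# ---------------------------------------------------------------------------
# Saving (NIfTI only)
# ---------------------------------------------------------------------------

def _affine(spacing: Spacing, origin: Triple) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: CTVolume, path) -> None:
    """Write a CT volume as NIfTI; reload yields identical voxels and spacing."""
    path = Path(path)
    data = vol.voxels
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    _save_nifti(img, path)


def save_mask(mask: BinaryMask | LabelMask, path) -> None:
    """Write a mask as NIfTI (background 0, foreground 1 / organ labels).

    Label masks additionally get a ``<path>.labels.json`` sidecar with the
    name-to-integer map.
    """
    path = Path(path)
    if isinstance(mask, BinaryMask):
        data = mask.mask.astype(np.uint8)
        spacing = mask.spacing
        sidecar = None
    elif isinstance(mask, LabelMask):
        data = mask.labels.astype(np.int16)
        spacing = mask.spacing
        sidecar = dict(mask.label_map)
    else:
        raise TypeError(f"expected BinaryMask or LabelMask, got {type(mask).__name__}")
    img = nib.Nifti1Image(data, _affine(spacing, (0.0, 0.0, 0.0)))
    img.header.set_zooms(spacing)
    _save_nifti(img, path)
    if sidecar is not None:
        Path(str(path) + ".labels.json").write_text(json.dumps(sidecar, indent=0))


def _save_nifti(img, path: Path) -> None:
    if not path.parent.exists():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Orientation standardization
# ---------------------------------------------------------------------------

def _grid_of(obj):
    if isinstance(obj, CTVolume):
        return obj.voxels
    if isinstance(obj, BinaryMask):
        return obj.mask
    if isinstance(obj, LabelMask):
        return obj.labels
    return np.asarray(obj)


def _rebuild(obj, arr, spacing):
    if isinstance(obj, CTVolume):
        return CTVolume(arr, spacing, obj.origin)
    if isinstance(obj, BinaryMask):
        return BinaryMask(arr, spacing)
    if isinstance(obj, LabelMask):
        return LabelMask(arr, obj.label_map, spacing)
    return arr


def standardize_orientation(obj, *, reflect: bool = True):
    """Rotate every axial slice 90 degrees clockwise, then mirror left-right.

    "Clockwise" is defined viewing a slice as displayed: first axis down,
    second axis right. The 2x2 slice ``[[a, b], [c, d]]`` becomes
    ``[[c, a], [d, b]]`` after rotation and ``[[a, c], [b, d]]`` after the
    reflection. Row/col spacing components are swapped accordingly.
    ``reflect=False`` applies the rotation only (period 4).
    The exact inverse is :func:`destandardize_orientation`.
    """
    arr = _grid_of(obj)
    out = np.rot90(arr, k=-1, axes=(0, 1))
    if reflect:
        out = out[:, ::-1, :]
    out = np.ascontiguousarray(out)
    spacing = getattr(obj, "spacing", None)
    if spacing is not None:
        spacing = (spacing[1], spacing[0], spacing[2])
    return _rebuild(obj, out, spacing)


def destandardize_orientation(obj, *, reflect: bool = True):
    """Exact inverse of :func:`standardize_orientation`."""
    arr = _grid_of(obj)
    out = arr[:, ::-1, :] if reflect else arr
    out = np.ascontiguousarray(np.rot90(out, k=1, axes=(0, 1)))
    spacing = getattr(obj, "spacing", None)
    if spacing is not None:
        spacing = (spacing[1], spacing[0], spacing[2])
    return _rebuild(obj, out, spacing)
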