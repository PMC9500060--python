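"""Synthetic abdominal CT phantoms with exact ground truth.

A phantom scene emulates the HU regimes that drive the pipeline's
knowledge-based corrections, on a grid small enough for seconds-scale
experiments (default 96 x 96 x 64 voxels at 2 x 2 x 3 mm):

* liver parenchyma around 60 HU (post-contrast),
* an adjacent spleen (~55 HU) and stomach (wall ~40 HU, fluid lumen near
  0 HU) tangent to the liver so contact boundaries exist,
* peri-hepatic ascites drawn uniformly in [0, 15) HU as a shell hugging the
  liver's lateral surface,
* aerated lung above the hepatic dome (-700 HU),
* background fat at -100 HU,
* optional additive Gaussian noise.

Ground-truth masks exactly match the generating geometry; compartments are
pairwise disjoint and, with the background, cover the grid. Generation is
bit-deterministic given the spec (including its seed).

The module also provides :func:`mock_segmenter`, a stand-in for a trained
multi-organ network with controllable failure modes (bleeding into an
adjacent compartment, or under-segmentation) so the pipeline's correction
stages can be exercised without any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, CTVolume, LabelMask, ValidationError, save_mask, save_volume

__all__ = [
    "Compartment",
    "PhantomSpec",
    "PhantomScene",
    "default_spec",
    "generate_phantom",
    "mock_segmenter",
    "write_scene",
    "FAILURE_MODES",
]

REQUIRED_COMPARTMENTS = ("liver", "spleen", "stomach")
FAILURE_MODES = ("perfect", "bleed_spleen", "bleed_stomach", "bleed_ascites", "undersegment")

# HU ranges of fluid-like compartments (upper bounds exclusive)
ASCITES_HU_RANGE = (0.0, 15.0)
LUMEN_HU_RANGE = (0.0, 10.0)
BACKGROUND_HU = -100.0


@dataclass(frozen=True)
class Compartment:
    """One parametric organ compartment (geometry in voxel index units)."""

    name: str
    kind: Literal["ellipsoid", "box"]
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    mean_hu: float
    hu_std: float = 0.0
    lumen_fraction: float = 0.0  # >0: inner ellipsoid carved out as fluid lumen

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "box"):
            raise ValidationError(f"unknown geometry kind {self.kind!r}")
        if self.hu_std < 0:
            raise ValidationError("hu_std must be >= 0")
        if not (0.0 <= self.lumen_fraction < 1.0):
            raise ValidationError("lumen_fraction must be in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic abdominal scene."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    compartments: tuple[Compartment, ...] = ()
    ascites_thickness: float = 12.0  # mm; 0 disables the fluid shell
    organ_clearance: float = 8.0  # mm; fluid keeps clear of non-liver organs
    noise_std: float = 5.0  # HU
    seed: int = 0

    def __post_init__(self):
        if self.noise_std < 0:
            raise ValidationError("noise_std must be >= 0")
        if self.ascites_thickness < 0:
            raise ValidationError("ascites_thickness must be >= 0")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValidationError(f"compartment names must be unique, got {names}")
        missing = [n for n in REQUIRED_COMPARTMENTS if n not in names]
        if missing:
            raise ValidationError(f"required compartments missing: {missing}")


@dataclass(frozen=True)
class PhantomScene:
    """A generated phantom: the HU volume plus exact truth masks."""

    volume: CTVolume
    truth: dict[str, BinaryMask]
    spec: PhantomSpec


def default_spec(seed: int = 0, *, noise_std: float = 5.0, ascites_thickness: float = 12.0,
                 grid_shape: tuple[int, int, int] = (96, 96, 64),
                 spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)) -> PhantomSpec:
    """The study's default scene; geometry scales linearly with the grid."""
    nr, nc, ns = grid_shape
    # scale against (n-1) so touching-the-edge geometry stays in bounds
    sr, sc, ss = (nr - 1) / 95.0, (nc - 1) / 95.0, (ns - 1) / 63.0

    def c(r, col, z):
        return (r * sr, col * sc, z * ss)

    comps = (
        Compartment("liver", "ellipsoid", c(46, 40, 30), c(30, 24, 19), 60.0),
        Compartment("spleen", "ellipsoid", c(46, 78, 30), c(16, 13, 14), 55.0),
        Compartment("stomach", "ellipsoid", c(84, 40, 30), c(7, 12, 10), 40.0,
                    lumen_fraction=0.55),
        Compartment("lung", "ellipsoid", c(46, 40, 58), c(22, 20, 5), -700.0),
    )
    return PhantomSpec(grid_shape=tuple(grid_shape), spacing=tuple(spacing),
                       compartments=comps, ascites_thickness=ascites_thickness,
                       noise_std=noise_std, seed=seed)


def _geometry_mask(comp: Compartment, shape, scale: float = 1.0) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    cr = comp.center
    rad = tuple(r * scale for r in comp.radii)
    if comp.kind == "ellipsoid":
        q = sum(((idx[a] - cr[a]) / rad[a]) ** 2 for a in range(3))
        return q <= 1.0
    lo = [cr[a] - rad[a] for a in range(3)]
    hi = [cr[a] + rad[a] for a in range(3)]
    return np.logical_and.reduce([(idx[a] >= lo[a]) & (idx[a] <= hi[a]) for a in range(3)])


def _check_bounds(comp: Compartment, shape) -> None:
    for a in range(3):
        if comp.center[a] - comp.radii[a] < 0 or comp.center[a] + comp.radii[a] > shape[a] - 1:
            raise ValidationError(
                f"compartment {comp.name!r} exceeds grid bounds along axis {a}"
            )


def generate_phantom(spec: PhantomSpec) -> PhantomScene:
    """Build the scene deterministically from the spec (bit-identical per seed)."""
    shape = tuple(spec.grid_shape)
    rng = np.random.default_rng(spec.seed)

    masks: dict[str, np.ndarray] = {}
    lumens: dict[str, np.ndarray] = {}
    for comp in spec.compartments:
        _check_bounds(comp, shape)
        m = _geometry_mask(comp, shape)
        if comp.lumen_fraction > 0:
            lumens[comp.name] = _geometry_mask(comp, shape, scale=comp.lumen_fraction)
        masks[comp.name] = m

    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValidationError(
                    f"compartments {a!r} and {b!r} overlap; phantoms must have "
                    "unambiguous truth"
                )

    occupied = np.logical_or.reduce(list(masks.values()))
    liver = masks["liver"]

    # Peri-hepatic fluid: everything within `ascites_thickness` mm of the
    # liver surface on its lateral (low-column) side, outside every organ.
    # The shell pools against the liver's free surface and keeps
    # `organ_clearance` mm away from the other compartments, so it never
    # forms capillary slivers inside inter-organ contact gaps.
    if spec.ascites_thickness > 0:
        dist = ndimage.distance_transform_edt(~liver, sampling=spec.spacing)
        liver_center_col = next(
            c.center[1] for c in spec.compartments if c.name == "liver"
        )
        cols = np.indices(shape)[1]
        ascites = (dist > 0) & (dist <= spec.ascites_thickness) & ~occupied
        ascites &= cols <= liver_center_col
        if spec.organ_clearance > 0:
            for comp in spec.compartments:
                if comp.name == "liver" or not masks[comp.name].any():
                    continue
                d_other = ndimage.distance_transform_edt(
                    ~masks[comp.name], sampling=spec.spacing
                )
                ascites &= d_other > spec.organ_clearance
    else:
        ascites = np.zeros(shape, dtype=bool)
    masks["ascites"] = ascites

    volume = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    for comp in spec.compartments:
        m = masks[comp.name]
        if comp.hu_std > 0:
            volume[m] = comp.mean_hu + rng.normal(0.0, comp.hu_std, size=int(m.sum()))
        else:
            volume[m] = comp.mean_hu
        if comp.name in lumens:
            lum = lumens[comp.name]
            volume[lum] = rng.uniform(*LUMEN_HU_RANGE, size=int(lum.sum()))
    if ascites.any():
        volume[ascites] = rng.uniform(*ASCITES_HU_RANGE, size=int(ascites.sum()))
    if spec.noise_std > 0:
        volume = volume + rng.normal(0.0, spec.noise_std, size=shape)

    truth_arrays = dict(masks)
    truth_arrays["background"] = ~np.logical_or.reduce(list(masks.values()))
    truth = {k: BinaryMask(v, spec.spacing) for k, v in truth_arrays.items()}
    return PhantomScene(CTVolume(volume, spec.spacing), truth, spec)


# ---------------------------------------------------------------------------
# Mock segmenter backends' engine
# ---------------------------------------------------------------------------

_LABEL_MAP = {"liver": 1, "spleen": 2, "stomach": 3}


def _grow_into(source: np.ndarray, target: np.ndarray, quota: int) -> np.ndarray:
    """Deterministic ring growth of the liver front into a target compartment.

    The reach front dilates with the 26-neighbourhood (so tangent organs with
    point contact are still reachable); target voxels are claimed ring by
    ring, the final partial ring in lexicographic (flat-index) order.
    """
    struct = np.ones((3, 3, 3), dtype=bool)
    reach = source.copy()
    bleed = np.zeros_like(source)
    n = 0
    while n < quota:
        new_reach = ndimage.binary_dilation(reach, structure=struct)
        if np.array_equal(new_reach, reach):
            break  # nothing left to reach
        ring = new_reach & target & ~bleed
        take = quota - n
        n_ring = int(ring.sum())
        if n_ring > take:
            sel = np.zeros(ring.size, dtype=bool)
            sel[np.flatnonzero(ring.ravel())[:take]] = True
            ring = sel.reshape(ring.shape)
            n_ring = take
        bleed |= ring
        n += n_ring
        reach = new_reach
    return bleed


def mock_segmenter(scene: PhantomScene, failure_mode: str = "perfect",
                   severity: float = 0.0, seed: int = 0) -> LabelMask:
    """Emulate a multi-organ segmenter with a controllable failure mode.

    ``perfect`` reproduces the truth; ``bleed_<X>`` lets the liver label
    additionally claim a contiguous fraction ``severity`` of compartment X
    grown from the liver boundary; ``undersegment`` erodes the liver label by
    a margin proportional to severity. Deterministic for a given scene,
    failure mode and severity (the seed is part of the backend contract).
    """
    if failure_mode not in FAILURE_MODES:
        raise ValidationError(f"unknown failure mode {failure_mode!r}; one of {FAILURE_MODES}")
    if not (0.0 <= severity <= 1.0):
        raise ValidationError(f"severity must be in [0, 1], got {severity}")

    truth = {k: v.mask for k, v in scene.truth.items()}
    liver = truth["liver"].copy()
    spleen = truth["spleen"].copy()
    stomach = truth["stomach"].copy()

    if failure_mode.startswith("bleed_"):
        target_name = failure_mode.split("_", 1)[1]
        target = truth[target_name]
        quota = int(round(severity * int(target.sum())))
        bleed = _grow_into(liver, target, quota)
        liver |= bleed
        spleen &= ~bleed
        stomach &= ~bleed
    elif failure_mode == "undersegment":
        iters = int(round(severity * 6))
        if iters > 0:
            liver = ndimage.binary_erosion(
                liver, structure=ndimage.generate_binary_structure(3, 1),
                iterations=iters, border_value=0,
            )

    labels = np.zeros(scene.volume.shape, dtype=np.int16)
    labels[liver] = _LABEL_MAP["liver"]
    labels[spleen] = _LABEL_MAP["spleen"]
    labels[stomach] = _LABEL_MAP["stomach"]
    return LabelMask(labels, dict(_LABEL_MAP), scene.volume.spacing)


def write_scene(scene: PhantomScene, out_dir) -> list[Path]:
    """Write volume.nii.gz plus truth_<name>.nii.gz per compartment."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    vol_path = out_dir / "volume.nii.gz"
    save_volume(scene.volume, vol_path)
    written.append(vol_path)
    for name, mask in scene.truth.items():
        p = out_dir / f"truth_{name}.nii.gz"
        save_mask(mask, p)
        written.append(p)
    return written
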