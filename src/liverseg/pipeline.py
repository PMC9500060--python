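"""Cascade orchestration with pluggable segmenter backends.

The pipeline runs, in order: orientation standardization -> initial
multi-organ segmentation (pluggable backend) -> organ knock-out -> ascites
removal -> liver bounding box -> crop -> liver refinement (pluggable
backend) -> re-embedding -> morphological finalization. Trained networks are
deliberately out of scope: any callable satisfying the backend contract can
stand in for the initial multi-organ segmenter or the liver refiner,
including file-based backends that replay masks produced externally by real
models, and mock/toy backends for phantom experiments.

Every run yields a provenance record (config hash, input hash, per-stage
voxel counts, final mask hash) sufficient to verify bit-identical replay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .correction import (BoundingBox, CorrectionConfig, apply_ascites_correction,
                         liver_bounding_box, remove_organs)
from .metrics import MetricReport, evaluate, welch_t
from .morphology import keep_largest
from .phantom import PhantomScene, default_spec, generate_phantom, mock_segmenter
from .postprocess import PostprocessConfig, finalize
from .volume_io import (BinaryMask, CTVolume, LabelMask, ValidationError, load_mask,
                        save_mask, save_volume, standardize_orientation)

__all__ = [
    "InitialBackend",
    "RefinerBackend",
    "MockInitialBackend",
    "FileInitialBackend",
    "IdentityRefiner",
    "ThresholdRefiner",
    "FileRefiner",
    "PipelineConfig",
    "PipelineError",
    "register_backend",
    "resolve_backend",
    "registered_backends",
    "run_pipeline",
    "compare_runs",
    "ComparisonResult",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline run cannot proceed (e.g. empty initial liver)."""


# ---------------------------------------------------------------------------
# Backend contracts and implementations
# ---------------------------------------------------------------------------

class InitialBackend:
    """Contract: CT volume in, multi-organ LabelMask (aligned grid) out."""

    name = "initial"
    kind = "initial_multiorgan"

    def segment(self, vol: CTVolume, seed: int) -> LabelMask:
        raise NotImplementedError

    def describe(self) -> dict:
        return {"backend": type(self).__name__}


class RefinerBackend:
    """Contract: cropped (edited) CT volume in, liver (+ tumor) mask out.

    Masks are returned in the cropped frame; the pipeline re-embeds them
    into the full grid using the bounding box.
    """

    name = "refiner"
    kind = "liver_refiner"

    def refine(self, vol_crop: CTVolume, box: BoundingBox,
               initial_liver_crop: BinaryMask | None, seed: int
               ) -> tuple[BinaryMask, BinaryMask | None]:
        raise NotImplementedError

    def describe(self) -> dict:
        return {"backend": type(self).__name__}


class MockInitialBackend(InitialBackend):
    """Phantom-truth segmenter with controllable failure modes."""

    name = "mock_initial"

    def __init__(self, scene: PhantomScene, failure_mode: str = "perfect",
                 severity: float = 0.0):
        self.scene = scene
        self.failure_mode = failure_mode
        self.severity = severity

    def segment(self, vol: CTVolume, seed: int) -> LabelMask:
        if vol.shape != self.scene.volume.shape:
            raise ValidationError(
                f"mock_initial scene grid {self.scene.volume.shape} does not "
                f"match pipeline volume {vol.shape}"
            )
        return mock_segmenter(self.scene, self.failure_mode, self.severity, seed)

    def describe(self) -> dict:
        return {
            "backend": "mock_initial",
            "failure_mode": self.failure_mode,
            "severity": self.severity,
            "scene_seed": self.scene.spec.seed,
        }


class FileInitialBackend(InitialBackend):
    """Replay a multi-organ label mask produced externally (e.g. a real DCNN)."""

    name = "file_initial"

    def __init__(self, path):
        self.path = Path(path)

    def segment(self, vol: CTVolume, seed: int) -> LabelMask:
        mask = load_mask(self.path)
        if not isinstance(mask, LabelMask):
            raise ValidationError(
                f"{self.path} is not a label mask (no label sidecar found)"
            )
        if mask.shape != vol.shape:
            raise ValidationError(
                f"file_initial mask shape {mask.shape} does not match volume "
                f"{vol.shape}"
            )
        return mask

    def describe(self) -> dict:
        return {"backend": "file_initial", "path": str(self.path)}


class IdentityRefiner(RefinerBackend):
    """Pass the initial liver label through unchanged (cropped frame)."""

    name = "identity_refiner"

    def refine(self, vol_crop, box, initial_liver_crop, seed):
        if initial_liver_crop is None:
            raise ValidationError("identity_refiner requires the initial liver crop")
        return initial_liver_crop, None

    def describe(self) -> dict:
        return {"backend": "identity_refiner"}


class ThresholdRefiner(RefinerBackend):
    """Toy HU-window refiner: foreground = HU in [low, high], largest component.

    With the default window [20, 200] it behaves like a parenchyma detector;
    widening the lower bound below 0 HU emulates a refiner that cannot tell
    simple fluid from liver, the failure the ascites correction targets.
    """

    name = "threshold_refiner"

    def __init__(self, low: float = 20.0, high: float = 200.0):
        self.low = float(low)
        self.high = float(high)

    def refine(self, vol_crop, box, initial_liver_crop, seed):
        fg = (vol_crop.voxels >= self.low) & (vol_crop.voxels <= self.high)
        return BinaryMask(keep_largest(fg), vol_crop.spacing), None

    def describe(self) -> dict:
        return {"backend": "threshold_refiner", "low": self.low, "high": self.high}


class FileRefiner(RefinerBackend):
    """Replay a full-grid liver (and optional tumor) mask from disk."""

    name = "file_refiner"

    def __init__(self, path, tumor_path=None):
        self.path = Path(path)
        self.tumor_path = Path(tumor_path) if tumor_path else None

    def _load_crop(self, path, box, spacing) -> BinaryMask:
        mask = load_mask(path)
        if isinstance(mask, LabelMask):
            raise ValidationError(f"{path} is a label mask; expected a binary mask")
        return BinaryMask(mask.mask[box.slices], spacing)

    def refine(self, vol_crop, box, initial_liver_crop, seed):
        liver = self._load_crop(self.path, box, vol_crop.spacing)
        tumor = (self._load_crop(self.tumor_path, box, vol_crop.spacing)
                 if self.tumor_path else None)
        return liver, tumor

    def describe(self) -> dict:
        return {"backend": "file_refiner", "path": str(self.path),
                "tumor_path": str(self.tumor_path) if self.tumor_path else None}


_REGISTRY: dict[str, Callable[..., Any]] = {}


def register_backend(name: str, factory: Callable[..., Any]) -> None:
    """Register a backend factory under a unique name."""
    if name in _REGISTRY:
        raise ValidationError(f"backend name {name!r} already registered")
    _REGISTRY[name] = factory


def registered_backends() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def resolve_backend(spec):
    """Resolve a backend instance, a name, or a (name, params) pair."""
    if isinstance(spec, (InitialBackend, RefinerBackend)):
        return spec
    if isinstance(spec, str):
        name, params = spec, {}
    elif isinstance(spec, (tuple, list)) and len(spec) == 2:
        name, params = spec
    elif isinstance(spec, dict) and "name" in spec:
        name, params = spec["name"], spec.get("params", {})
    else:
        raise ValidationError(f"cannot interpret backend spec {spec!r}")
    if name not in _REGISTRY:
        raise ValidationError(
            f"unknown backend {name!r}; registered: {registered_backends()}"
        )
    return _REGISTRY[name](**params)


for _cls in (MockInitialBackend, FileInitialBackend, IdentityRefiner,
             ThresholdRefiner, FileRefiner):
    register_backend(_cls.name, _cls)


# ---------------------------------------------------------------------------
# Pipeline configuration and run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    initial_backend: Any = None
    refiner_backend: Any = None
    standardize: bool = True
    reflect: bool = True
    enable_knockout: bool = True
    enable_ascites: bool = True
    save_intermediates: str | None = None
    seed: int = 0


def _hash_bytes(*chunks: bytes) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c)
    return h.hexdigest()


def _hash_array(arr: np.ndarray) -> str:
    data = np.ascontiguousarray(arr)
    return _hash_bytes(str(data.shape).encode(), str(data.dtype).encode(),
                       data.tobytes())


def _hash_mask(mask: BinaryMask) -> str:
    return _hash_bytes(str(mask.shape).encode(), np.packbits(mask.mask).tobytes())


def _config_payload(cfg: PipelineConfig) -> dict:
    payload = {
        "correction": dataclasses.asdict(cfg.correction),
        "postprocess": dataclasses.asdict(cfg.postprocess),
        "initial_backend": resolve_backend(cfg.initial_backend).describe(),
        "refiner_backend": resolve_backend(cfg.refiner_backend).describe(),
        "standardize": cfg.standardize,
        "reflect": cfg.reflect,
        "enable_knockout": cfg.enable_knockout,
        "enable_ascites": cfg.enable_ascites,
        "seed": cfg.seed,
    }
    return payload


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, default=str)


def run_pipeline(vol: CTVolume, cfg: PipelineConfig) -> tuple[BinaryMask, dict]:
    """Run the full cascade; returns the final liver mask and provenance.

    Deterministic: identical (volume, config, seed) produce a bit-identical
    final mask and an identical provenance hash.
    """
    if cfg.initial_backend is None or cfg.refiner_backend is None:
        raise ValidationError("pipeline config must name initial and refiner backends")
    initial = resolve_backend(cfg.initial_backend)
    refiner = resolve_backend(cfg.refiner_backend)
    out_dir = Path(cfg.save_intermediates) if cfg.save_intermediates else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    stages: list[dict] = []
    prov: dict = {
        "config_hash": _hash_bytes(_canonical_json(_config_payload(cfg)).encode()),
        "input_hash": _hash_array(vol.voxels),
        "stages": stages,
    }

    def record(stage: str, **info):
        stages.append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    if cfg.standardize:
        vol = standardize_orientation(vol, reflect=cfg.reflect)
        record("standardize_orientation", reflect=cfg.reflect, shape=list(vol.shape))

    seg = initial.segment(vol, cfg.seed)
    if seg.shape != vol.shape:
        raise PipelineError(
            f"initial backend {type(initial).__name__} returned misaligned grid "
            f"{seg.shape} (expected {vol.shape})"
        )
    liver_label = seg.mask_for("liver")
    if not liver_label.mask.any():
        raise PipelineError("no liver found by initial segmenter; aborting")
    record("initial_segmentation", backend=initial.describe(),
           n_liver=liver_label.count())

    edited = vol
    if cfg.enable_knockout:
        edited = remove_organs(edited, seg, cfg.correction)
        n_changed = int(np.count_nonzero(edited.voxels != vol.voxels))
        record("remove_organs", organs=list(cfg.correction.organs_to_remove),
               n_changed=n_changed)

    if cfg.enable_ascites:
        before = edited.voxels
        edited, fluid_mask = apply_ascites_correction(edited, cfg.correction)
        record("ascites_correction",
               n_masked=fluid_mask.count(),
               n_changed=int(np.count_nonzero(edited.voxels != before)))
        if out_dir is not None:
            save_mask(fluid_mask, out_dir / "ascites_mask.nii.gz")

    box = liver_bounding_box(seg, cfg.correction.bbox_margin)
    record("bounding_box", lo=list(box.lo), hi=list(box.hi))

    crop = CTVolume(np.ascontiguousarray(edited.voxels[box.slices]), edited.spacing,
                    tuple(o + l * s for o, l, s in
                          zip(edited.origin, box.lo, edited.spacing)))
    init_crop = BinaryMask(np.ascontiguousarray(liver_label.mask[box.slices]),
                           edited.spacing)
    liver_c, tumor_c = refiner.refine(crop, box, init_crop, cfg.seed)
    for m, what in ((liver_c, "liver"), (tumor_c, "tumor")):
        if m is not None and m.shape != crop.shape:
            raise PipelineError(
                f"refiner backend {type(refiner).__name__} returned misaligned "
                f"{what} mask {m.shape} (expected crop {crop.shape})"
            )
    record("refine", backend=refiner.describe(), n_liver=liver_c.count())

    def embed(crop_mask):
        if crop_mask is None:
            return None
        full = np.zeros(vol.shape, dtype=bool)
        full[box.slices] = crop_mask.mask
        return BinaryMask(full, vol.spacing)

    liver_full = embed(liver_c)
    tumor_full = embed(tumor_c)
    if out_dir is not None:
        save_volume(edited, out_dir / "edited_volume.nii.gz")
        save_mask(liver_full, out_dir / "refined_liver_raw.nii.gz")

    collect: dict | None = {} if out_dir is not None else None
    final = finalize(liver_full, edited, cfg.postprocess, tumor=tumor_full,
                     collect=collect)
    record("finalize", n_final=final.count())
    if out_dir is not None:
        for name, m in (collect or {}).items():
            save_mask(m, out_dir / f"post_{name}.nii.gz")
        save_mask(final, out_dir / "final_liver.nii.gz")

    prov["final_mask_hash"] = _hash_mask(final)
    prov["provenance_hash"] = _hash_bytes(_canonical_json(
        {k: v for k, v in prov.items() if k != "provenance_hash"}).encode())
    return final, prov


# ---------------------------------------------------------------------------
# Phantom experiments: the with/without-correction comparison design
# ---------------------------------------------------------------------------

def phantom_correction_experiment(seeds, mode: str = "ascites",
                                  noise_std: float = 5.0
                                  ) -> tuple[list[MetricReport], list[MetricReport]]:
    """Run the cascade with and without corrections over seeded phantoms.

    ``mode="ascites"``: a perfect initial segmenter feeds a fluid-blind toy
    refiner (HU window [-50, 200]) that bleeds into peri-hepatic fluid unless
    the ascites correction has knocked it out. ``mode="spleen"``: the initial
    segmenter bleeds into the spleen and a parenchyma-window refiner
    ([20, 200]) picks up whatever spleen tissue was not knocked out.

    Returns ``(corrected_reports, uncorrected_reports)`` of per-seed metric
    reports against truth liver, in seed order.
    """
    if mode not in ("ascites", "spleen"):
        raise ValidationError(f"unknown experiment mode {mode!r}")
    reports_c: list[MetricReport] = []
    reports_u: list[MetricReport] = []
    for seed in seeds:
        scene = generate_phantom(default_spec(seed=int(seed), noise_std=noise_std))
        if mode == "ascites":
            initial = MockInitialBackend(scene, "perfect")
            refiner = ThresholdRefiner(low=-50.0, high=200.0)
        else:
            initial = MockInitialBackend(scene, "bleed_spleen", severity=0.4)
            refiner = ThresholdRefiner(low=20.0, high=200.0)
        truth = scene.truth["liver"]
        for enabled, out in ((True, reports_c), (False, reports_u)):
            cfg = PipelineConfig(
                initial_backend=initial, refiner_backend=refiner,
                standardize=False, enable_knockout=enabled,
                enable_ascites=enabled, seed=int(seed),
            )
            final, _ = run_pipeline(scene.volume, cfg)
            out.append(evaluate(final, truth))
    return reports_c, reports_u


# ---------------------------------------------------------------------------
# Run comparison (with/without correction design)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    table: pd.DataFrame  # mean/sd per metric per arm
    t_dice: float
    p_dice: float
    significant: bool


def compare_runs(reports_a, reports_b, alpha: float = 0.05) -> ComparisonResult:
    """Per-metric mean +/- sd for two arms plus Welch's t-test on Dice.

    Standard deviations are sample sd (ddof=1). Requires >= 2 cases per arm.
    """
    reports_a, reports_b = list(reports_a), list(reports_b)
    if len(reports_a) < 2 or len(reports_b) < 2:
        raise ValidationError("compare_runs needs at least 2 cases per arm")
    metric_cols = ["voe_pct", "rvd_pct", "asd_mm", "rmsd_mm", "hd_mm", "dice"]
    frames = {}
    for arm, reports in (("a", reports_a), ("b", reports_b)):
        df = pd.DataFrame([r.as_dict() for r in reports])[metric_cols]
        frames[f"mean_{arm}"] = df.mean()
        frames[f"sd_{arm}"] = df.std(ddof=1)
    table = pd.DataFrame(frames)
    t, p = welch_t([r.dice for r in reports_a], [r.dice for r in reports_b])
    return ComparisonResult(table, t, p, bool(p < alpha))
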