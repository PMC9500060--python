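"""Segmentation evaluation: overlap scores, surface distances and statistics.

With prediction A and reference B (voxel sets) the overlap metrics are

* ``Dice  = 2|A ∩ B| / (|A| + |B|)``             (unitless, 1 is perfect)
* ``VOE   = 100 (1 - |A ∩ B| / |A ∪ B|)``        (%, 0 is perfect)
* ``RVD   = 100 (|A| - |B|) / |B|``              (%, signed; + means oversegmentation)

Surface distances use S(A), S(B): foreground voxels with at least one
face-adjacent background neighbour (out-of-bounds counts as background),
located at voxel centers scaled by the per-axis spacing in mm. With d(x, S)
the Euclidean nearest-surface distance,

* ``ASD  = ( Σ_{a∈S(A)} d(a,S(B)) + Σ_{b∈S(B)} d(b,S(A)) ) / (|S(A)|+|S(B)|)``
* ``RMSD = sqrt( ( Σ d²(a,S(B)) + Σ d²(b,S(A)) ) / (|S(A)|+|S(B)|) )``
* ``HD   = max( max_a d(a,S(B)), max_b d(b,S(A)) )``  (symmetric; a directed
  variant is available)

The module also provides the ascites-threshold ROC sweep over phantom scenes
(Youden-J operating point) and Welch's unequal-variance t-test for comparing
per-case score lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .volume_io import BinaryMask, ValidationError

__all__ = [
    "MetricReport",
    "SurfacePointSet",
    "ROCPoint",
    "RocResult",
    "dice",
    "voe",
    "rvd",
    "extract_surface",
    "asd",
    "rmsd",
    "hausdorff",
    "evaluate",
    "ascites_roc",
    "welch_t",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricReport:
    """The six segmentation scores for one prediction/reference pair."""

    dice: float
    voe_pct: float
    rvd_pct: float
    asd_mm: float
    rmsd_mm: float
    hd_mm: float
    n_pred_voxels: int
    n_ref_voxels: int

    def as_dict(self) -> dict:
        return {
            "dice": self.dice, "voe_pct": self.voe_pct, "rvd_pct": self.rvd_pct,
            "asd_mm": self.asd_mm, "rmsd_mm": self.rmsd_mm, "hd_mm": self.hd_mm,
            "n_pred_voxels": self.n_pred_voxels, "n_ref_voxels": self.n_ref_voxels,
        }


@dataclass(frozen=True)
class SurfacePointSet:
    """Voxel-center coordinates (mm) of a mask's face-boundary voxels."""

    points: np.ndarray  # (n, 3) float, mm

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    tpr: float
    fpr: float


@dataclass(frozen=True)
class RocResult:
    points: tuple[ROCPoint, ...]
    best_threshold: float
    best_youden: float


def _arrays(pred, ref):
    a = pred.mask if isinstance(pred, BinaryMask) else np.asarray(pred, bool)
    b = ref.mask if isinstance(ref, BinaryMask) else np.asarray(ref, bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice(pred, ref) -> float:
    """Dice overlap; two empty masks are defined as 1.0 (with a warning)."""
    a, b = _arrays(pred, ref)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        log.warning("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def voe(pred, ref) -> float:
    """Volumetric overlap error in percent (100 x (1 - Jaccard))."""
    a, b = _arrays(pred, ref)
    union = int((a | b).sum())
    if union == 0:
        raise ValidationError("VOE undefined for two empty masks")
    return 100.0 * (1.0 - int((a & b).sum()) / union)


def rvd(pred, ref) -> float:
    """Signed relative volume difference in percent; + is oversegmentation."""
    a, b = _arrays(pred, ref)
    nb = int(b.sum())
    if nb == 0:
        raise ValidationError("RVD undefined for an empty reference mask")
    return 100.0 * (int(a.sum()) - nb) / nb


def extract_surface(mask, spacing=None) -> SurfacePointSet:
    """Surface voxels (>= 1 of 6 face neighbours background/out-of-bounds)."""
    if isinstance(mask, BinaryMask):
        spacing = spacing or mask.spacing
        arr = mask.mask
    else:
        arr = np.asarray(mask, bool)
        if spacing is None:
            raise ValidationError("spacing required for a bare array mask")
    interior = ndimage.binary_erosion(
        arr, structure=ndimage.generate_binary_structure(arr.ndim, 1), border_value=0
    )
    idx = np.argwhere(arr & ~interior).astype(np.float64)
    return SurfacePointSet(idx * np.asarray(spacing, dtype=np.float64))


def _surface_distance_sets(pred, ref, spacing):
    a, b = _arrays(pred, ref)
    if not a.any() or not b.any():
        raise ValidationError("surface distances undefined for an empty mask")
    if spacing is None:
        sp = getattr(pred, "spacing", None) or getattr(ref, "spacing", None)
        if sp is None:
            raise ValidationError("spacing required for bare array masks")
        spacing = sp
    sa = extract_surface(a, spacing).points
    sb = extract_surface(b, spacing).points
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return d_ab, d_ba


def asd(pred, ref, spacing=None) -> float:
    """Average symmetric surface distance in mm."""
    d_ab, d_ba = _surface_distance_sets(pred, ref, spacing)
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


def rmsd(pred, ref, spacing=None) -> float:
    """Root-mean-square symmetric surface distance in mm."""
    d_ab, d_ba = _surface_distance_sets(pred, ref, spacing)
    return float(np.sqrt((np.square(d_ab).sum() + np.square(d_ba).sum())
                         / (d_ab.size + d_ba.size)))


def hausdorff(pred, ref, spacing=None, directed: bool = False) -> float:
    """Hausdorff surface distance in mm (symmetric max unless ``directed``)."""
    d_ab, d_ba = _surface_distance_sets(pred, ref, spacing)
    if directed:
        return float(d_ab.max())
    return float(max(d_ab.max(), d_ba.max()))


def evaluate(pred: BinaryMask, ref: BinaryMask, spacing=None) -> MetricReport:
    """All six metrics for one prediction/reference pair."""
    a, b = _arrays(pred, ref)
    d_ab, d_ba = _surface_distance_sets(pred, ref, spacing)
    n = d_ab.size + d_ba.size
    return MetricReport(
        dice=dice(pred, ref),
        voe_pct=voe(pred, ref),
        rvd_pct=rvd(pred, ref),
        asd_mm=float((d_ab.sum() + d_ba.sum()) / n),
        rmsd_mm=float(np.sqrt((np.square(d_ab).sum() + np.square(d_ba).sum()) / n)),
        hd_mm=float(max(d_ab.max(), d_ba.max())),
        n_pred_voxels=int(a.sum()),
        n_ref_voxels=int(b.sum()),
    )


DEFAULT_ROC_THRESHOLDS = (0.0, 5.0, *[float(t) for t in range(10, 21)], 25.0, 30.0)


def ascites_roc(scenes, thresholds=None, cfg=None) -> RocResult:
    """ROC sweep of the fluid threshold over phantom scenes, pooled.

    For each threshold t the full fluid-mask construction (threshold,
    per-slice opening, per-slice area filter) is run; TPR/FPR are computed
    against the truth ascites masks, pooled over scenes. The operating point
    maximizes Youden's J = TPR - FPR; ties go to the smallest threshold (the
    most specific choice among equals).
    """
    from .correction import CorrectionConfig, build_ascites_mask  # local: avoid cycle

    cfg = cfg or CorrectionConfig()
    thresholds = tuple(float(t) for t in (thresholds or DEFAULT_ROC_THRESHOLDS))
    scenes = list(scenes)
    if not scenes:
        raise ValidationError("ascites_roc needs at least one scene")
    total_ascites = sum(int(s.truth["ascites"].mask.sum()) for s in scenes)
    if total_ascites == 0:
        raise ValidationError("no truth ascites in any scene")

    points = []
    for t in sorted(thresholds):
        tp = fp = pos = neg = 0
        for scene in scenes:
            truth = scene.truth["ascites"].mask
            mask = build_ascites_mask(
                scene.volume, replace(cfg, ascites_threshold=t)
            ).mask
            tp += int((mask & truth).sum())
            fp += int((mask & ~truth).sum())
            pos += int(truth.sum())
            neg += int((~truth).sum())
        points.append(ROCPoint(t, tp / pos, fp / neg))

    best = max(points, key=lambda p: (p.tpr - p.fpr, -p.threshold))
    return RocResult(tuple(points), best.threshold, best.tpr - best.fpr)


def welch_t(scores_a, scores_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p).

    Each sample needs >= 2 observations and at least one nonzero variance;
    two elementwise-identical samples return (0.0, 1.0) by convention.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t needs at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
            return 0.0, 1.0
        raise ValidationError("welch_t undefined: zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
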