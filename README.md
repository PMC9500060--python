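# liverseg

A segmenter-agnostic framework for automated liver segmentation from
contrast-enhanced abdominal CT. Deep networks that segment the liver tend to
*oversegment*: they bleed into the spleen, the stomach, and — in patients with
chronic liver disease — into peri-hepatic ascites, whose attenuation overlaps
simple fluid (≈ 0–15 HU). `liverseg` implements the knowledge-based corrections
and morphological post-processing that fix this, around *pluggable* segmenter
backends: any callable with the contract "volume in, organ mask out" can serve
as the initial multi-organ segmenter or the liver refiner, including file-based
backends that replay masks produced externally by trained networks.

The package is aimed at medical-image-analysis researchers who want the
correction/evaluation machinery without GPUs or trained weights: every stage is
testable end-to-end on synthetic abdominal phantoms with exact ground truth.

## The method

Given a CT volume `V` (HU) and an initial multi-organ label mask:

1. **Orientation standardization** — each axial slice is rotated 90° clockwise
   and mirrored left-right; the exact inverse is provided for export.
2. **Organ knock-out** — voxels labelled spleen or stomach are set to −100 HU.
3. **Ascites removal** — a binary mask `A = {v : V(v) < 15 HU}` is opened per
   slice with a digital disk of radius 2 (`A ∘ B = (A ⊖ B) ⊕ B`), components
   with per-slice area ≤ 1500 px are dropped, and surviving voxels are set to
   −100 HU.
4. **Bounding box & refinement** — the liver label's bounding box crops the
   edited volume for the refiner backend; its output is re-embedded.
5. **Post-processing** — slice truncation, exclusion of voxels < 0 HU (lung at
   the hepatic dome), largest-component selection, per-slice closing (disk
   r = 2), liver+tumor merge, hole filling, and volumetric closing (sphere
   r = 3), where `A · B = (A ⊕ B) ⊖ B`.

Evaluation uses the standard six scores for prediction `A` vs reference `B`:
Dice `= 2|A∩B|/(|A|+|B|)`, VOE `= 100(1−|A∩B|/|A∪B|)`, signed RVD
`= 100(|A|−|B|)/|B|`, and the symmetric surface distances ASD, RMSD and
Hausdorff over face-boundary voxel centers in mm. The fluid threshold is
selected by a ROC sweep (Youden's J) and arms are compared with Welch's
t-test.

## Worked example

```python
import liverseg as ls

# a synthetic abdominal scene: liver (60 HU) with tangent spleen/stomach,
# a 12 mm peri-hepatic ascites shell in [0, 15) HU, lung, fat, exact truth
scene = ls.generate_phantom(ls.default_spec(seed=7, noise_std=0.0))

cfg = ls.PipelineConfig(
    initial_backend=ls.MockInitialBackend(scene, "perfect"),
    refiner_backend=ls.ThresholdRefiner(low=-50.0, high=200.0),  # fluid-blind
    standardize=False,          # phantoms are already in the canonical frame
)
final, prov = ls.run_pipeline(scene.volume, cfg)
print(ls.evaluate(final, scene.truth["liver"]).as_dict())

cfg.enable_knockout = cfg.enable_ascites = False   # ablate the corrections
uncorrected, _ = ls.run_pipeline(scene.volume, cfg)
print(ls.evaluate(uncorrected, scene.truth["liver"]).as_dict())
```

prints (numbers from this exact run):

```
{'dice': 1.0, 'voe_pct': 0.0, 'rvd_pct': 0.0, 'asd_mm': 0.0, 'rmsd_mm': 0.0,
 'hd_mm': 0.0, 'n_pred_voxels': 57231, 'n_ref_voxels': 57231}
{'dice': 0.8696..., 'voe_pct': 23.07..., 'rvd_pct': 29.99..., 'asd_mm': 4.58...,
 'rmsd_mm': 6.56..., 'hd_mm': 11.83..., 'n_pred_voxels': 74395, 'n_ref_voxels': 57231}
```

With the corrections enabled the fluid-blind refiner recovers the liver
exactly (the entire noiseless ascites shell is knocked out to −100 HU before
refinement); with corrections ablated it bleeds ~17k fluid voxels into the
mask and Dice drops to 0.87.

There is also a CLI: `liverseg phantom | correct | postprocess | run |
evaluate | roc | compare` (see `liverseg --help`).

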