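# tribrats

Tri-planar ("2.5D") whole-tumor segmentation of multimodal brain MRI,
built as a complete, CPU-testable pipeline:

1. **Defect screening** — each case's four modalities (FLAIR, T1ce, T1,
   T2) are reduced to one foreground contour area each; Dixon's Q-test
   on the four areas flags cases where one modality was truncated by
   the scanner:  Q = (x(2) − x(1)) / (x(n) − x(1)) against tabulated
   critical values (α = 0.001 → 0.964 for n = 4).
2. **Intensity normalization** — smooth multiplicative bias-field
   correction (polynomial log-domain fit, N4-style model) and
   foreground z-scoring, z′ = (z − μ)/δ.
3. **Tri-planar slicing** — the 3D volumes are cut into axial, coronal
   and sagittal 2D stacks; EfficientUNet models consume ordered
   three-modality channel combos, U-Net the full four-channel stack.
4. **Segmentation networks** — a five-level U-Net and an EfficientUNet
   (EfficientNetV2-S encoder: Fused-MBConv/MBConv stages with
   squeeze-excitation, feature taps per resolution halving, five-block
   conv decoder), trained with the generalized Dice loss
   GDL = 1 − (2 Σ w Σ gp + ε)/(Σ w Σ (g+p) + ε), w = 1/Σg, via Adam.
   Networks run on a small built-in numpy autodiff engine, so training
   and inference need no GPU and no deep-learning framework.
5. **Majority-vote fusion** — per-plane probability volumes are
   binarized at 0.5 and fused voxelwise by the 2-of-3 rule; evaluation
   reports (GDL, pixel accuracy, DSC = 2TP/(2TP+FP+FN)) per case.

A seeded phantom generator produces BraTS-like synthetic cases
(ellipsoidal brain, modality-specific tumor contrast, bias fields,
truncation defects) so the entire pipeline is exercisable end to end
without any download. Intended users: researchers who want a
transparent, dependency-light reference implementation of the 2.5D
majority-voting segmentation recipe, at desk scale.

## Worked example

```python
import numpy as np
from tribrats import dixon_q_test, make_dataset, filter_defective_cases
from tribrats.synthetic import PhantomParams, inject_defect

# Dixon screening arithmetic on a truncated-FLAIR case's four modality areas
r = dixon_q_test([9245.5, 14609, 14617, 14625.5], alpha=0.001)
print(round(r.q, 4), r.critical, r.is_outlier)
# 0.9969 0.964 True      -> the case is rejected as defective

# phantom dataset: 5 clean cases, then truncate one modality of one case
cases = make_dataset(5, PhantomParams(), seed=21)
cases[2] = inject_defect(cases[2], "FLAIR", 0.4)
kept, rejected = filter_defective_cases(cases, alpha=0.001)
print(len(kept), [cid for cid, _ in rejected])
# 4 ['phantom-829042257']
```

The Q statistic 0.9969 exceeds the α = 0.001 critical value 0.964, so
the screening stage drops the truncated case; the four clean phantoms
pass (their four areas are nearly identical, so Q ≈ 0).

The scaled-down tri-planar study — a width-0.25 EfficientUNet per
plane, 64 × 64 inputs, 5 epochs on 12 phantom cases — trains in about
four minutes on one CPU and fuses the three planes by majority vote:

```python
from tribrats.pipeline import desk_scale_experiment
fused, per_plane, df = desk_scale_experiment(seed=1)
print(round(fused.dsc, 4), {p: round(r.dsc, 3) for p, r in per_plane.items()})
# 0.9087 {'axial': 0.916, 'coronal': 0.3, 'sagittal': 0.888}
```

Here the coronal model trained poorly on this seed (DSC 0.30), yet the
fused whole-tumor DSC is 0.9087 — the 2-of-3 vote suppresses the weak
plane, which is the point of the tri-planar ensemble.

## Command line

```bash
tribrats synth --out data/ --n-cases 10 --defect-rate 0.1 --seed 0
tribrats preprocess --cases data/ --out prep/          # QC CSV + corrected tree
tribrats split --cases prep/ --out split.json --seed 0
tribrats train --cases prep/ --plane axial --combo FLAIR,T1ce,T2 --out axial.npz
tribrats predict --case prep/<id> --model axial.npz --model cor.npz --model sag.npz --out masks/
tribrats evaluate --cases prep/ --model axial.npz --model cor.npz --model sag.npz --out report.csv
```

## Layout

```
src/tribrats/
  mri_io.py       NIfTI case IO and the on-disk layout
  synthetic.py    seeded phantom generator + corruption operators
  preprocess.py   Dixon screening, bias correction, resize, z-score
  planes.py       tri-planar slicing, channel combos, inverse mapping
  nets.py         U-Net / EfficientUNet architectures
  nn/             numpy autodiff engine (conv, BN, SE, Adam, GDL)
  metrics.py      confusion counts, accuracy, DSC, generalized Dice
  ensemble.py     plane-model selection, majority voting
  training.py     splits, slice streams, training loop, evaluation
  pipeline.py     end-to-end orchestration (incl. desk-scale study)
  cli.py          the `tribrats` command
docs/methods.md   model details, conventions, limitations
```
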