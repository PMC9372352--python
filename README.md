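# wmhkit

Automatic segmentation and quantification of **white matter hyperintensities
(WMH)** on routine clinical brain MRI acquired with 2D thick-slice protocols
(~5 mm slices, 16–20 slices per series), where most published 3D pipelines
struggle.

WMH are bright lesions on FLAIR/T2-weighted images, a core imaging marker of
cerebral small vessel disease. `wmhkit` is aimed at researchers who need a
testable, end-to-end reference implementation of a thick-slice WMH pipeline:

- **2D VB-Net** — a lightweight fully convolutional encoder–decoder
  (V-Net lineage: residual bottleneck blocks, strided 2×2 down-convolutions,
  transposed 2×2 up-convolutions, per-level skip connections, two-layer
  softmax output head). The default configuration (3 input modalities ×
  3 output classes) has **1.08 M trainable parameters**. The network and its
  training loop run on a small NumPy reverse-mode autodiff core shipped with
  the package — no deep-learning framework required.
- **Two-rater label fusion** — voxels delineated by both raters are
  *definite* WMH, voxels delineated by exactly one are *suspected*; the union
  is the training ground truth.
- **Weighted Dice loss** — per-class soft Dice
  `L = 1 − (1/C) Σ_c 2Σwpg / (Σwp² + Σwg²)` where the WMH-class sums carry
  per-voxel weights `w(x) = 2` on definite WMH and
  `w(x) = 1 + (1 − dis/dis_max)` on suspected WMH (`dis` = mm distance to the
  nearest definite-lesion centroid). Optimized with Adam (0.9, 0.999, lr 1e-3)
  from Kaiming initialization.
- **Evaluation metrics** — voxel Dice/recall/precision, definite-WMH recall,
  lesion-level recall and F1 over 3D connected components, average volume
  difference (AVD, %), and the symmetric 95th-percentile Hausdorff distance in
  physical mm, all cross-checked against brute-force oracles.
- **WMH subclassification** — exact anisotropic Euclidean distance maps split
  WMH into juxtaventricular (≤3 mm from the ventricle), periventricular
  (3–13 mm), juxtacortical (≤4 mm from the corticomedullary junction) and deep
  WMH, or the traditional 2-class split at 10 mm.
- **Correlation statistics** — Spearman correlation of WMH volume (%ICV) with
  ordinal Fazekas scores, and a paired bootstrap (N = 1000) for
  Δr = r_manual − r_algorithm with a percentile 95 % CI.
- **Synthetic phantoms** — seeded multi-modal (T1/T2/FLAIR) thick-slice brain
  phantoms with ventricles, banded WMH lesions, cortical "other" lesions and
  simulated rater pairs, so the whole pipeline is testable without any data
  download.

## Worked example

```python
import numpy as np
from wmhkit.phantom import PhantomSpec, generate_phantom, simulate_raters
from wmhkit.fusion import fuse_pair, build_weight_map, consistency_report
from wmhkit.nn import build_network, tiny_config, count_parameters, default_config
from wmhkit.training import TrainConfig, train, predict
from wmhkit.metrics import metrics_report

print(count_parameters(default_config()))   # 1079843  (~1.08 M)

# 20 seeded thick-slice phantoms with two simulated raters each
data = []
for seed in range(20):
    spec = PhantomSpec(shape=(12, 64, 64), spacing=(5.0, 2.0, 2.0),
                       n_wmh_lesions=5, n_other_lesions=2, seed=seed)
    study = generate_phantom(spec)
    fus = fuse_pair(*simulate_raters(study.truth, spec))
    data.append((study, (fus.union_label, build_weight_map(fus))))

net = build_network(tiny_config(), seed=0)
result = train(net, [d[0] for d in data], [d[1] for d in data],
               TrainConfig.desk_scale(seed=0))
print(result.history.tail(1))
#    epoch  train_loss  val_loss  val_dice
# 7      7    0.319134  0.314395  0.925486

test = generate_phantom(PhantomSpec(shape=(12, 64, 64), spacing=(5, 2, 2),
                                    n_wmh_lesions=5, n_other_lesions=2,
                                    seed=200))
label, probs = predict(result.network, test)
rep = metrics_report(label.data == 1, test.truth.data == 1, test.spacing)
print(round(rep.dice, 3), round(rep.lesion_f1, 3))
# 0.969 1.0
```

The printed numbers: the trained desk-scale network reaches a validation WMH
Dice around 0.93 on the phantom cohort, and voxel Dice 0.97 with every lesion
detected (lesion F1 = 1.0) on a held-out phantom — the FLAIR-hyperintense lesions are learned from the
weighted multi-modal loss, with the "other lesion" class kept separate.

A command-line pipeline mirrors the library:

```bash
wmhkit generate --n 5 --seed 7 --out cohort/
wmhkit preprocess cohort/sub-000
wmhkit train cohort/ --checkpoint model.npz --seed 0
wmhkit segment cohort/sub-000 --checkpoint model.npz --out cohort/sub-000/pred.nii.gz
wmhkit evaluate cohort/ --out metrics.csv
wmhkit subclassify cohort/sub-000 --out volumes.csv
wmhkit correlate cohort.csv --out delta_r.csv
```

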