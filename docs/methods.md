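# Methods

This note documents the models and procedures implemented in `wmhkit`, the
parameter choices that matter, and what the phantom-based evaluation does and
does not demonstrate.

## Problem setting

White matter hyperintensities (WMH) appear bright on FLAIR and T2-weighted
MRI and dark-to-isointense on T1. Routine clinical acquisitions are 2D axial
series with thick slices (≈5 mm) and sub-millimetre in-plane resolution, so
through-plane context is weak and 3D convolutional models are poorly matched
to the data. The package therefore treats a study as a stack of 2D slices for
learning, while all *distances* (loss weights, Hausdorff, subclassification
bands) are computed in 3D physical millimetres using the anisotropic voxel
spacing. Label codes are 0 background, 1 WMH, 2 other intracranial lesion
(lacunes, perivascular spaces, cortical infarcts — lesions that can also be
FLAIR-bright and are only separable with multi-modal information).

## Preprocessing

Bias-field correction, inter-modality registration, and skull stripping are
the province of established external tools; `wmhkit` consumes their outputs
and *asserts* co-registration (identical shape and spacing across T1/T2/FLAIR
and masks) instead of silently resampling.

In-package preprocessing is:

- **Quantile normalization**: intensities are mapped to [0, 1] linearly
  between the 0.1 % and 99.9 % landmarks of the sorted intensity
  distribution, clamping below/above. Quantiles use the nearest-rank rule
  (value at rank ⌈qn⌉), which is exactly reproducible across platforms.
  When a brain mask is supplied the landmarks are computed inside it;
  normalization runs after skull stripping, and the background zeros would
  otherwise dominate the lower landmark. (Whether the landmarks should be
  mask-restricted is an open choice; mask-restricted is this package's.)
- **In-plane resampling** to a common pixel spacing (0.5 mm for the
  paper-scale protocol), linear for images and nearest-neighbour for labels
  and masks; the z axis is never resampled.

## Rater fusion and the loss weight map

Two independent delineations of the same study are fused per class into
their union (the training ground truth). For WMH, voxels marked by **both**
raters are *definite*, voxels marked by exactly one are *suspected*. When
one rater calls a voxel WMH and the other calls it "other lesion", the union
keeps WMH, so definite ∪ suspected always equals the union WMH mask.

The per-voxel loss weight is

- 2 on definite WMH,
- `1 + f(dis)` on suspected WMH with `f = 1 − dis/dis_max ∈ [0, 1]`, where
  `dis` is the Euclidean mm distance from the voxel to the **centroid** of
  the nearest definite connected component (26-connectivity; nearest by
  centroid distance, which is deterministic and parameter-free), and
  `dis_max` is the per-volume maximum of `dis` over all suspected voxels so
  that `f` spans [0, 1] exactly,
- 1 everywhere else, including other-lesion voxels.

Degenerate cases are defined, not special-cased downstream: no definite WMH
→ all suspected weights are 1; all suspected voxels equidistant (including a
single suspected voxel, or `dis_max = 0`) → weight 1. Weights therefore
always lie in [1, 2].

The labeling protocol's guard rail is also implemented: the Dice agreement
of two delineations with a 0.5 pass/fail threshold, plus a cohort-level
Pearson correlation of rater volumes. Silver-standard consensus labels from
≥3 raters use per-voxel majority voting with ties resolved toward the lower
class code (background-conservative) and a tie count reported.

## 2D VB-Net

A five-level fully convolutional encoder–decoder:

- input block: 3×3 convolution (3 modality channels → 24), batch norm,
  per-channel PReLU;
- encoder: 2×2 stride-2 convolutions between levels with channel widths
  24 / 48 / 96 / 192 / 280 and (1, 2, 3, 3, 2) residual bottleneck blocks per
  level. Each bottleneck block is 1×1 reduce (ratio 4) → 3×3 → 1×1 expand
  with a residual addition — the canonical structure that shrinks feature
  maps to keep the model small;
- decoder: 2×2 transposed convolutions, additive per-level skip connections
  from the encoder, and (1, 2, 3, 2) bottleneck blocks per level. Additive
  (rather than concatenative) skips were chosen to keep channel widths and
  the parameter count symmetric between the two paths;
- output head: two convolutional layers (3×3 then 1×1 classifier) and a
  channel softmax, so per-voxel class probabilities sum to 1.

Block counts are deliberately reduced at the deepest levels: with only three
output classes the widest levels do not need many bottleneck structures, and
trimming them is what keeps the default configuration at **1,079,843**
trainable parameters (≈1.08 M — convolution kernels and biases, batch-norm
affine terms, PReLU slopes). `count_parameters` computes this analytically
from the configuration and the test suite verifies it equals the
instantiated network exactly; the count is independent of crop size because
the network is fully convolutional. Exact per-level widths live in
`configs/vbnet_default.json`, not in code. Normalization (batch norm) and
activation (PReLU) follow the V-Net convention; they are configuration
choices, not derived requirements.

The network runs on a small tape-based reverse-mode autodiff engine over
NumPy (`wmhkit.nn.autodiff`) with GEMM-based im2col convolutions and fused
batch-norm/PReLU/softmax operations; every operation's gradient is verified
against central finite differences in double precision. Default compute
precision is float32.

## Training

Loss: multi-class soft Dice,
`L = 1 − (1/C) Σ_c 2Σᵢwᵢpᵢgᵢ / (Σᵢwᵢpᵢ² + Σᵢwᵢgᵢ² + ε)`, with ε = 1e-5 in
the denominator only. The weight map enters the accumulators of the **WMH
class only** — this is the reading under which the loss degenerates exactly
to the unweighted Dice loss at w ≡ 1 and under which re-weighting WMH voxels
leaves the background and other-lesion class terms untouched. The softmax
head (exclusive classes) feeds the loss.

Optimization: Adam with moment coefficients (0.9, 0.999) and learning rate
1e-3, Kaiming-normal initialization, seeded throughout. The learning-rate
schedule is constant with best-validation checkpoint selection (epoch count
and schedule are configuration choices). Patches are sampled randomly from
axial slices with lesion-bearing slices oversampled 5:1 (the class-balance
strategy is a configuration choice); patches larger than a slice are
symmetrically zero-padded with neutral weight 1. Divergence (NaN loss)
aborts with a diagnostic rather than continuing.

Two named protocols ship with the package:

- **paper-scale**: 256×256 patches, mini-batch 48, 0.5 mm in-plane
  resampling — the printed protocol, impractical on a laptop CPU;
- **desk-scale**: 64×64 patches, mini-batch 8, 8 epochs × 50 steps — sized
  so a full training run on 20 small phantoms takes a couple of CPU minutes.

Inference is fully convolutional: whole slices are padded to the next
multiple of 2^(levels−1), passed through the network in inference mode
(batch-norm running statistics), argmax-labelled with ties toward the lower
class code, and masked to the brain.

## Evaluation metrics

Voxel level: Dice = 2TP/(2TP+FP+FN), recall = TP/(TP+FN), precision =
TP/(TP+FP); recall is additionally computed against the definite-WMH mask
alone. Lesion level: lesions are 3D connected components (26-connectivity; 8
in-plane for single-slice fixtures), a truth lesion is *detected* iff at
least one predicted voxel overlaps it (the minimal consistent reading — no
overlap fraction is imposed), lesion recall/precision are detected/total for
truth/predicted components, lesion F1 is their harmonic mean. AVD =
|A−B|/B × 100 with B the truth volume. Hausdorff95 is the max of the two
directed nearest-rank 95th-percentile nearest-neighbour distances in
physical mm, symmetric by construction.

Empty-mask conventions (the literature leaves these unstated; these are this
package's): both masks empty → perfect score (1, or 0 mm); a ratio with an
empty reference (recall with empty truth, AVD with empty truth, Hausdorff
with one empty mask) → NaN, never a sentinel value. Cohort summaries average
per-subject metrics (NaN-aware) rather than pooling voxels.

All metric implementations are tested against brute-force oracles
(all-pairs distances, explicit flood fill, per-voxel tallies) on ≥100 random
fixtures.

## Subclassification

An exact anisotropic Euclidean distance transform from the ventricle mask
(0 inside the ventricles) drives two partitions of the WMH mask:

- **4-class (Kim)**: juxtaventricular ≤3 mm, periventricular 3–13 mm, then
  juxtacortical ≤4 mm from the corticomedullary junction, deep otherwise.
  Precedence is ventricle-first (JV → PV → JC → DW): a voxel at 8 mm from
  the ventricle and 2 mm from the cortex is periventricular. Band edges are
  inclusive ("within N mm" read as ≤N); both the precedence and the edge
  convention are recorded choices since the criteria as usually quoted do
  not resolve them.
- **2-class (traditional)**: periventricular ≤10 mm, deep otherwise.

The corticomedullary junction is operationalized as the inner cortical
ribbon; phantoms generate this ribbon explicitly, and on real data the user
supplies a cortex/junction mask — the package does not segment cortex. A
ventricle mask on real data likewise comes from an external segmentation
(the training module can be reused with a ventricle-label phantom
configuration). Volumes are reported per class in mm³ and as % of
intracranial volume; the classes partition the WMH mask, so they sum to the
total exactly.

## Correlation statistics

Spearman rank correlation (average ranks on ties, ≥5 subjects) relates WMH
volume (%ICV) to the ordinal Fazekas score (0–6 total, as the sum of 0–3
periventricular and 0–3 deep scores). To compare a manual and an algorithmic
volume series against the same scores, the package computes
Δr = r_manual − r_algo and a **paired** bootstrap 95 % CI: subjects are
resampled with replacement keeping each (manual, algo, score) triple
together, because the two correlations share subjects. The CI is the
2.5/97.5 percentile of replicates (the minimal reading of a bootstrap CI;
no bias correction), significance means the CI excludes 0, and no
multiplicity correction is applied. Replicates in which any resampled
vector is constant have an undefined rank correlation; they are dropped and
counted.

## Synthetic phantoms

Each phantom is an ellipsoidal "brain" with two mirrored lateral-ventricle
lobes and a 3 mm cortical ribbon on an anisotropic grid (default 18×128×128
at 5×1×1 mm; the desk-scale cohort uses 12×64×64 at 5×2×2 mm so the same
physical geometry fits a smaller grid). WMH lesions are irregular blobs —
thresholded smoothed noise around a seed, confined to one slice and to their
target distance band — drawn from a mixture over the four bands (default
0.25/0.35/0.25/0.15 JV/PV/DW/JC). Other-lesion blobs sit within 6 mm of the
cortex. Per-modality tissue means (on the normalized [0, 1] scale) encode
the clinical contrast pattern: WMH bright on FLAIR (0.85 vs 0.40 white
matter) and T2, mildly dark on T1; the other-lesion class near-CSF on T1 and
bright on T2/FLAIR, so only multi-modal information separates the two
classes; CSF suppressed on FLAIR. Gaussian noise with σ = 0.03 of the
intensity range is added. Lesion counts default to 6 WMH + 2 other at full
scale (5 + 2 at desk scale). These defaults are fixed study conditions, not
tuning knobs.

Simulated raters copy the truth and independently drop a `rater_disagreement`
fraction (default 0.3) of the one-voxel inner boundary shell of the WMH
mask, computed per slice — mimicking boundary-localized disagreement without
destroying lesion cores. Disagreement 0 reproduces the truth exactly;
disagreement 1 erodes both raters to the per-slice core.

**What the phantoms do not model**: MR physics (bias fields, partial volume,
motion), registration error, skull, realistic lesion texture or
confluence, and rater disagreement away from boundaries. Passing tests on
phantoms therefore demonstrate the correctness and trainability of the
pipeline — not clinical segmentation accuracy; the held-out phantom Dice
(≈0.9) is a property of an easy synthetic contrast task, and the 0.70
acceptance threshold is an engineering floor for the learning machinery.

## Numerical and degenerate-input choices

- Distances in mm via the voxel spacing everywhere; 26-connectivity for 3D
  components; nearest-rank percentiles.
- Argmax ties at inference go to the lower class code.
- Quantile normalization of a constant volume is an error naming the
  modality; empty brain masks and empty distance-map references are errors.
- Majority voting requires ≥3 raters; ties are counted and reported.
- Seeds: every stochastic routine takes an explicit seed or derives one from
  a `numpy` `SeedSequence`; identical seeds give bit-identical phantoms and
  reproducible training on a single device.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: 12×64×64
phantoms (5×2×2 mm), the `tiny` network configuration (3 levels, 12/24/48
channels, 18,405 parameters), 20 training + 5 held-out phantoms, 400 Adam
steps, and 20 bootstrap cohorts of n = 100 with 1,000 replicates each. The
paper-scale network configuration is instantiated for parameter accounting
but not trained by the tests.

## Known limitations

- The NumPy autodiff core is single-threaded apart from BLAS; paper-scale
  training (256×256, batch 48) is out of reach on CPU — the configuration is
  provided for architecture accounting and for users with patience or a
  faster backend.
- Batch-norm running statistics make inference deterministic but mean that
  severely under-trained networks (e.g. 1-step smoke runs) can predict a
  single class everywhere.
- The phantom's cortical ribbon is a geometric stand-in for the
  corticomedullary junction; juxtacortical volumes on real data depend
  entirely on the quality of the supplied cortex mask.
- `bootstrap_delta_r` drops degenerate replicates rather than redrawing
  them; with heavily tied scores and tiny cohorts the effective replicate
  count can fall below the nominal N (it is reported).
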