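# Methods

## Segmentation model

The dual-path network predicts a binary tumor mask for one axial slice of
one respiratory phase from two 3-slice stacks: the spatial triplet
(adjacent slices within the phase) and the temporal triplet (the same
slice index in the previous/current/next phase). Phase adjacency is cyclic
— the 0%–90% phases sample one periodic breathing cycle, so phase 0's
predecessor is phase P−1; clamping instead would starve the two end phases
of a temporal neighbor. Slice adjacency clamps at the volume edges because
anatomy is not periodic along the scan axis.

Each path is a standard 5-level U-Net encoder: per level two 3×3
convolutions each followed by batch normalization and ReLU, then 2×2 max
pooling; channel widths double from the base width C (64 at full scale) to
16C at the bottleneck, spatial side shrinks by 16. The two paths share
structure but not weights. The triplet enters as 3 input channels of a 2D
convolution — the only reading under which the first layer consumes all
three slices at once.

The fusion block concatenates the two bottleneck maps (32C channels) and
gates them twice, CBAM-style. The channel gate pools the concatenated map
globally by average and by max, pushes both 32C-vectors through one shared
MLP (32C → max(32C/r, 4) → 32C, r = 16), sums, and applies a sigmoid; the
spatial gate pools channel-wise (average and max), concatenates the two
1-channel maps and convolves them with a single 7×7 kernel into a sigmoid
map. Both gates are strictly inside (0, 1), so gated features never exceed
the raw ones elementwise. A 1×1 convolution then adjusts 32C back to 16C —
the minimal parameterization of a channel-adjust layer — before a single
decoder (four upsample–concat–double-conv stages with output widths 16C,
8C, 4C, 2C and a final 3×3 convolution to one logit channel) reconstructs
the slice. Decoder skips come from the spatial path only: the prediction
target is the center slice of the spatial triplet, and temporal evidence
reaches the decoder through the fusion bottleneck. Upsampling is bilinear
interpolation followed by convolution (a `nearest` flag exists). Weights
are Kaiming-uniform, seeded; biases start at zero.

The five-slice single-path U-Net (inputs
`{I_p^{k−1}, I_{p−1}^k, I_p^k, I_{p+1}^k, I_p^{k+1}}` as 5 channels,
identical blocks, own-encoder skips) serves two roles: the comparator with
an input budget matched to the dual-path model, and the liver-stage model
of the two-stage pipeline.

## Compute engine

The networks run on a small reverse-mode autodiff engine over numpy arrays
(`st4dseg.nn`): stride-1 'same' convolution via im2col + GEMM, 2×2 max
pooling, ×2 bilinear upsampling as a cached sparse interpolation matrix,
batch normalization with running statistics, the pooled reductions used by
the attention gates, and a fused BCE-with-logits loss. Every primitive's
gradient is verified against central differences in float64 in the test
suite. Float32 is the training dtype.

## Loss and optimization

BCE-with-logits in the log-sum-exp form
`(1−y)x + (1 + (w−1)y)·softplus(−x)` — the sigmoid is never materialized,
so ±50-logit inputs stay finite. The positive-class weight w is the
background/tumor pixel ratio of each batch, clipped to [1, 50]; an
all-background batch falls back to the cap. Optimization is Adam
(lr 1e−4 as the general default; the desk-scale experiments use 1e−3,
recorded in their config), batch 8, left-right flip augmentation only
(rotations would scramble the anterior-posterior / superior-inferior
motion semantics), model selection by best validation Dice with early
stopping, binarization at sigmoid 0.5. Training slices are those whose
label contains at least one tumor pixel plus an equal number of random
negatives — batch-level loss weighting alone cannot fix the slice-level
imbalance.

## Phantom

The phantom stands in for clinical free-breathing liver 4D-CT. Defaults:
64×64×24 voxels at (1.5, 1.5, 3.0) mm — the clinical 3 mm slice thickness
with a reduced in-plane matrix (512×512 at 0.977 mm is supported but not
default) — 10 phases, a liver ellipsoid at mean 106.5 HU containing a
tumor ellipsoid at mean 25.0 HU (the measured contrast situation that
makes 4D-CT delineation feasible at all), background −80 HU, Gaussian
noise sd 12 HU. Organ motion is a raised cosine
`d(p) = A(1 − cos(2πp/P))/2` — zero at end-inspiration (0%), maximal at
end-expiration (50%) — applied along SI and AP; per-subject amplitudes are
drawn uniformly from the observed patient ranges, SI 5.3–16.1 mm and AP
2.1–8.0 mm. Masks are integer-voxel translations of the phase-0
ellipsoids, so tumor volume is exactly conserved across phases and labels
stay sharp.

Motion blur is the phantom's key feature: the image (never the labels) is
Gaussian-blurred with sigma proportional to the inter-phase displacement
step, up to `blur_sigma_mm` (default 1.5 mm, a free parameter — the
blurred-boundary effect is qualitative, not quantified, in the clinical
literature) at the fastest-moving intermediate phases. Resolving the
blurred boundary therefore requires temporal context, which is precisely
the mechanism the dual-path model is built to exploit — and what the
comparative test measures.

What the phantom does *not* emulate: CT reconstruction physics (beam
hardening, irregular-breathing artifacts), deformable organ motion (pure
translation only), multiple lesions, inter-organ anatomy, metallic
markers. Passing tests therefore demonstrate that the implementation
learns and exploits spatio-temporal structure as designed — not clinical
performance, which can only be established on patient data.

Dataset splits are BY SUBJECT: all phases of one synthetic subject stay in
one split, because phases of one 4D-CT are near-duplicates and a set-level
split would leak.

## Two-stage pipeline

Liver first (five-slice model, largest connected component kept per
phase), then one ROI per subject — the bounding box of the union of all
phase livers, margin-expanded, in-plane sides padded up to multiples of 16
so four poolings divide evenly — applied identically to every phase so
temporal triplets stay spatially aligned. GTV inference runs per slice
inside the ROI and is re-embedded into the full volume geometry before any
metric is computed; GTV masks get no post-processing. The IGTV is the
exact voxelwise union of the per-phase predictions.

## Metrics

DSC with both-empty defined as 1.0 and one-empty as 0.0; HD95 via
6-connected surface extraction (erosion difference), anisotropic Euclidean
distance transform in mm, linear-interpolation percentile of each directed
distance set, symmetrized by max, and *undefined* (reported missing, never
0) for an empty mask; VD signed as truth-minus-prediction in cc (positive
= under-segmentation), with |VD| carried alongside for magnitude-style
comparison. All three are verified against brute-force oracles (all-pairs
surface distances, explicit voxel counting) on 50 random small mask pairs
per run.

## Scaled recovery experiment

The end-to-end study (`st4dseg.experiments`, also driven by
`scripts/acceptance.py`) runs at desk scale: 10 subjects split 6/2/2, base
width 8, GTV training on fixed 48×48 liver-centered crops, a budget of 3
epochs × 30 steps for the liver model and 8 epochs × 25 steps (batch 8,
lr 1e−3) for each GTV model, three training seeds per architecture with
one shared cohort and liver model. These sizes keep the whole study at
roughly ten minutes on one CPU while leaving the learning problem
non-trivial (motion-blurred boundaries, per-subject geometry and amplitude
jitter, 12 HU noise). The quantities reported are the median-over-seeds
mean test DSC per architecture, their paired difference, pooled HD95 and
|VD|, and the liver-stage validation DSC.

## Numerical and degenerate-input choices

HU normalization window (−200, 300): brackets the tumor (−171…497) and
liver (10…228) HU ranges; values outside clip to [0, 1]. Max-pool ties
resolve to the first maximum (argmax order); BN uses batch statistics in
training and running statistics (momentum 0.1) at inference; the
percentile rule is numpy's linear interpolation; the binarization
threshold is fixed at 0.5. Empty mask sets, non-binary masks, indivisible
input extents, out-of-range phase/slice indices, tumor ellipsoids leaving
the image under motion, and degenerate ROI boxes all raise informative
errors rather than propagating silently.

## Known limitations

The phantom's translation-only motion makes the segmentation task easier
than deformable clinical anatomy; desk-scale budgets stop training well
before convergence plateaus; the numpy engine is single-device and
single-precision; DICOM/RT-STRUCT clinical interchange is out of scope
(NIfTI-1 is the I/O dialect throughout).
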