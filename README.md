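# st4dseg

Automatic internal gross target volume (IGTV) delineation from respiratory
4D-CT with a spatial-temporal dual-path segmentation network.

## The problem

Radiotherapy planning for liver tumors must account for respiratory motion:
the liver moves by up to several centimetres over a breathing cycle, so a
tumor contour drawn on a single static CT under- or over-covers the true
excursion. 4D-CT sorts the acquisition into P (typically 10) respiratory
phases — 0% end-inspiration through 50% end-expiration and back — and the
clinically ideal workflow delineates the gross target volume (GTV) on
*every* phase and merges the per-phase contours into the IGTV. Doing that
by hand for all ten phases is prohibitively laborious, which is what this
package automates.

Tumor boundaries on intermediate phases are blurred by motion during
reconstruction, and the blurred band's intensity is close to normal liver —
a single-phase model tends to misclassify it. A clinician resolves the
ambiguity by looking at the *adjacent phases*; the network here does the
same thing architecturally.

## The model

For the slice `I_p^k` (phase `p`, axial slice `k`) the network consumes two
triplets:

* spatial: `I_S = {I_p^{k-1}, I_p^k, I_p^{k+1}}` — anatomical context
  within the phase (slice edges clamp);
* temporal: `I_T = {I_{p-1}^k, I_p^k, I_{p+1}^k}` — the same slice across
  adjacent phases (phase edges wrap: breathing is periodic).

Each triplet enters its own 5-level U-Net encoder (two 3×3 conv–BN–ReLU
blocks per level, 2×2 max pooling, channels C…16C; for 512×512 input and
C = 64 the bottleneck is 32×32×1024). The two bottleneck maps are fused by
a CBAM-style attention block:

```
M_C = σ( MLP(AvgPool[F_s, F_t]) + MLP(MaxPool[F_s, F_t]) )   (channel gate)
M_S = σ( conv7x7[ AvgPool_c(F′) ; MaxPool_c(F′) ] )          (spatial gate)
F′  = M_C ⊙ [F_s, F_t],   F″ = M_S ⊙ F′
```

followed by a 1×1 convolution back to 16C channels. A single decoder
(skip connections from the spatial path) upsamples to a one-channel logit
map for the center slice. Training minimizes BCE-with-logits with a
positive-class weight equal to the background/tumor pixel ratio of the
batch (clipped to [1, 50]).

The full two-stage pipeline first segments the liver with a five-slice
single-path U-Net, crops to the union-of-phases liver bounding box, runs
the dual-path network per phase inside the ROI, and merges the per-phase
GTVs into the IGTV by exact voxelwise union. Evaluation uses the Dice
similarity coefficient (DSC), the 95th-percentile symmetrized surface
distance (HD95, mm), and the signed volume difference (VD, cc,
truth minus prediction).

Because clinical 4D-CT cannot be redistributed, the package ships a
synthetic respiratory phantom (`st4dseg.phantom`): a liver-like ellipsoid
(≈106.5 HU) containing a tumor-like ellipsoid (≈25 HU) translated by a
raised-cosine displacement with per-subject SI amplitudes in 5.3–16.1 mm
and AP amplitudes in 2.1–8.0 mm, with image-only motion blur at
fast-moving phases and noise-free labels. All training and evaluation in
the tests runs on this phantom.

## Worked example

```python
from st4dseg.phantom import PhantomConfig, generate_phantom
from st4dseg.core import merge_igtv
from st4dseg.metrics import evaluate_subject

subject = generate_phantom(PhantomConfig(seed=3))
truth = merge_igtv(subject.masks)
print([int(subject.masks.phase(p).sum()) for p in (0, 5)], int(truth.igtv.sum()))
report = evaluate_subject(truth, subject.masks)
print(report.row("IGTV"))
```

prints

```
[519, 519] 1077
{'phase': 'IGTV', 'hd95_mm': 0.0, 'dsc': 1.0, 'vd_cc': 0.0, 'abs_vd_cc': 0.0}
```

i.e. the tumor occupies 519 voxels in every phase, its respiratory
excursion sweeps out a 1077-voxel IGTV (about twice the single-phase
volume at ~11 mm SI amplitude), and a prediction identical to the truth
scores DSC 1.0 / HD95 0.0 mm / VD 0.0 cc on every row of the per-phase
report.

The CLI exposes the same functionality: `st4dseg phantom`, `st4dseg train`,
`st4dseg predict`, `st4dseg evaluate`, and `st4dseg summary` (which prints
the full-scale per-layer shape table of the dual-path network).

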