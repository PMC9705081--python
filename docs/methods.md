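# Methods

## Problem and pipeline

Pterygium is a wing-shaped fibrovascular overgrowth of the conjunctiva that
invades the cornea from the nasal side; when it advances toward the visual
axis it impairs vision and must be resected, and both diagnosis and surgical
planning hinge on locating the lesion on anterior-segment (slit-lamp)
photographs. This package implements a two-stage pipeline: (1) image-level
screening — four classical CNNs decide normal vs. pterygium; (2) pixel-level
delineation — PSPNet-family segmenters mark the lesion area.

## Screening classifiers

AlexNet, VGG16, ResNet18 and ResNet50 are rebuilt with one change: an
adaptive average pooling stage inserted between the convolutional trunk and
the first fully connected layer. The pooling grid equals the grid the
original FC layer expects (6×6 AlexNet, 7×7 VGG16, 1×1 ResNets), so the
flattened feature size is independent of input size and the networks accept
the native 336×224 (width×height) frame rather than a 224×224 crop.
Canonical-grid pooling also keeps full-width FC weights loadable from
external checkpoints.

Training: cross-entropy loss; SGD with momentum 0.9 (the optimizer is a
package choice — exposed in the schedule); learning rate 0.001 for 30 epochs
(AlexNet, VGG16) or 0.01 for 100 epochs (ResNets); random ±3° rotation
augmentation; batch size 8 by default. The returned model is the checkpoint
with the **best validation accuracy** over all epochs, not the last epoch.
The training pool is split 9:1 into train/validation (seeded, unstratified;
367 records split 330/37).

`width_scale` multiplies every channel/feature width (`max(1, round(c·s))`).
It is an artifact addition for CPU-scale work; `width_scale=1.0` reproduces
the canonical architectures. `pretrained_init` accepts a local checkpoint
path; no weights ship with the package, and all tests run from seeded random
(He) initialization.

## Segmentation models

Inputs are letterboxed to a square with gray (128,128,128) bands — masks with
zeros — and resized to 473×473 (bilinear for images, nearest-neighbor for
masks so they stay binary). Both trunks run at **output stride 16**, so 473
maps to the 30×30 working grid (ceil(473/16)); the canonical dilated
stride-8 PSPNet trunk is deliberately not used because it would put the grid
at 60×60. The ResNet50-style trunk reaches stride 16 by running its fourth
stage at stride 1; the MobileNet trunk is an inverted-residual (V2-style)
stack with strides 2,2,2,2,1.

The pyramid pooling module (PPM) average-pools the working-grid feature map
at 1×1, 2×2, 3×3 and 6×6, reduces each pooled map to `C_r = C/4` channels
with a 1×1 conv + BN + ReLU (the PSPNet convention; the reduction ratio is
not otherwise prescribed), bilinearly upsamples each branch back to the grid
and concatenates with the backbone map.

**Stage upsampling module / PPM+.** The four *pooled, channel-reduced
branches* are additionally fused by a cascade: the 1×1 branch is bilinearly
enlarged to 2×2 and added element-wise to the 2×2 branch; the sum is
enlarged to 3×3 and added to the 3×3 branch; then to 6×6 and added to the
6×6 branch; the result is enlarged to the working grid. Appending this fused
map to the PPM concatenation gives PPM+ — exactly one branch more than PPM
(head input channels `C + 5·C_r` vs `C + 4·C_r`). Reading the cascade's
inputs as the pooled branches (rather than backbone stage outputs) is the
central interpretive decision: the cascade's first ×2 step maps 1×1 → 2×2
exactly, the branches share a channel count so element-wise addition is
well-defined without extra projections, and the module is described as part
of the pyramid pooling block. The alternative reading (backbone stages)
would require per-stage projections the source never mentions.

*Phase-fusion PSPNet* = ResNet50-style trunk + PPM+ + output block
(3×3 conv + BN + ReLU, then 1×1 conv to the class maps) + bilinear upsample
to input resolution + per-pixel softmax.

*Double phase-fusion PSPNet* adds a second, independently weighted PPM+ and
output block on the shallow features — the tensor entering the third
residual stage (1/8 scale, 512 channels at full width). Its class maps are
bilinearly resized to the deep 30×30 grid (addition requires equal shapes;
the alignment step is a package choice) and added element-wise to the deep
maps before the final upsample. Weights are **not** shared between the two
PPM+ heads; the description of the shallow branch constrains shapes, not
parameters.

Segmentation training: per-pixel cross-entropy over {background, lesion}
(the loss is a package choice), SGD + momentum, 80 epochs by default, and
checkpoint selection by best validation MIOU.

## Evaluation metrics

Pixel metrics come from a pooled confusion matrix `p[i,j]` (true i,
predicted j) over the k+1 classes including background:
`IOU_i = p_ii / (Σ_j p_ij + Σ_j p_ji − p_ii)`, `MIOU = mean_i IOU_i`,
`PA = Σ p_ii / Σ p_ij`, `MPA = mean_i (p_ii / Σ_j p_ij)`. Dataset scores
**micro-average**: confusions are summed over all images before the
divisions (whether the original evaluation pooled or averaged per image is
not stated; pooling is the documented choice here and it changes results).
A class absent from both prediction and truth contributes 1 to the means
(documented convention; never exercised by the published evaluation). Note
a naming wrinkle: some summaries label MPA/PA "mean average precision"/
"average precision", but the defining formulas are pixel-accuracy
quantities; the formulas as printed are what is implemented.

Screening indicators from a hard-label 2×2 confusion matrix: per-class
sensitivity (recall), specificity (the other class's recall), F1, accuracy,
Cohen's kappa, and the **single-operating-point AUC** — the area under the
two-segment ROC through (0,0), (1−specificity, sensitivity), (1,1), i.e.
(sensitivity+specificity)/2. A hard-label classifier has exactly one
operating point, and this definition reproduces all four published AUCs
(0.97 / 0.99 / 0.94 / 0.93) from the diagnostic counts, which a
score-threshold ROC could not without per-image probabilities. Indicators
with an empty margin are reported as undefined (None) rather than poisoning
the rest of the report. Displayed values round half-up to two decimals.

## Numerical conventions

- All resampling is **corner-aligned** bilinear (nearest for masks), both in
  preprocessing and inside the networks, so the fusion-cascade oracle and
  the resize oracles are bit-comparable. No antialiasing filter is applied
  on downscale.
- Padding splits bands equally; an odd remainder goes to the bottom/right.
- Rotation fills out-of-frame pixels with 0 (image and mask; a gray fill
  would fabricate lesion-colored context, a nonzero mask fill would
  fabricate lesions); positive angles turn content counterclockwise about
  the pixel-center.
- The networks run in float32 on a small numpy tape-autodiff engine written
  for this package (conv via im2col, exact adjoints for every op — verified
  against central differences in the test suite). Argmax ties in prediction
  resolve toward "normal" (index 0).
- BatchNorm uses momentum 0.1 and eps 1e-5, with unbiased running variance.

## Synthetic phantom

The clinical images (1034 photographs from a hospital partner) are private,
so the package ships a seeded phantom generator: elliptical sclera on a dark
lid background, concentric iris and pupil disks, jittered episcleral vessel
polylines, additive Gaussian noise (sd 6 intensity units), and — for
positives — a wedge growing from the nasal margin across the limbus onto
the cornea, recolored to a fleshy tone with extra internal vessels. The mask
equals the wedge support exactly, by construction. Positive extents are
drawn uniformly from [0.15, 0.8] of the corneal radius (neither sub-pixel
nor full-cornea); wedge area grows strictly with extent at fixed seed.

What the phantom does *not* emulate: slit-lamp optics, specular highlights,
reflections, vendor color profiles, eyelids/lashes occlusion, diffuse or
atypical lesion margins, acquisition variability between devices. Passing
training tests on phantoms therefore demonstrates that the pipeline's
mechanics (shapes, gradients, checkpointing, metrics) are sound and that the
models can fit a color/shape-separable lesion — not clinical performance.

## Problem sizes used by tests and the acceptance script

Tests and the acceptance script run reduced configurations — the package's
own desk-scale study conditions: classifiers at `width_scale` 0.25 on 64 px
phantoms (16-sample overfit; 64 train / 32 held-out separability), segmenters
at `width_scale` 0.125 on 129 px inputs (8-pair overfit, 200 optimizer
steps), and full-geometry (473 px, `width_scale` 0.25) forward passes for the
architecture contracts.

## What is, and is not, reproduced

The published headline numbers were measured on the private clinical test
set after GPU-scale training: 99% screening accuracy with AUC 0.99 (VGG16),
and MIOU 86.57%, lesion IOU 78.1%, MPA 92.3%, PA 86.96% for the double
phase-fusion segmenter. Those figures are **not reproducible** here — the
clinical images are unavailable and desk-scale training is orders of
magnitude smaller — and this package makes no claim to reproduce them by
retraining. What *is* reproduced exactly is everything derivable from the
published tables: all screening indicator cells recompute from the printed
diagnostic counts (the acceptance suite checks every cell), and the
architecture, metric and training contracts are verified by property tests
and oracle comparisons on synthetic data.

U-Net and DeepLabv3+ baselines, the three-stage pterygium grading task, CI
computation for AUC, and any statistical-package workflow are out of scope.

## Known limitations

- The numpy engine targets clarity and testability; it is single-device,
  eager, and far slower than a GPU framework at full width.
- `width_scale` changes capacity, so reduced-width results are smoke-level
  evidence only.
- The phantom's lesion is color-separable almost by construction; real
  lesions are not, and no domain-shift robustness is claimed.
- Hard-label AUC is a two-segment trapezoid; it is not comparable to
  probability-threshold AUCs from other studies.
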