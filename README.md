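# pterynet

Pterygium screening and lesion-area segmentation on anterior-segment
(slit-lamp) photographs, for ophthalmology imaging researchers and engineers
who need a fully testable, desk-scale implementation of the two-stage
pipeline: classify an eye photograph as *normal* vs *pterygium*, then
delineate the lesion pixel-by-pixel to support diagnosis and surgical
planning.

## What is inside

- **Classifier zoo** (`pterynet.classifiers`) — AlexNet, VGG16, ResNet18 and
  ResNet50, each with an adaptive average pooling stage inserted before the
  first fully connected layer so they accept the native 336×224 frame (and
  any other size above the trunk minimum). Training: cross-entropy, SGD,
  lr 0.001/30 epochs (AlexNet, VGG16) or 0.01/100 epochs (ResNets), ±3°
  rotation augmentation, best-on-validation checkpoint selection.
- **Segmenter family** (`pterynet.pspnet`) — PSPNet with MobileNet or
  ResNet50-style backbones at output stride 16 (473×473 input → 30×30
  working grid), plus two extended variants:
  - *phase-fusion PSPNet*: the pyramid pooling module (average pooling at
    1×1, 2×2, 3×3, 6×6 with 1×1-conv channel reduction to `C_r = C/4`) is
    extended by a **stage upsampling module** — the 1×1 branch is bilinearly
    enlarged and element-wise added up the scale ladder
    (1→2, +b₂, →3, +b₃, →6, +b₄, →grid) — giving PPM+ with exactly one
    branch more than PPM;
  - *double phase-fusion PSPNet*: a second PPM+ head on the shallow backbone
    features (the 1/8-scale tensor entering the third residual stage), its
    class maps resized and added element-wise to the deep head's before the
    final upsample.
- **Metrics** (`pterynet.metrics`) — pixel metrics from pooled confusion
  counts (IOU, MIOU = mean over classes incl. background, PA, MPA) and
  screening indicators from a 2×2 confusion matrix (sensitivity,
  specificity, F1, accuracy, Cohen's kappa, single-operating-point
  AUC = (sensitivity+specificity)/2, two-segment ROC).
- **Synthetic phantom** (`pterynet.synthetic`) — a seeded generator of
  eye-like images (sclera, iris, pupil, vessels, noise) with an exact
  wedge-lesion mask for positives. The clinical dataset behind the original
  study is private, so the phantom makes every training and evaluation path
  runnable and bit-reproducible.
- **Preprocessing/IO** (`pterynet.preprocess_io`) — PNG/CSV readers and
  writers, gray-128 letterboxing + 473×473 resize for segmentation,
  336×224 resize for classification, seeded 9:1 train/validation splits
  (367 records → 330/37).
- **numpy autodiff engine** (`pterynet.nn`) — a compact tape-autograd with
  conv/BN/pooling/bilinear ops and SGD, written for this package and
  gradient-checked in the test suite; no GPU framework required.

## Worked example

Generate a phantom dataset, train a reduced-width screening classifier and a
reduced-width phase-fusion segmenter, and score both:

```sh
pterynet gen-data --out data --n-normal 12 --n-pterygium 12 --size 96 --seed 7
pterynet train-classify --data data --out cls --arch resnet18 \
    --width-scale 0.25 --epochs 10 --input-h 96 --input-w 96 \
    --batch-size 4 --seed 7
pterynet eval-classify --data data --checkpoint cls/classifier.npz --out eval
pterynet train-segment --data data --out seg --variant phase_fusion \
    --width-scale 0.125 --input-size 129 --epochs 50 --lr 0.05 \
    --batch-size 2 --val-every 5 --seed 7
pterynet eval-segment --data data --checkpoint seg/segmenter.npz --out segeval
```

The classifier separates the phantom classes perfectly (they differ by a
color-distinct lesion wedge), and the segmenter output prints:

```
MIOU 84.97%  IOU 70.82%  MPA 87.02%  PA 99.14%
```

i.e. pooled over all 24 images, predicted and true lesion pixels overlap by
70.8% of their union (IOU); MIOU averages that with the background class's
IOU; PA is the fraction of all pixels labeled correctly and MPA the mean of
the two per-class accuracies. Published-style indicator tables can also be
recomputed directly from raw diagnostic counts, with no model involved:

```sh
pterynet eval-classify --from-counts 149 1 2 148 --out ec
```

```
indicator                 normal   pterygium
Sensitivity               99.33%      98.67%
Specificity               98.67%      99.33%
F1-score                  99.00%      99.00%
AUC                         0.99
Kappa                     98.00%
Accuracy              99.00%
```

Every subcommand honors `--seed`, accepts a flat YAML `--config` file
(flags take precedence) and writes a resolved-config snapshot plus a
timestamped log next to its outputs.

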