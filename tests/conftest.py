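"""Shared fixtures: synthetic training sets and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from pterynet.classifiers import LabeledImages
from pterynet.nn import interp_matrix
from pterynet.pspnet import SegDataset
from pterynet.synthetic import EyePhantomParams, generate_sample

#: the published diagnostic counts (true x predicted over normal/pterygium)
#: and the published indicator values they must reproduce.
PUBLISHED_COUNTS = {
    "alexnet": (147, 3, 6, 144),
    "vgg16": (149, 1, 2, 148),
    "resnet18": (143, 7, 12, 138),
    "resnet50": (140, 10, 11, 139),
}

PUBLISHED_INDICATORS = {
    # sens/spec/f1 are (normal, pterygium) percents; auc on [0,1]; rest percents
    "alexnet": dict(sens=(98.00, 96.00), spec=(96.00, 98.00), f1=(97.03, 96.97),
                    auc=0.97, kappa=94.00, acc=97.00),
    "vgg16": dict(sens=(99.33, 98.67), spec=(98.67, 99.33), f1=(99.00, 99.00),
                  auc=0.99, kappa=98.00, acc=99.00),
    "resnet18": dict(sens=(95.33, 92.00), spec=(92.00, 95.33), f1=(93.77, 93.56),
                     auc=0.94, kappa=87.33, acc=93.67),
    "resnet50": dict(sens=(93.33, 92.67), spec=(92.67, 93.33), f1=(93.02, 92.98),
                     auc=0.93, kappa=86.00, acc=93.00),
}


def make_labeled_set(n: int, seed: int, size: int = 64) -> LabeledImages:
    """n phantoms, alternating normal/pterygium, as a classifier batch."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for i in range(n):
        positive = i % 2 == 1
        extent = float(rng.uniform(0.15, 0.8)) if positive else 0.0
        side = "nasal-left" if rng.random() < 0.5 else "nasal-right"
        img, _, _ = generate_sample(EyePhantomParams(
            image_size=size, lesion_extent=extent, lesion_side=side,
            seed=int(rng.integers(2**31))))
        xs.append(img.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(int(positive))
    return LabeledImages(np.stack(xs), np.array(ys))


def make_seg_dataset(n: int, seed: int, size: int = 129) -> SegDataset:
    """n pterygium phantoms with paired masks at a square size."""
    rng = np.random.default_rng(seed)
    xs, ms = [], []
    for i in range(n):
        img, mask, _ = generate_sample(EyePhantomParams(
            image_size=size, lesion_extent=float(rng.uniform(0.25, 0.7)),
            lesion_side="nasal-left" if i % 2 else "nasal-right",
            seed=int(rng.integers(2**31))))
        xs.append(img.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0)
        ms.append(mask.pixels)
    return SegDataset(np.stack(xs), np.stack(ms))


def bilinear_resize_oracle(arr: np.ndarray, oh: int, ow: int) -> np.ndarray:
    """Straight-line corner-aligned bilinear resize of an (N,C,H,W) array."""
    rm = interp_matrix(oh, arr.shape[2])
    cm = interp_matrix(ow, arr.shape[3])
    return np.matmul(np.matmul(rm[None, None], arr), cm.T[None, None])


def cascade_oracle(branches: list[np.ndarray], target: int) -> np.ndarray:
    """Independent straight-line implementation of the stage-upsampling cascade."""
    s = branches[0]
    for b, k in zip(branches[1:], (2, 3, 6)):
        s = bilinear_resize_oracle(s, k, k) + b
    return bilinear_resize_oracle(s, target, target)


def pixel_confusion_oracle(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Brute-force pixel-by-pixel counting loop."""
    m = np.zeros((2, 2), dtype=np.int64)
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            m[int(truth[i, j]), int(pred[i, j])] += 1
    return m


def seg_metrics_oracle(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Eq-by-eq counting oracle for IOU/MIOU/PA/MPA on one binary pair."""
    m = pixel_confusion_oracle(pred, truth)
    ious, accs = [], []
    for c in (0, 1):
        inter = m[c, c]
        union = m[c, :].sum() + m[:, c].sum() - inter
        ious.append(1.0 if union == 0 else inter / union)
        accs.append(1.0 if m[c, :].sum() == 0 else inter / m[c, :].sum())
    return dict(iou=ious[1], miou=float(np.mean(ious)),
                pa=float(np.trace(m) / m.sum()), mpa=float(np.mean(accs)))


@pytest.fixture(scope="session")
def tiny_seg_dataset() -> SegDataset:
    return make_seg_dataset(4, seed=77)


@pytest.fixture(scope="session")
def tiny_labeled_set() -> LabeledImages:
    return make_labeled_set(8, seed=55)
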