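"""Image/mask/manifest IO and the two preprocessing pipelines.

Anterior-segment photographs are plain RGB arrays (H x W x 3, uint8); lesion
annotations are binary masks stored as single-channel 0/255 PNG and held in
memory as H x W arrays over {0, 1}.  A manifest is a CSV with columns
``image,label,mask,split`` tying the pieces together.

Two preprocessing routes are provided:

* classification — resize to 336 x 224 (width x height) with an optional
  random rotation in [-3, +3] degrees as augmentation;
* segmentation — letterbox the image to a square with gray (128,128,128)
  bands, the mask with zeros, then resize the square to 473 x 473 (bilinear
  for the image, nearest-neighbor for the mask so it stays binary).

Geometric conventions (fixed so tests can be exact): arrays are row-major
with the origin at the top-left; sizes quoted as "336 x 224" follow the
width x height convention of the imaging literature but are stored H x W.
Bilinear resampling is corner-aligned.  When a padding band has odd length
the extra pixel goes to the bottom/right.  Rotation by a positive angle moves
content counterclockwise (screen view, row 0 on top) about the pixel-center
of the array; out-of-frame samples are filled with 0 in both image and mask.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from . import nn

NORMAL = "normal"
PTERYGIUM = "pterygium"
LABELS = (NORMAL, PTERYGIUM)

CLASSIFY_HW = (224, 336)   # H x W — i.e. 336 x 224 in width x height terms
SEGMENT_SIZE = 473
PAD_GRAY = 128
ROTATE_DEGREES = (-3.0, 3.0)
VAL_FRACTION = 0.1


class InvalidInputError(ValueError):
    """Raised when an image, mask or parameter violates a precondition."""


class DimensionMismatchError(ValueError):
    """Raised when an image and its mask disagree on spatial dimensions."""


class NotAnImageError(ValueError):
    """Raised when a file cannot be decoded as an image."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnteriorSegmentImage:
    """An RGB anterior-segment photograph with provenance."""

    pixels: np.ndarray  # H x W x 3 uint8
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(f"image must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidInputError("image must have positive height and width")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidInputError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class SegMask:
    """Binary per-pixel lesion annotation aligned to its image."""

    pixels: np.ndarray  # H x W in {0, 1}

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidInputError(f"mask must be HxW, got shape {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise InvalidInputError("mask values must be strictly binary {0, 1}")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class ManifestRecord:
    image: str
    label: str
    mask: str | None = None
    split: str | None = None


@dataclasses.dataclass
class Manifest:
    records: list[ManifestRecord]
    root: Path = Path(".")

    def subset(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]


# ---------------------------------------------------------------------------
# geometric transforms
# ---------------------------------------------------------------------------

def _pad_amounts(short: int, long: int) -> tuple[int, int]:
    total = long - short
    before = total // 2
    return before, total - before  # extra pixel to the bottom/right


def pad_to_square(image: AnteriorSegmentImage, fill_value: int = PAD_GRAY) -> AnteriorSegmentImage:
    """Letterbox to S x S, S = max(H, W), centered, gray fill by default."""
    if not 0 <= fill_value <= 255:
        raise InvalidInputError(f"fill_value {fill_value} outside [0, 255]")
    h, w = image.height, image.width
    s = max(h, w)
    top, bottom = _pad_amounts(h, s)
    left, right = _pad_amounts(w, s)
    out = np.pad(image.pixels, ((top, bottom), (left, right), (0, 0)),
                 constant_values=fill_value)
    return AnteriorSegmentImage(out, source_id=image.source_id)


def pad_mask_to_square(mask: SegMask) -> SegMask:
    h, w = mask.height, mask.width
    s = max(h, w)
    top, bottom = _pad_amounts(h, s)
    left, right = _pad_amounts(w, s)
    return SegMask(np.pad(mask.pixels, ((top, bottom), (left, right)), constant_values=0))


def crop_from_square(image: AnteriorSegmentImage, orig_h: int, orig_w: int) -> AnteriorSegmentImage:
    """Inverse of :func:`pad_to_square` — recover the original content."""
    top, _ = _pad_amounts(orig_h, image.height)
    left, _ = _pad_amounts(orig_w, image.width)
    return AnteriorSegmentImage(image.pixels[top:top + orig_h, left:left + orig_w],
                                source_id=image.source_id)


def resize_bilinear(image: AnteriorSegmentImage, target_h: int, target_w: int) -> AnteriorSegmentImage:
    """Corner-aligned bilinear resize (up or down, no antialias filter)."""
    if target_h < 1 or target_w < 1:
        raise InvalidInputError("target dimensions must be >= 1")
    if (target_h, target_w) == (image.height, image.width):
        return AnteriorSegmentImage(image.pixels.copy(), source_id=image.source_id)
    rm = nn.interp_matrix(target_h, image.height).astype(np.float64)
    cm = nn.interp_matrix(target_w, image.width).astype(np.float64)
    px = image.pixels.astype(np.float64)
    out = np.einsum("ij,jkc,lk->ilc", rm, px, cm, optimize=True)
    return AnteriorSegmentImage(np.clip(np.rint(out), 0, 255).astype(np.uint8),
                                source_id=image.source_id)


def resize_mask_nearest(mask: SegMask, target_h: int, target_w: int) -> SegMask:
    """Nearest-neighbor resize (corner-aligned source grid) — stays binary."""
    if target_h < 1 or target_w < 1:
        raise InvalidInputError("target dimensions must be >= 1")
    h, w = mask.height, mask.width
    ri = np.rint(np.arange(target_h) * ((h - 1) / (target_h - 1) if target_h > 1 else 0)).astype(int)
    ci = np.rint(np.arange(target_w) * ((w - 1) / (target_w - 1) if target_w > 1 else 0)).astype(int)
    return SegMask(mask.pixels[np.ix_(ri, ci)])


def _rotate_channels(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate an H x W (x C) float array about its pixel-center.

    Positive angle = counterclockwise on screen.  ``order`` 1 = bilinear,
    0 = nearest.  Out-of-frame samples are 0.
    """
    h, w = arr.shape[:2]
    theta = math.radians(angle_deg)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dy, dx = rr - cy, cc - cx
    # inverse map: sample source at R(+theta) applied to output offsets
    # (content moves by R(-theta) in array coords, which is CCW on screen)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    sx = cos_t * dx - sin_t * dy + cx
    sy = sin_t * dx + cos_t * dy + cy
    if order == 0:
        si = np.rint(sy).astype(int)
        sj = np.rint(sx).astype(int)
        valid = (si >= 0) & (si < h) & (sj >= 0) & (sj < w)
        out = np.zeros_like(arr)
        out[valid] = arr[si[valid], sj[valid]]
        return out
    y0 = np.floor(sy).astype(int)
    x0 = np.floor(sx).astype(int)
    fy, fx = sy - y0, sx - x0
    out = np.zeros(arr.shape, dtype=np.float64)
    for oy, ox, wgt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                        (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yi, xi = y0 + oy, x0 + ox
        valid = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
        contrib = np.zeros(arr.shape[:2] + arr.shape[2:], dtype=np.float64)
        contrib[valid] = arr[yi[valid], xi[valid]]
        wv = np.where(valid, wgt, 0.0)
        out += contrib * (wv[..., None] if arr.ndim == 3 else wv)
    return out


def random_rotate(image: AnteriorSegmentImage, mask: SegMask | None,
                  degrees_range: tuple[float, float] = ROTATE_DEGREES,
                  seed: int = 0) -> tuple[AnteriorSegmentImage, SegMask | None]:
    """Jointly rotate image (bilinear) and mask (nearest) by one random angle."""
    lo, hi = degrees_range
    if lo > hi:
        raise InvalidInputError(f"degrees_range min {lo} > max {hi}")
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(lo, hi))
    return rotate_pair(image, mask, angle)


def rotate_pair(image: AnteriorSegmentImage, mask: SegMask | None,
                angle_deg: float) -> tuple[AnteriorSegmentImage, SegMask | None]:
    if angle_deg == 0.0:
        return (AnteriorSegmentImage(image.pixels.copy(), source_id=image.source_id),
                SegMask(mask.pixels.copy()) if mask is not None else None)
    img = _rotate_channels(image.pixels.astype(np.float64), angle_deg, order=1)
    out_img = AnteriorSegmentImage(np.clip(np.rint(img), 0, 255).astype(np.uint8),
                                   source_id=image.source_id)
    out_mask = None
    if mask is not None:
        if (mask.height, mask.width) != (image.height, image.width):
            raise DimensionMismatchError("mask does not match image dimensions")
        out_mask = SegMask(_rotate_channels(mask.pixels.astype(np.float64),
                                            angle_deg, order=0).astype(np.uint8))
    return out_img, out_mask


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def prepare_for_classification(image: AnteriorSegmentImage,
                               target_hw: tuple[int, int] = CLASSIFY_HW) -> AnteriorSegmentImage:
    return resize_bilinear(image, *target_hw)


def prepare_for_segmentation(image: AnteriorSegmentImage, mask: SegMask | None = None,
                             size: int = SEGMENT_SIZE) -> tuple[AnteriorSegmentImage, SegMask | None]:
    """Square-pad with gray (mask: zeros) then resize to ``size`` x ``size``."""
    if mask is not None and (mask.height, mask.width) != (image.height, image.width):
        raise DimensionMismatchError("mask does not match image dimensions")
    sq = pad_to_square(image, PAD_GRAY)
    out_img = resize_bilinear(sq, size, size)
    out_mask = None
    if mask is not None:
        out_mask = resize_mask_nearest(pad_mask_to_square(mask), size, size)
    return out_img, out_mask


def to_network_input(image: AnteriorSegmentImage, normalize: bool = False) -> np.ndarray:
    """HxWx3 uint8 -> 1x3xHxW float32 in [0,1] (optionally ImageNet-normalized)."""
    x = image.pixels.astype(np.float32) / 255.0
    if normalize:
        mean = np.array([0.485, 0.456, 0.406], np.float32)
        std = np.array([0.229, 0.224, 0.225], np.float32)
        x = (x - mean) / std
    return x.transpose(2, 0, 1)[None]


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> AnteriorSegmentImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except UnidentifiedImageError as e:
        raise NotAnImageError(f"not a decodable image: {path}") from e
    return AnteriorSegmentImage(arr, source_id=path.stem)


def save_image(image: AnteriorSegmentImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def load_mask(path: str | Path) -> SegMask:
    """Load a single-channel PNG; values threshold at 128 to {0, 1}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except UnidentifiedImageError as e:
        raise NotAnImageError(f"not a decodable image: {path}") from e
    return SegMask((arr >= 128).astype(np.uint8))


def save_mask(mask: SegMask, path: str | Path) -> None:
    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(path)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in manifest.records]
    pd.DataFrame(rows, columns=["image", "label", "mask", "split"]).to_csv(path, index=False)


def load_manifest(path: str | Path, validate: bool = True) -> Manifest:
    """Read a manifest CSV; optionally check masks resolve and match dims."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    root = path.parent
    records = []
    for row in df.itertuples(index=False):
        label = str(row.label)
        if label not in LABELS:
            raise InvalidInputError(f"unknown label {label!r} for {row.image}")
        mask = None if pd.isna(getattr(row, "mask", None)) else str(row.mask)
        split = None if pd.isna(getattr(row, "split", None)) else str(row.split)
        records.append(ManifestRecord(str(row.image), label, mask, split))
    manifest = Manifest(records, root=root)
    if validate:
        for rec in manifest.records:
            if rec.mask is None:
                continue
            img = load_image(root / rec.image)
            msk = load_mask(root / rec.mask)
            if (img.height, img.width) != (msk.height, msk.width):
                raise DimensionMismatchError(
                    f"record {rec.image}: image {img.height}x{img.width} vs "
                    f"mask {msk.height}x{msk.width}")
    return manifest


def split_train_val(records: Sequence[ManifestRecord], seed: int,
                    val_fraction: float = VAL_FRACTION) -> list[ManifestRecord]:
    """Assign a 9:1 train/validation split (random, seeded, unstratified)."""
    n = len(records)
    n_val = int(round(n * val_fraction))
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    out = []
    for i, rec in enumerate(records):
        out.append(dataclasses.replace(rec, split="val" if i in val_idx else "train"))
    return out
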