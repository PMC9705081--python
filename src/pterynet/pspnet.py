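"""PSPNet lesion segmenters and the phase-fusion variants.

Four variants share one skeleton — backbone trunk, pyramid pooling, output
convolution, upsample to input resolution, per-pixel softmax:

* ``pspnet_mobilenet`` — plain PSPNet on an inverted-residual MobileNet trunk;
* ``pspnet_resnet50``  — plain PSPNet on a ResNet50-style trunk;
* ``phase_fusion``     — ResNet50 trunk whose pyramid pooling module (PPM)
  is extended to PPM+: a fifth branch built by the *stage upsampling module*,
  the cascade that bilinearly enlarges the 1x1 pooled branch to 2x2, adds the
  2x2 branch element-wise, enlarges to 3x3, adds, enlarges to 6x6, adds, and
  finally enlarges the sum to the working grid;
* ``double_phase_fusion`` — phase_fusion plus a second, independently
  weighted PPM+ head on the shallow backbone features (the tensor entering
  the third residual stage, at 1/8 scale); the shallow head's class maps are
  bilinearly resized to the deep grid and added element-wise before the final
  upsample.

Both trunks run at output stride 16, so a 473 x 473 input yields the 30 x 30
working grid (ceil(473/16) = 30).  The canonical dilated stride-8 PSPNet
trunk is deliberately not used — it would put the working grid at 60 x 60.
Pyramid branches are average-pooled at 1x1, 2x2, 3x3 and 6x6 and reduced to
``C_r = C/4`` channels by a 1x1 conv + BN + ReLU, the PSPNet convention.
All interpolation is corner-aligned bilinear.

Training: per-pixel cross-entropy over {background, lesion}, SGD with
momentum, 80 epochs by default, checkpoint selection by best validation MIOU.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .classifiers import Bottleneck, ConfigurationError, ResNetTrunk, _c
from .metrics import SegMetricReport, seg_metrics_dataset
from .preprocess_io import AnteriorSegmentImage, InvalidInputError, SegMask

VARIANTS = ("pspnet_mobilenet", "pspnet_resnet50", "phase_fusion", "double_phase_fusion")
POOL_SCALES = (1, 2, 3, 6)
OUTPUT_STRIDE = 16
MIN_INPUT_SIZE = 113   # smallest square whose /16 working grid still fits 6x6 pooling


@dataclasses.dataclass
class SegModelConfig:
    variant: str = "phase_fusion"
    input_size: int = 473
    n_classes: int = 2
    width_scale: float = 1.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}; "
                                     f"expected one of {VARIANTS}")
        if self.input_size < MIN_INPUT_SIZE:
            raise ConfigurationError(
                f"input_size must be >= {MIN_INPUT_SIZE} so the working grid "
                f"supports 6x6 pyramid pooling; got {self.input_size}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not 0.0 < self.width_scale <= 1.0:
            raise ConfigurationError("width_scale must lie in (0, 1]")

    @property
    def feature_grid(self) -> int:
        """Working-grid side length at the configured input size."""
        return math.ceil(self.input_size / OUTPUT_STRIDE)


@dataclasses.dataclass
class SegSchedule:
    learning_rate: float = 0.01
    epochs: int = 80
    seed: int = 0
    batch_size: int = 2
    momentum: float = 0.9
    val_every: int = 1    # validate (and consider checkpointing) every n epochs

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1 or self.val_every < 1:
            raise ConfigurationError("epochs and val_every must be >= 1")


@dataclasses.dataclass
class SegEpochRecord:
    epoch: int
    train_loss: float
    val_miou: float | None


class SegHistory(list):
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def best_val_miou(self) -> float:
        return max(r.val_miou for r in self if r.val_miou is not None)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class InvertedResidual(nn.Module):
    """MobileNetV2-style block: expand 1x1 -> depthwise 3x3 -> project 1x1."""

    def __init__(self, cin: int, cout: int, stride: int, expand: int, rng):
        super().__init__()
        mid = cin * expand
        self.use_res = stride == 1 and cin == cout
        layers: list[nn.Module] = []
        if expand != 1:
            layers += [nn.Conv2d(cin, mid, 1, rng, bias=False),
                       nn.BatchNorm2d(mid), nn.ReLU()]
        layers += [nn.DepthwiseConv2d(mid, 3, rng, stride=stride, padding=1),
                   nn.BatchNorm2d(mid), nn.ReLU(),
                   nn.Conv2d(mid, cout, 1, rng, bias=False), nn.BatchNorm2d(cout)]
        self.block = nn.Sequential(*layers)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = self.block(x)
        return nn.add(out, x) if self.use_res else out


class MobileNetTrunk(nn.Module):
    """Inverted-residual trunk at output stride 16."""

    # (expand, channels, repeats, first-stride)
    _CFG = ((1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 3, 2), (6, 96, 2, 1))

    def __init__(self, ws: float, rng):
        super().__init__()
        c32 = _c(32, ws)
        self.stem = nn.Sequential(
            nn.Conv2d(3, c32, 3, rng, stride=2, padding=1, bias=False),
            nn.BatchNorm2d(c32), nn.ReLU())
        blocks: list[nn.Module] = []
        cin = c32
        for expand, ch, reps, stride in self._CFG:
            cout = _c(ch, ws)
            for r in range(reps):
                blocks.append(InvertedResidual(cin, cout, stride if r == 0 else 1,
                                               expand, rng))
                cin = cout
        self.blocks = nn.Sequential(*blocks)
        self.out_channels = cin

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.blocks(self.stem(x))


# ---------------------------------------------------------------------------
# pyramid pooling
# ---------------------------------------------------------------------------

class PyramidPooling(nn.Module):
    """The four pooled-and-reduced branches at grids 1, 2, 3 and 6."""

    def __init__(self, cin: int, rng):
        super().__init__()
        self.reduced_channels = max(1, cin // 4)
        self.reducers = [nn.Sequential(nn.Conv2d(cin, self.reduced_channels, 1, rng,
                                                 bias=False),
                                       nn.BatchNorm2d(self.reduced_channels), nn.ReLU())
                         for _ in POOL_SCALES]

    def pool_branches(self, feature_map: nn.Tensor) -> list[nn.Tensor]:
        h, w = feature_map.data.shape[2:]
        if h < max(POOL_SCALES) or w < max(POOL_SCALES):
            raise InvalidInputError(
                f"feature map {h}x{w} too small for {max(POOL_SCALES)}x"
                f"{max(POOL_SCALES)} pyramid pooling")
        return [reducer(nn.adaptive_avg_pool2d(feature_map, (k, k)))
                for k, reducer in zip(POOL_SCALES, self.reducers)]


def pool_branches_raw(feature_map: nn.Tensor) -> list[nn.Tensor]:
    """Pre-convolution pooled maps (the 1x1 one is the global mean)."""
    return [nn.adaptive_avg_pool2d(feature_map, (k, k)) for k in POOL_SCALES]


def stage_upsample_fuse(branches: list[nn.Tensor], target_grid: int) -> nn.Tensor:
    """The stage upsampling module: cascade-add 1->2->3->6, then to the grid.

    ``u1 = bilinear(b1 -> 2x2); s2 = u1 + b2; s3 = bilinear(s2 -> 3x3) + b3;
    s4 = bilinear(s3 -> 6x6) + b4; out = bilinear(s4 -> target_grid)``.
    """
    if len(branches) != len(POOL_SCALES):
        raise ConfigurationError(f"expected {len(POOL_SCALES)} branches, got {len(branches)}")
    channels = {b.data.shape[1] for b in branches}
    if len(channels) != 1:
        raise ConfigurationError(f"branch channel counts differ: {sorted(channels)}")
    for b, k in zip(branches, POOL_SCALES):
        if b.data.shape[2:] != (k, k):
            raise ConfigurationError(
                f"branch grids must be {POOL_SCALES}, got {b.data.shape[2:]} for {k}")
    s = branches[0]
    for b, k in zip(branches[1:], POOL_SCALES[1:]):
        s = nn.add(nn.upsample_bilinear(s, (k, k)), b)
    return nn.upsample_bilinear(s, (target_grid, target_grid))


class SegHead(nn.Module):
    """Output convolution block: 3x3 conv + BN + ReLU, then 1x1 to classes."""

    def __init__(self, cin: int, cmid: int, n_classes: int, rng):
        super().__init__()
        self.conv = nn.Sequential(nn.Conv2d(cin, cmid, 3, rng, padding=1, bias=False),
                                  nn.BatchNorm2d(cmid), nn.ReLU())
        self.classify = nn.Conv2d(cmid, n_classes, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.classify(self.conv(x))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class PSPNetModel(nn.Module):
    def __init__(self, config: SegModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ws = config.width_scale
        if config.variant == "pspnet_mobilenet":
            self.backbone = MobileNetTrunk(ws, rng)
        else:
            # ResNet50-style trunk, last stage at stride 1 => output stride 16
            self.backbone = ResNetTrunk(Bottleneck, (3, 4, 6, 3), ws, rng,
                                        strides=(1, 2, 2, 1))
        cin = self.backbone.out_channels
        self.ppm = PyramidPooling(cin, rng)
        cr = self.ppm.reduced_channels
        n_branches = 5 if self.has_fused_branch else 4
        self.head = SegHead(cin + n_branches * cr, cr, config.n_classes, rng)
        if config.variant == "double_phase_fusion":
            sc = self.backbone.stage2_out_channels
            self.shallow_ppm = PyramidPooling(sc, rng)
            scr = self.shallow_ppm.reduced_channels
            self.shallow_head = SegHead(sc + 5 * scr, scr, config.n_classes, rng)

    @property
    def has_fused_branch(self) -> bool:
        return self.config.variant in ("phase_fusion", "double_phase_fusion")

    # -- features ----------------------------------------------------------

    def extract_features(self, x: nn.Tensor):
        """Deep feature map (and the shallow one for the double variant)."""
        n, c, h, w = x.data.shape
        if h != w:
            raise InvalidInputError(f"input must be square, got {h}x{w}")
        if h < MIN_INPUT_SIZE:
            raise InvalidInputError(f"input below minimum {MIN_INPUT_SIZE}px")
        if self.config.variant == "double_phase_fusion":
            return self.backbone.forward_with_shallow(x)
        return self.backbone(x)

    def _ppm_plus_logits(self, feature_map: nn.Tensor, ppm: PyramidPooling,
                         head: SegHead, fused_on: bool, zero_fused: bool) -> nn.Tensor:
        grid = feature_map.data.shape[2]
        branches = ppm.pool_branches(feature_map)
        parts = [feature_map] + [nn.upsample_bilinear(b, (grid, grid)) for b in branches]
        if fused_on:
            fused = stage_upsample_fuse(branches, grid)
            if zero_fused:
                fused = nn.mul_scalar(fused, 0.0)
            parts.append(fused)
        return head(nn.concat(parts, axis=1))

    def logits(self, x: nn.Tensor, zero_fused: bool = False) -> nn.Tensor:
        h, w = x.data.shape[2:]
        feats = self.extract_features(x)
        if self.config.variant == "double_phase_fusion":
            deep, shallow = feats
            grid = deep.data.shape[2]
            deep_logits = self._ppm_plus_logits(deep, self.ppm, self.head,
                                                True, zero_fused)
            shallow_logits = self._ppm_plus_logits(shallow, self.shallow_ppm,
                                                   self.shallow_head, True, zero_fused)
            fused_logits = nn.add(deep_logits,
                                  nn.upsample_bilinear(shallow_logits, (grid, grid)))
            return nn.upsample_bilinear(fused_logits, (h, w))
        grid_logits = self._ppm_plus_logits(feats, self.ppm, self.head,
                                            self.has_fused_branch, zero_fused)
        return nn.upsample_bilinear(grid_logits, (h, w))

    def deep_branch_logits(self, x: nn.Tensor) -> nn.Tensor:
        """Double variant's deep path alone, upsampled — the ablation reference."""
        if self.config.variant != "double_phase_fusion":
            raise ConfigurationError("deep_branch_logits applies to the double variant")
        h, w = x.data.shape[2:]
        deep, _ = self.extract_features(x)
        return nn.upsample_bilinear(
            self._ppm_plus_logits(deep, self.ppm, self.head, True, False), (h, w))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return nn.softmax(self.logits(x), axis=1)


def build_segmenter(config: SegModelConfig, seed: int = 0) -> PSPNetModel:
    return PSPNetModel(config, seed=seed)


# ---------------------------------------------------------------------------
# operation-level convenience wrappers
# ---------------------------------------------------------------------------

def extract_features(model: PSPNetModel, image: nn.Tensor | np.ndarray):
    x = image if isinstance(image, nn.Tensor) else nn.Tensor(image)
    with nn.no_grad():
        return model.extract_features(x)


def pyramid_pool(model: PSPNetModel, feature_map: nn.Tensor) -> list[nn.Tensor]:
    return model.ppm.pool_branches(feature_map)


def forward_segment(model: PSPNetModel, image: nn.Tensor | np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (N, n_classes, H, W) at input resolution."""
    x = image if isinstance(image, nn.Tensor) else nn.Tensor(image)
    model.eval()
    with nn.no_grad():
        return model(x).data


def predict_mask(model: PSPNetModel, image: nn.Tensor | np.ndarray) -> SegMask:
    probs = forward_segment(model, image)
    return SegMask((probs[0].argmax(axis=0) == 1).astype(np.uint8))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SegDataset:
    """Images (N,3,S,S) float32 in [0,1] with integer masks (N,S,S)."""

    x: np.ndarray
    masks: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.masks = np.asarray(self.masks)
        if self.x.ndim != 4 or self.x.shape[1] != 3:
            raise InvalidInputError(f"expected (N,3,S,S) images, got {self.x.shape}")
        if self.masks.shape != (self.x.shape[0],) + self.x.shape[2:]:
            raise InvalidInputError("each record needs a mask matching its image")
        if not np.isin(self.masks, (0, 1)).all():
            raise InvalidInputError("masks must be binary")
        self.masks = self.masks.astype(np.int64)

    def __len__(self) -> int:
        return len(self.x)


def evaluate_miou(model: PSPNetModel, data: SegDataset) -> SegMetricReport:
    pairs = ((predict_mask(model, data.x[i:i + 1]), SegMask(data.masks[i].astype(np.uint8)))
             for i in range(len(data)))
    return seg_metrics_dataset(pairs)


def train_segmenter(model: PSPNetModel, train_set: SegDataset, val_set: SegDataset,
                    schedule: SegSchedule) -> tuple[PSPNetModel, SegHistory]:
    """Per-pixel CE + SGD; returns the best-validation-MIOU checkpoint."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ConfigurationError("train and validation sets must be non-empty")
    rng = np.random.default_rng(schedule.seed)
    opt = nn.SGD(model.parameters(), lr=schedule.learning_rate,
                 momentum=schedule.momentum)
    history = SegHistory()
    best_state, best_miou = None, -1.0
    n = len(train_set)
    for epoch in range(1, schedule.epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, schedule.batch_size):
            idx = order[i:i + schedule.batch_size]
            loss = nn.pixel_cross_entropy(model.logits(nn.Tensor(train_set.x[idx])),
                                          train_set.masks[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_miou = None
        if epoch % schedule.val_every == 0 or epoch == schedule.epochs:
            val_miou = evaluate_miou(model, val_set).miou
            if val_miou > best_miou:
                best_miou, best_state = val_miou, model.state_dict()
        history.append(SegEpochRecord(epoch, float(np.mean(losses)), val_miou))
    model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# checkpoints / prediction export
# ---------------------------------------------------------------------------

def save_checkpoint(model: PSPNetModel, path: str | Path) -> None:
    np.savez(path, __config__=json.dumps(dataclasses.asdict(model.config)),
             **dict(model.named_state()))


def load_checkpoint(path: str | Path, seed: int = 0) -> PSPNetModel:
    with np.load(path, allow_pickle=False) as z:
        config = SegModelConfig(**json.loads(str(z["__config__"])))
        model = PSPNetModel(config, seed=seed)
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    model.eval()
    return model
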