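"""Two-category screening networks (AlexNet / VGG16 / ResNet18 / ResNet50).

Each classical trunk is rebuilt with one modification: an adaptive average
pooling stage between the convolutional trunk and the first fully connected
layer, so the flattened feature size no longer depends on the input size and
the networks accept the native 336 x 224 (width x height) anterior-segment
frame instead of the canonical 224 x 224 crop.  The pooling grid per
architecture equals the grid the original fully connected layer expects
(6x6 AlexNet, 7x7 VGG16, 1x1 ResNets), so canonical-weight checkpoints stay
loadable at ``width_scale`` 1.

``width_scale`` shrinks every channel/feature width proportionally; it exists
so CPU-scale tests and demos train in seconds, and ``width_scale=1.0``
reproduces the canonical architectures.

Training follows the published recipe: cross-entropy loss, SGD (momentum
0.9), learning rate 0.001 for 30 epochs (AlexNet, VGG16) or 0.01 for 100
epochs (ResNet18, ResNet50), random +/-3 degree rotation augmentation, and
the checkpoint with the best validation accuracy — not the last epoch — is
returned.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .preprocess_io import (
    LABELS, NORMAL, AnteriorSegmentImage, InvalidInputError, rotate_pair,
)

ARCHITECTURES = ("alexnet", "vgg16", "resnet18", "resnet50")

#: smallest H or W that survives each trunk's downsampling chain
MIN_INPUT = {"alexnet": 63, "vgg16": 32, "resnet18": 32, "resnet50": 32}

#: adaptive-pooling grid matching the original first FC layer
POOL_GRID = {"alexnet": (6, 6), "vgg16": (7, 7), "resnet18": (1, 1), "resnet50": (1, 1)}

#: published learning rate / epoch count per architecture
PAPER_SCHEDULE = {"alexnet": (0.001, 30), "vgg16": (0.001, 30),
                  "resnet18": (0.01, 100), "resnet50": (0.01, 100)}


class ConfigurationError(ValueError):
    """Raised for invalid model/training configurations."""


@dataclasses.dataclass
class ClassifierConfig:
    architecture: str = "vgg16"
    input_h: int = 224
    input_w: int = 336
    n_classes: int = 2
    width_scale: float = 1.0
    pretrained_init: bool = False
    weights_path: str | None = None   # local checkpoint for pretrained_init
    normalize: bool = False           # ImageNet channel statistics toggle

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}; "
                                     f"expected one of {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if not 0.0 < self.width_scale <= 1.0:
            raise ConfigurationError("width_scale must lie in (0, 1]")
        m = MIN_INPUT[self.architecture]
        if self.input_h < m or self.input_w < m:
            raise ConfigurationError(
                f"{self.architecture} needs input dims >= {m}, got "
                f"{self.input_h}x{self.input_w}")


@dataclasses.dataclass
class TrainSchedule:
    learning_rate: float
    epochs: int
    seed: int = 0
    batch_size: int = 8
    momentum: float = 0.9
    loss: str = "cross_entropy"
    augment_rotate: tuple[float, float] | None = (-3.0, 3.0)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.loss != "cross_entropy":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")


def default_schedule(architecture: str, seed: int = 0, **overrides) -> TrainSchedule:
    """The published learning-rate/epoch pairing for an architecture."""
    lr, epochs = PAPER_SCHEDULE[architecture]
    kw = dict(learning_rate=lr, epochs=epochs, seed=seed)
    kw.update(overrides)
    return TrainSchedule(**kw)


@dataclasses.dataclass
class LabeledImages:
    """An in-memory labeled batch: X is (N,3,H,W) float32 in [0,1], y int."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64).reshape(-1)
        if self.x.ndim != 4 or self.x.shape[1] != 3:
            raise InvalidInputError(f"expected (N,3,H,W) inputs, got {self.x.shape}")
        if len(self.x) != len(self.y):
            raise InvalidInputError("image/label count mismatch")

    def __len__(self) -> int:
        return len(self.y)


@dataclasses.dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float


class History(list):
    """Per-epoch training log (list of :class:`EpochRecord`)."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def best_val_accuracy(self) -> float:
        return max(r.val_accuracy for r in self)


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

def _c(base: int, ws: float) -> int:
    return max(1, int(round(base * ws)))


class ClassifierModel(nn.Module):
    """Trunk + adaptive average pooling + fully connected head."""

    def __init__(self, config: ClassifierConfig, trunk: nn.Module,
                 head: nn.Module, pool_grid: tuple[int, int]):
        super().__init__()
        self.config = config
        self.trunk = trunk
        self.pool = nn.AdaptiveAvgPool2d(pool_grid)
        self.head = head

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        m = MIN_INPUT[self.config.architecture]
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise InvalidInputError(f"expected (N,3,H,W) input, got {x.data.shape}")
        if x.data.shape[2] < m or x.data.shape[3] < m:
            raise InvalidInputError(
                f"{self.config.architecture} needs input >= {m}px per side")
        f = self.trunk(x)
        return self.head(nn.flatten(self.pool(f)))


def _alexnet(cfg: ClassifierConfig, rng) -> ClassifierModel:
    ws = cfg.width_scale
    c64, c192, c384, c256 = _c(64, ws), _c(192, ws), _c(384, ws), _c(256, ws)
    fc = _c(4096, ws)
    trunk = nn.Sequential(
        nn.Conv2d(3, c64, 11, rng, stride=4, padding=2), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(c64, c192, 5, rng, padding=2), nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(c192, c384, 3, rng, padding=1), nn.ReLU(),
        nn.Conv2d(c384, c256, 3, rng, padding=1), nn.ReLU(),
        nn.Conv2d(c256, c256, 3, rng, padding=1), nn.ReLU(),
        nn.MaxPool2d(3, 2),
    )
    head = nn.Sequential(
        nn.Dropout(0.5, rng), nn.Linear(c256 * 36, fc, rng), nn.ReLU(),
        nn.Dropout(0.5, rng), nn.Linear(fc, fc, rng), nn.ReLU(),
        nn.Linear(fc, cfg.n_classes, rng),
    )
    return ClassifierModel(cfg, trunk, head, POOL_GRID["alexnet"])


_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")


def _vgg16(cfg: ClassifierConfig, rng) -> ClassifierModel:
    ws = cfg.width_scale
    layers: list[nn.Module] = []
    cin = 3
    for item in _VGG16_CFG:
        if item == "M":
            layers.append(nn.MaxPool2d(2, 2))
        else:
            cout = _c(int(item), ws)
            layers += [nn.Conv2d(cin, cout, 3, rng, padding=1), nn.ReLU()]
            cin = cout
    fc = _c(4096, ws)
    head = nn.Sequential(
        nn.Linear(cin * 49, fc, rng), nn.ReLU(), nn.Dropout(0.5, rng),
        nn.Linear(fc, fc, rng), nn.ReLU(), nn.Dropout(0.5, rng),
        nn.Linear(fc, cfg.n_classes, rng),
    )
    return ClassifierModel(cfg, nn.Sequential(*layers), head, POOL_GRID["vgg16"])


class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, cin: int, cout: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(
                nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(cout))
        else:
            self.down = nn.Identity()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return nn.relu(nn.add(out, self.down(x)))


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin: int, cmid: int, stride: int, rng):
        super().__init__()
        cout = cmid * self.expansion
        self.conv1 = nn.Conv2d(cin, cmid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(cmid)
        self.conv2 = nn.Conv2d(cmid, cmid, 3, rng, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(cmid)
        self.conv3 = nn.Conv2d(cmid, cout, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(
                nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False),
                nn.BatchNorm2d(cout))
        else:
            self.down = nn.Identity()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        out = nn.relu(self.bn1(self.conv1(x)))
        out = nn.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return nn.relu(nn.add(out, self.down(x)))


def _resnet_stage(block, cin: int, cmid: int, n_blocks: int, stride: int, rng):
    layers = [block(cin, cmid, stride, rng)]
    cout = cmid * block.expansion
    for _ in range(n_blocks - 1):
        layers.append(block(cout, cmid, 1, rng))
    return nn.Sequential(*layers), cout


class ResNetTrunk(nn.Module):
    """Stem + four residual stages; ``strides`` controls the output stride."""

    def __init__(self, block, blocks_per_stage, ws: float, rng,
                 strides=(1, 2, 2, 2)):
        super().__init__()
        c64 = _c(64, ws)
        self.stem = nn.Sequential(
            nn.Conv2d(3, c64, 7, rng, stride=2, padding=3, bias=False),
            nn.BatchNorm2d(c64), nn.ReLU(), nn.MaxPool2d(3, 2, padding=1))
        widths = [_c(w, ws) for w in (64, 128, 256, 512)]
        cin = c64
        stages = []
        for width, n, s in zip(widths, blocks_per_stage, strides):
            stage, cin = _resnet_stage(block, cin, width, n, s, rng)
            stages.append(stage)
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.out_channels = cin
        self.stage2_out_channels = widths[1] * block.expansion

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.stem(x)
        x = self.stage1(x)
        x = self.stage2(x)
        x = self.stage3(x)
        return self.stage4(x)

    def forward_with_shallow(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Deep feature map plus the tensor entering the third stage."""
        x = self.stem(x)
        x = self.stage1(x)
        shallow = self.stage2(x)
        deep = self.stage4(self.stage3(shallow))
        return deep, shallow


def _resnet(cfg: ClassifierConfig, rng, block, blocks_per_stage) -> ClassifierModel:
    trunk = ResNetTrunk(block, blocks_per_stage, cfg.width_scale, rng)
    head = nn.Linear(trunk.out_channels, cfg.n_classes, rng)
    return ClassifierModel(cfg, trunk, head, POOL_GRID[cfg.architecture])


def build_classifier(config: ClassifierConfig, seed: int = 0) -> ClassifierModel:
    """Construct a screening network per ``config`` with seeded random init."""
    rng = np.random.default_rng(seed)
    if config.architecture == "alexnet":
        model = _alexnet(config, rng)
    elif config.architecture == "vgg16":
        model = _vgg16(config, rng)
    elif config.architecture == "resnet18":
        model = _resnet(config, rng, BasicBlock, (2, 2, 2, 2))
    else:
        model = _resnet(config, rng, Bottleneck, (3, 4, 6, 3))
    if config.pretrained_init:
        if not config.weights_path or not Path(config.weights_path).exists():
            raise ConfigurationError(
                "pretrained_init requires weights_path pointing at a local "
                "checkpoint (no weights are bundled with this package)")
        load_checkpoint_into(model, config.weights_path)
    return model


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def _forward_batches(model: ClassifierModel, x: np.ndarray, batch: int = 16) -> np.ndarray:
    logits = []
    with nn.no_grad():
        for i in range(0, len(x), batch):
            logits.append(model(nn.Tensor(x[i:i + batch])).data)
    return np.concatenate(logits, axis=0)


def evaluate_accuracy(model: ClassifierModel, data: LabeledImages) -> float:
    model.eval()
    logits = _forward_batches(model, data.x)
    pred = _argmax_tie_low(logits)
    return float((pred == data.y).mean())


def _argmax_tie_low(logits: np.ndarray) -> np.ndarray:
    # np.argmax already breaks ties toward the lowest index ("normal" = 0)
    return logits.argmax(axis=1)


def _augment_batch(x: np.ndarray, degrees: tuple[float, float], rng) -> np.ndarray:
    out = np.empty_like(x)
    for i in range(len(x)):
        angle = float(rng.uniform(*degrees))
        img = AnteriorSegmentImage(
            np.clip(np.rint(x[i].transpose(1, 2, 0) * 255), 0, 255).astype(np.uint8))
        rot, _ = rotate_pair(img, None, angle)
        out[i] = rot.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0
    return out


def train_classifier(model: ClassifierModel, train_set: LabeledImages,
                     val_set: LabeledImages, schedule: TrainSchedule
                     ) -> tuple[ClassifierModel, History]:
    """SGD training; returns the best-on-validation checkpoint and the log."""
    if len(train_set) == 0:
        raise ConfigurationError("empty training set")
    if len(val_set) == 0:
        raise ConfigurationError("empty validation set")
    if len(np.unique(train_set.y)) < 2:
        raise ConfigurationError("training set must contain both classes")

    rng = np.random.default_rng(schedule.seed)
    opt = nn.SGD(model.parameters(), lr=schedule.learning_rate,
                 momentum=schedule.momentum)
    history = History()
    best_state, best_acc = None, -1.0
    n = len(train_set)
    for epoch in range(1, schedule.epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, schedule.batch_size):
            idx = order[i:i + schedule.batch_size]
            xb = train_set.x[idx]
            if schedule.augment_rotate is not None:
                xb = _augment_batch(xb, schedule.augment_rotate, rng)
            loss = nn.cross_entropy_logits(model(nn.Tensor(xb)), train_set.y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_acc = evaluate_accuracy(model, val_set)
        history.append(EpochRecord(epoch, float(np.mean(losses)), val_acc))
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict_class(model: ClassifierModel, image: AnteriorSegmentImage | np.ndarray
                  ) -> tuple[str, np.ndarray]:
    """Predict (label, softmax probabilities); ties resolve toward "normal"."""
    if isinstance(image, AnteriorSegmentImage):
        x = image.pixels.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    else:
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
    if x.shape[1] != 3:
        raise InvalidInputError(f"expected 3-channel input, got {x.shape[1]}")
    model.eval()
    with nn.no_grad():
        probs = nn.softmax(model(nn.Tensor(x)), axis=1).data[0]
    label = LABELS[int(_argmax_tie_low(probs[None])[0])] if model.config.n_classes == 2 \
        else str(int(probs.argmax()))
    return label, probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ClassifierModel, path: str | Path) -> None:
    state = model.named_state()
    np.savez(path, __config__=json.dumps(dataclasses.asdict(model.config)),
             **{k: v for k, v in state})


def load_checkpoint(path: str | Path, seed: int = 0) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["__config__"]))
        cfg_dict.pop("pretrained_init", None)
        config = ClassifierConfig(**cfg_dict, pretrained_init=False)
        model = build_classifier(config, seed=seed)
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    model.eval()
    return model


def load_checkpoint_into(model: ClassifierModel, path: str | Path) -> None:
    with np.load(path, allow_pickle=False) as z:
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
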