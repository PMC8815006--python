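"""Classifier assembly and the two-stage transfer-learning schedule.

The network is a convolutional backbone followed by a custom head: global
average and global max pooling are concatenated (length 2C for a backbone
with C final feature channels — 1024 for the ResNet-34-style backbone),
then block B1 (batchnorm → dropout 0.5 → fully connected → ReLU) and block
B2 (batchnorm → dropout 0.25 → fully connected → softmax over the classes).

Training runs in two stages: stage 1 freezes the backbone and optimises
only the head; stage 2 fine-tunes the whole network with the backbone at a
tenth of the head learning rate. Both stages use Adam under a two-phase
simultaneous cosine annealing: the learning rate rises from
``lr_start_frac·lr_max`` to ``lr_max`` over the first ``phase1_frac`` of
steps while momentum falls from its maximum to its minimum, then the
learning rate decays to ``lr_end_frac·lr_max`` while momentum recovers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .dataset import SpecimenRecord
from .patches import PatchConfig, center_patch, make_minibatch

__all__ = [
    "ModelConfig", "TrainConfig", "WoodNet", "build_model",
    "lr_momentum_at", "train_two_stage", "save_checkpoint",
    "load_checkpoint", "load_image", "predict_image_scores",
]

BACKBONE_CHANNELS = {
    "compact_cnn": 64,
    "resnet34_style": 512,
    "resnet50_style": 2048,
}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    backbone: str = "compact_cnn"
    backbone_channels: int | None = None  # final conv feature channels C
    head_hidden: int = 512
    dropout_b1: float = 0.5
    dropout_b2: float = 0.25
    n_classes: int = 22
    in_channels: int = 1
    pretrained_weights_path: str | None = None

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONE_CHANNELS:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not (0 <= self.dropout_b1 < 1 and 0 <= self.dropout_b2 < 1):
            raise ValueError("dropouts must lie in [0, 1)")
        if self.backbone_channels is None:
            object.__setattr__(
                self, "backbone_channels", BACKBONE_CHANNELS[self.backbone]
            )

    @property
    def concat_length(self) -> int:
        return 2 * self.backbone_channels


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs_stage1: int = 5
    epochs_stage2: int = 10
    lr_max: float = 1e-3
    lr_start_frac: float = 0.04
    lr_end_frac: float = 0.01
    momentum_max: float = 0.95
    momentum_min: float = 0.85
    phase1_frac: float = 0.3
    backbone_lr_scale: float = 0.1  # stage-2 backbone discriminative rate
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.phase1_frac < 1.0:
            raise ValueError("phase1_frac must lie strictly in (0, 1)")
        if self.lr_max <= 0:
            raise ValueError("lr_max must be positive")


class WoodNet:
    """Backbone + custom head with explicit stage-aware parameter groups."""

    def __init__(self, backbone: nn.Layer, head: nn.Layer, config: ModelConfig):
        self.backbone = backbone
        self.head = head
        self.config = config

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Return logits for an (N, C, H, W) batch."""
        return self.head.forward(
            self.backbone.forward(x, training=training, rng=rng),
            training=training, rng=rng,
        )

    def backward(self, dlogits: np.ndarray, through_backbone: bool = True):
        d = self.head.backward(dlogits)
        if through_backbone:
            self.backbone.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class scores; rows are non-negative and sum to one."""
        return nn.softmax(self.forward(x, training=False))

    def head_parameters(self):
        return list(self.head.named_parameters("head."))

    def backbone_parameters(self):
        return list(self.backbone.named_parameters("backbone."))

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer, key in self.backbone.named_parameters("backbone."):
            out[name] = layer.params[key]
        for name, layer, key in self.head.named_parameters("head."):
            out[name] = layer.params[key]
        for name, layer, key in self.backbone.named_buffers("backbone."):
            out[name] = layer.buffers[key]
        for name, layer, key in self.head.named_buffers("head."):
            out[name] = layer.buffers[key]
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = {}
        for name, layer, key in list(self.backbone.named_parameters("backbone.")) + list(
            self.head.named_parameters("head.")
        ):
            own[name] = (layer.params, key)
        for name, layer, key in list(self.backbone.named_buffers("backbone.")) + list(
            self.head.named_buffers("head.")
        ):
            own[name] = (layer.buffers, key)
        for name, (store, key) in own.items():
            if name not in arrays:
                raise ValueError(f"checkpoint is missing array {name!r}")
            if arrays[name].shape != store[key].shape:
                raise ValueError(
                    f"checkpoint array {name!r} has shape {arrays[name].shape}, "
                    f"expected {store[key].shape}"
                )
            store[key] = arrays[name].copy()

    def backbone_checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name, layer, key in sorted(
            self.backbone.named_parameters(""), key=lambda t: t[0]
        ):
            h.update(layer.params[key].tobytes())
        return h.hexdigest()


def _compact_backbone(cfg: ModelConfig, rng) -> nn.Sequential:
    # 4 conv blocks; pooling in the first three keeps small patches usable
    c = cfg.backbone_channels
    widths = [max(8, c // 8), max(16, c // 4), max(32, c // 2), c]
    layers: list[nn.Layer] = []
    in_ch = cfg.in_channels
    for i, w in enumerate(widths):
        layers += [nn.Conv2d(in_ch, w, 3, rng=rng), nn.BatchNorm2d(w), nn.ReLU()]
        if i < 3:
            layers.append(nn.MaxPool2d())
        in_ch = w
    return nn.Sequential(*layers)


def _resnet_backbone(cfg: ModelConfig, rng, bottleneck: bool) -> nn.Sequential:
    counts = [3, 4, 6, 3]
    widths = [64, 128, 256, 512]
    layers: list[nn.Layer] = [
        nn.Conv2d(cfg.in_channels, 64, 7, stride=2, pad=3, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
        nn.MaxPool2d(),
    ]
    in_ch = 64
    for stage, (n, w) in enumerate(zip(counts, widths)):
        for b in range(n):
            stride = 2 if (stage > 0 and b == 0) else 1
            if bottleneck:
                block = nn.BottleneckBlock(in_ch, w, stride=stride, rng=rng)
                in_ch = w * nn.BottleneckBlock.expansion
            else:
                block = nn.BasicBlock(in_ch, w, stride=stride, rng=rng)
                in_ch = w
            layers.append(block)
    return nn.Sequential(*layers)


def build_model(cfg: ModelConfig, seed: int = 0) -> WoodNet:
    """Construct the classifier; optionally load pretrained backbone weights.

    The head always uses He-style random initialisation; the backbone uses
    the same unless ``pretrained_weights_path`` points at a compatible
    checkpoint saved by :func:`save_checkpoint`.
    """
    rng = np.random.default_rng(seed)
    if cfg.backbone == "compact_cnn":
        backbone = _compact_backbone(cfg, rng)
    elif cfg.backbone == "resnet34_style":
        backbone = _resnet_backbone(cfg, rng, bottleneck=False)
    else:
        backbone = _resnet_backbone(cfg, rng, bottleneck=True)
    head = nn.Sequential(
        nn.GlobalAvgMaxConcat(),
        nn.BatchNorm1d(cfg.concat_length),
        nn.Dropout(cfg.dropout_b1),
        nn.Linear(cfg.concat_length, cfg.head_hidden, rng=rng),
        nn.ReLU(),
        nn.BatchNorm1d(cfg.head_hidden),
        nn.Dropout(cfg.dropout_b2),
        nn.Linear(cfg.head_hidden, cfg.n_classes, rng=rng),
    )
    model = WoodNet(backbone, head, cfg)
    if cfg.pretrained_weights_path:
        arrays = dict(np.load(cfg.pretrained_weights_path))
        backbone_arrays = {
            k: v for k, v in arrays.items() if k.startswith("backbone.")
        }
        if not backbone_arrays:
            raise ValueError(
                f"{cfg.pretrained_weights_path}: no backbone arrays found"
            )
        for name, layer, key in list(model.backbone.named_parameters("backbone.")):
            if name not in backbone_arrays:
                raise ValueError(f"pretrained file missing {name!r}")
            if backbone_arrays[name].shape != layer.params[key].shape:
                raise ValueError(
                    f"pretrained array {name!r} incompatible with backbone "
                    f"{cfg.backbone!r}"
                )
            layer.params[key] = backbone_arrays[name].copy()
        for name, layer, key in list(model.backbone.named_buffers("backbone.")):
            if name in backbone_arrays:
                layer.buffers[key] = backbone_arrays[name].copy()
    return model


# ---------------------------------------------------------------------------
# Schedule


def _cosine(t: float, start: float, end: float) -> float:
    return end + (start - end) * 0.5 * (1.0 + math.cos(math.pi * t))


def lr_momentum_at(
    step: int, total_steps: int, cfg: TrainConfig
) -> tuple[float, float]:
    """Learning rate and momentum at a step of the two-phase cosine cycle.

    Phase 1 (the first ``phase1_frac`` of steps) raises the learning rate
    from its start value to ``lr_max`` while momentum anneals from its
    maximum to its minimum; phase 2 decays the learning rate to its end
    value while momentum mirrors back up.
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    lr_start = cfg.lr_start_frac * cfg.lr_max
    lr_end = cfg.lr_end_frac * cfg.lr_max
    split = cfg.phase1_frac * total_steps
    if step <= split:
        t = step / split if split > 0 else 1.0
        return (
            _cosine(t, lr_start, cfg.lr_max),
            _cosine(t, cfg.momentum_max, cfg.momentum_min),
        )
    t = (step - split) / (total_steps - split)
    return (
        _cosine(t, cfg.lr_max, lr_end),
        _cosine(t, cfg.momentum_min, cfg.momentum_max),
    )


# ---------------------------------------------------------------------------
# Training


def load_image(path: str | Path) -> np.ndarray:
    """Load a greyscale image as float32 in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float32) / 255.0


class _ImageCache:
    def __init__(self, root: Path | None):
        self.root = root
        self._cache: dict[str, np.ndarray] = {}

    def get(self, path: str) -> np.ndarray:
        if path not in self._cache:
            full = Path(path) if self.root is None else self.root / path
            self._cache[path] = load_image(full)
        return self._cache[path]


def _label_index(class_labels: Sequence[str]) -> dict[str, int]:
    return {c: i for i, c in enumerate(class_labels)}


def train_two_stage(
    model: WoodNet,
    train_specimens: Sequence[SpecimenRecord],
    class_labels: Sequence[str],
    train_cfg: TrainConfig,
    patch_cfg: PatchConfig,
    images_root: str | Path | None = None,
    image_arrays: dict[str, np.ndarray] | None = None,
) -> tuple[WoodNet, pd.DataFrame]:
    """Run the two-stage schedule and return the per-epoch loss log.

    Stage 1 updates only head parameters (the backbone is bit-exactly
    frozen); stage 2 updates everything with the backbone learning rate
    scaled down. Images may be supplied pre-loaded via ``image_arrays``
    (keyed by manifest path) or read from ``images_root``.
    """
    present = {r.class_label for r in train_specimens}
    if len(present) < 2:
        raise ValueError("training requires at least two classes of specimens")
    missing = set(class_labels) - present
    if missing:
        import warnings

        warnings.warn(
            f"classes with no training specimens: {sorted(missing)}",
            stacklevel=2,
        )

    cache = _ImageCache(Path(images_root) if images_root else None)
    items: list[tuple[str, str]] = []  # (image path, class label)
    for rec in train_specimens:
        items += [(p, rec.class_label) for p in rec.image_paths]
    idx = _label_index(class_labels)

    def get_image(path: str) -> np.ndarray:
        if image_arrays is not None and path in image_arrays:
            return image_arrays[path]
        return cache.get(path)

    rng = np.random.default_rng(train_cfg.seed)
    bs = min(train_cfg.batch_size, len(items))
    log_rows = []

    for stage in (1, 2):
        epochs = train_cfg.epochs_stage1 if stage == 1 else train_cfg.epochs_stage2
        if epochs <= 0:
            continue
        head_refs = [(layer, key) for _, layer, key in model.head_parameters()]
        if stage == 1:
            groups = [{"params": head_refs, "lr_scale": 1.0}]
        else:
            bb_refs = [(layer, key) for _, layer, key in model.backbone_parameters()]
            groups = [
                {"params": head_refs, "lr_scale": 1.0},
                {"params": bb_refs, "lr_scale": train_cfg.backbone_lr_scale},
            ]
        opt = nn.Adam(groups)
        batches_per_epoch = max(1, len(items) // bs)
        total_steps = epochs * batches_per_epoch
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(len(items))
            epoch_losses = []
            lr = mom = 0.0
            for b in range(batches_per_epoch):
                take = order[b * bs : (b + 1) * bs]
                imgs = [get_image(items[i][0]) for i in take]
                labels = [items[i][1] for i in take]
                keys = [items[i][0] for i in take]
                batch_cfg = (
                    patch_cfg if bs == patch_cfg.batch_size
                    else dataclasses.replace(patch_cfg, batch_size=bs)
                )
                batch, labels = make_minibatch(imgs, labels, batch_cfg, rng, keys=keys)
                x = np.transpose(batch, (0, 3, 1, 2))  # NHWC → NCHW
                x = (x - 0.5) / 0.25
                targets = np.array([idx[l] for l in labels])
                logits = model.forward(x, training=True, rng=rng)
                loss, dlogits = nn.softmax_cross_entropy(logits, targets)
                model.backward(dlogits, through_backbone=(stage == 2))
                lr, mom = lr_momentum_at(step, total_steps, train_cfg)
                opt.step(lr, mom)
                step += 1
                epoch_losses.append(loss)
            log_rows.append(
                {
                    "stage": stage,
                    "epoch": epoch + 1,
                    "loss": float(np.mean(epoch_losses)),
                    "lr": lr,
                    "momentum": mom,
                }
            )
    return model, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Inference and checkpoints


def predict_image_scores(
    model: WoodNet, image: np.ndarray, patch_cfg: PatchConfig
) -> np.ndarray:
    """Class scores for one image, averaged over a deterministic patch tiling.

    Three full-width patches at the top, centre, and bottom row offsets
    cover the image deterministically; their softmax scores are averaged.
    A single patch can miss structure (e.g. every earlywood band of a
    wide-ringed specimen), so the tiling stabilises image-level calls while
    keeping inference exactly reproducible.
    """
    rows = image.shape[0]
    span = rows - patch_cfg.patch_rows
    offsets = sorted({0, span // 2, span})
    patches = [
        center_patch(image[r0 : r0 + patch_cfg.patch_rows], patch_cfg)
        for r0 in offsets
    ]
    x = ((np.stack(patches)[:, None, :, :] - 0.5) / 0.25).astype(np.float32)
    return model.predict_proba(x).mean(axis=0)


def save_checkpoint(model: WoodNet, path: str | Path) -> None:
    """Single-file .npz checkpoint with the model config embedded."""
    arrays = model.state_arrays()
    arrays["__config__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> WoodNet:
    data = dict(np.load(path))
    cfg_json = bytes(data.pop("__config__")).decode()
    cfg = ModelConfig(**json.loads(cfg_json))
    model = build_model(cfg, seed=0)
    model.load_state_arrays(data)
    return model
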