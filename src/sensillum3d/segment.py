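"""Binary sacculus segmentation: labels, augmentation, U-Net training, fallback.

The trainable route resizes sections to a square model resolution, normalizes
intensities to [0, 1], splits images 90:5:5 into train/test/validation,
optionally augments the training split (vertical flip, horizontal flip, 45°
and 130° rotations — four variants per image), and trains a small
encoder–decoder with Adam on binary cross-entropy. The epoch with the best
validation IoU is checkpointed, and the learning rate is halved when the
validation loss plateaus. A deterministic intensity-threshold fallback makes
the downstream stages testable without any training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from ._unet import Adam, UNet, bce_with_logits
from .geometry import ImageStack, LabelStack, VoxelGeometry

__all__ = [
    "TrainConfig",
    "TrainMetrics",
    "UNetModel",
    "augment_pair",
    "split_dataset",
    "iou",
    "train_unet",
    "predict_masks",
    "threshold_segment",
]

AUGMENT_ANGLES = (45.0, 130.0)


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run."""

    input_size: int = 256
    split_ratios: tuple[float, float, float] = (0.90, 0.05, 0.05)
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0
    augment: bool = True
    depth: int = 4
    base_filters: int = 16
    lr_patience: int = 3
    lr_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.input_size <= 0:
            raise ValueError("input_size must be positive")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError(f"split_ratios must sum to 1, got {self.split_ratios}")
        if self.input_size % 2**self.depth:
            raise ValueError(f"input_size {self.input_size} not divisible by 2**depth")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("input_size", "split_ratios", "epochs", "batch_size", "lr", "seed",
                 "augment", "depth", "base_filters", "lr_patience", "lr_factor")}


@dataclass
class TrainMetrics:
    """Per-epoch validation metrics; IoU governs model selection."""

    accuracy: list[float] = field(default_factory=list)
    iou: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_iou: float = 0.0
    best_epoch: int = -1


@dataclass
class UNetModel:
    """Trained model artifact: network weights plus the config fingerprint."""

    net: UNet
    input_size: int
    config: dict


def augment_pair(image: np.ndarray, label: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Four augmented variants of an (image, label) pair.

    Vertical flip, horizontal flip, and rotations by 45° and 130° about the
    image center on the same canvas (corners filled with 0). Images are
    interpolated bilinearly; labels are re-binarized at 0.5.
    """
    image = np.asarray(image)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ValueError(f"image/label shape mismatch {image.shape} vs {label.shape}")
    out = [(np.flipud(image).copy(), np.flipud(label).copy()),
           (np.fliplr(image).copy(), np.fliplr(label).copy())]
    for angle in AUGMENT_ANGLES:
        img_r = _sk_rotate(image.astype(float), angle, resize=False, cval=0.0,
                           preserve_range=True)
        lab_r = _sk_rotate(label.astype(float), angle, resize=False, cval=0.0,
                           preserve_range=True)
        out.append((img_r, (lab_r > 0.5).astype(label.dtype)))
    return out


def split_dataset(items: list, ratios: tuple[float, ...], seed: int) -> tuple[list, ...]:
    """Shuffled, disjoint, exhaustive split with largest-remainder sizing."""
    ratios = tuple(ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(items)
    nonzero = sum(r > 0 for r in ratios)
    if n < nonzero:
        raise ValueError(f"cannot split {n} items into {nonzero} nonempty parts")
    quotas = [n * r for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for i in sorted(range(len(ratios)), key=lambda i: -remainders[i])[: n - sum(sizes)]:
        sizes[i] += 1
    order = np.random.default_rng(seed).permutation(n)
    parts, start = [], 0
    for s in sizes:
        parts.append([items[i] for i in order[start:start + s]])
        start += s
    return tuple(parts)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _resize_pairs(images: np.ndarray, labels: np.ndarray, size: int,
                  ) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([_sk_resize(im.astype(float), (size, size), preserve_range=True,
                                anti_aliasing=True) for im in images])
    labs = np.stack([(_sk_resize(lb.astype(float), (size, size), preserve_range=True,
                                 order=0) > 0.5) for lb in labels])
    return imgs.astype(np.float32), labs.astype(np.float32)


def _evaluate(net: UNet, images: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(val loss, pixel accuracy, IoU) of the current weights."""
    logits = np.concatenate([net.forward(images[i:i + 8, None], train=False)
                             for i in range(0, len(images), 8)])
    loss, _ = bce_with_logits(logits, labels)
    pred = logits > 0.0  # sigmoid(z) > 0.5 <=> z > 0
    acc = float((pred == (labels > 0.5)).mean())
    return loss, acc, iou(pred, labels > 0.5)


def train_unet(images: ImageStack, labels: LabelStack, cfg: TrainConfig,
               ) -> tuple[UNetModel, TrainMetrics]:
    """Train the U-Net on paired stacks; returns the best-validation-IoU model.

    The 90:5:5 split is performed on original images; when augmentation is on,
    the four variants of each training image join the training set (the split
    never mixes a parent and its augmented copies across subsets).
    """
    if images.sections.shape != labels.sections.shape:
        raise ValueError("image and label stacks must have matching shapes")
    if labels.sections.sum() == 0:
        raise ValueError("degenerate labels: no foreground pixels to learn from")
    imgs, labs = _resize_pairs(images.sections, labels.sections, cfg.input_size)
    lo, hi = float(imgs.min()), float(imgs.max())
    imgs = (imgs - lo) / (hi - lo) if hi > lo else np.zeros_like(imgs)
    train_idx, _test_idx, val_idx = split_dataset(list(range(len(imgs))),
                                                  cfg.split_ratios, cfg.seed)
    if not train_idx:
        raise ValueError("empty training split")
    if not val_idx:
        raise ValueError("empty validation split: increase the stack size")
    x_tr = [imgs[i] for i in train_idx]
    y_tr = [labs[i] for i in train_idx]
    if cfg.augment:
        for i in train_idx:
            for im_a, lb_a in augment_pair(imgs[i], labs[i]):
                x_tr.append(im_a.astype(np.float32))
                y_tr.append(lb_a.astype(np.float32))
    x_tr = np.stack(x_tr)
    y_tr = np.stack(y_tr)
    x_val = imgs[val_idx]
    y_val = labs[val_idx]

    rng = np.random.default_rng(cfg.seed)
    net = UNet(depth=cfg.depth, base_filters=cfg.base_filters, seed=cfg.seed)
    opt = Adam(net, lr=cfg.lr)
    metrics = TrainMetrics()
    best_params = net.snapshot()
    plateau = 0
    best_loss = np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            _, dlogits = bce_with_logits(net.forward(x_tr[sel][:, None]), y_tr[sel])
            net.backward(dlogits)
            opt.step()
        val_loss, acc, val_iou = _evaluate(net, x_val, y_val)
        metrics.val_loss.append(val_loss)
        metrics.accuracy.append(acc)
        metrics.iou.append(val_iou)
        metrics.lr.append(opt.lr)
        if val_iou > metrics.best_iou:
            metrics.best_iou = val_iou
            metrics.best_epoch = epoch
            best_params = net.snapshot()
        if val_loss < best_loss - 1e-4:
            best_loss = val_loss
            plateau = 0
        else:
            plateau += 1
            if plateau >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                plateau = 0
    net.set_parameters(best_params)
    model = UNetModel(net=net, input_size=cfg.input_size, config=cfg.to_dict())
    return model, metrics


def predict_masks(model: UNetModel, images: ImageStack, threshold: float = 0.5,
                  ) -> LabelStack:
    """Predict binary masks at model resolution (geometry rescaled to match)."""
    size = model.input_size
    data = np.stack([_sk_resize(im.astype(float), (size, size), preserve_range=True,
                                anti_aliasing=True) for im in images.sections])
    lo, hi = float(data.min()), float(data.max())
    data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    proba = model.net.predict_proba(data.astype(np.float32))
    masks = (proba > threshold).astype(np.uint8)
    rows, cols = images.section_shape
    geom = VoxelGeometry(pixel_x=images.geometry.pixel_x * cols / size,
                         pixel_y=images.geometry.pixel_y * rows / size,
                         slice_z=images.geometry.slice_z)
    return LabelStack(sections=masks, geometry=geom, origin_index=images.origin_index,
                      metadata={"threshold": threshold, "model": model.config})


def threshold_segment(images: ImageStack, level: float) -> LabelStack:
    """Deterministic fallback: mask = image > level, per section."""
    if not 0 <= level <= 255:
        raise ValueError(f"level must be in [0, 255], got {level}")
    masks = (images.sections > level).astype(np.uint8)
    return LabelStack(sections=masks, geometry=images.geometry,
                      origin_index=images.origin_index, metadata={"level": level})
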