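"""Stratum-corneum segmentation: splitting, U-Net training, inference, metrics.

The dataset split is done at the patient level so frames from one subject
never leak across train/validation/test. The network is the package's NumPy
U-Net (see :mod:`octstiff.nn`); evaluation reports pixel accuracy, Dice and
IoU macro-averaged over images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import UNet, Adam, bce_dice_loss

__all__ = [
    "DatasetSplit", "TrainConfig", "SegMetrics", "SplitError",
    "split_dataset", "build_unet", "train", "predict_mask",
    "dice", "iou", "pixel_accuracy", "evaluate",
    "save_model", "load_model",
]


class SplitError(ValueError):
    pass


@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    patient_of: dict
    ratios: tuple
    seed: int

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise SplitError("subsets are not disjoint")
        for a, b in ((0, 1), (0, 2), (1, 2)):
            pa = {self.patient_of[x] for x in sets[a]}
            pb = {self.patient_of[x] for x in sets[b]}
            if pa & pb:
                raise SplitError("a patient appears in two subsets")


@dataclass
class TrainConfig:
    """U-Net architecture and optimisation settings.

    Defaults are sized for CPU training on small phantom rasters: a depth-4
    encoder starting at 16 channels, combined BCE + soft-Dice loss, Adam at
    1e-3, up to 50 epochs with early stopping (patience 10) on validation
    loss. ``input_size_px`` must be divisible by 2**depth.
    """

    depth: int = 4
    base_channels: int = 16
    loss: str = "bce+dice"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    input_size_px: int = 512
    patience: int = 10
    threshold: float = 0.5

    def __post_init__(self):
        if self.loss not in ("bce", "dice", "bce+dice"):
            raise ValueError(f"loss must be bce, dice or bce+dice, got {self.loss!r}")
        for name in ("depth", "base_channels", "learning_rate", "epochs",
                     "batch_size", "input_size_px"):
            if getattr(self, name) is None or getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SegMetrics:
    pixel_accuracy: float
    dice: float
    iou: float
    n_images: int


def split_dataset(items: list, patient_of: dict, ratios=(0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Patient-level train/val/test split approaching item-count ratios.

    Patients are shuffled with ``seed`` and assigned greedily (largest
    remaining deficit first) so that subset item counts approach
    ``ratios * n_items``; with single-item patients the subset sizes equal
    the largest-remainder rounding of the ratios exactly.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise SplitError("need three positive ratios")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError("ratios must sum to 1")
    patients = {}
    for it in items:
        patients.setdefault(patient_of[it], []).append(it)
    if len(patients) < 3:
        raise SplitError(f"need >= 3 patients, got {len(patients)}")
    n = len(items)
    # largest-remainder integer targets
    raw = [r * n for r in ratios]
    targets = [int(np.floor(x)) for x in raw]
    rem = n - sum(targets)
    order = np.argsort([t - x for t, x in zip(targets, raw)])  # most negative first
    for i in range(rem):
        targets[order[i]] += 1

    rng = np.random.default_rng(seed)
    pids = sorted(patients)
    rng.shuffle(pids)
    counts = [0, 0, 0]
    buckets: list[list] = [[], [], []]
    for pid in pids:
        deficits = [t - c for t, c in zip(targets, counts)]
        k = int(np.argmax(deficits))
        buckets[k].extend(patients[pid])
        counts[k] += len(patients[pid])
    return DatasetSplit(train_ids=buckets[0], val_ids=buckets[2],
                        test_ids=buckets[1], patient_of=dict(patient_of),
                        ratios=ratios, seed=seed)


def build_unet(config: TrainConfig) -> UNet:
    """Instantiate the U-Net; rejects input sizes not divisible by 2**depth."""
    if config.input_size_px % (2 ** config.depth):
        raise ValueError(
            f"input_size_px {config.input_size_px} not divisible by "
            f"2^depth = {2 ** config.depth}")
    return UNet(depth=config.depth, base_channels=config.base_channels,
                seed=config.seed)


def _as_batches(ids, batch_size):
    for i in range(0, len(ids), batch_size):
        yield ids[i : i + batch_size]


def _epoch_loss(model, images, masks, ids, config):
    total, npx = 0.0, 0
    for batch in _as_batches(ids, config.batch_size):
        x = images[batch][:, None]
        y = masks[batch][:, None]
        loss, _ = bce_dice_loss(model.forward(x), y, config.loss)
        total += loss * len(batch)
        npx += len(batch)
    model._cache = None
    return total / npx


def train(model: UNet, split: DatasetSplit, images: np.ndarray,
          masks: np.ndarray, config: TrainConfig):
    """Mini-batch Adam training with early stopping on validation loss.

    ``images``/``masks`` are (n, H, W) arrays indexed by the split's integer
    ids. Returns ``(model, history)`` where the model carries the weights of
    the best-validation epoch and ``history`` has per-epoch train/val losses.
    A fixed config seed fixes both initialisation and shuffling order.
    """
    if not split.train_ids or not split.val_ids:
        raise ValueError("training requires non-empty train and val subsets")
    model.check_input(images.shape[1:])
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model, lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_weights, since_best = np.inf, model.get_weights(), 0
    train_ids = np.array(split.train_ids)
    for epoch in range(config.epochs):
        rng.shuffle(train_ids)
        running, seen = 0.0, 0
        for batch in _as_batches(train_ids, config.batch_size):
            x = images[batch][:, None]
            y = masks[batch][:, None]
            logits = model.forward(x)
            loss, dz = bce_dice_loss(logits, y, config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; aborting")
            model.backward(dz)
            if config.learning_rate > 0:
                opt.step()
            running += loss * len(batch)
            seen += len(batch)
        val = _epoch_loss(model, images, masks, list(split.val_ids), config)
        history["train_loss"].append(running / seen)
        history["val_loss"].append(val)
        if val < best_val - 1e-9:
            best_val, best_weights, since_best = val, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_weights(best_weights)
    model._cache = None
    return model, history


def predict_mask(model: UNet, frame: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold the sigmoid output; ties at the threshold go to background."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim != 2:
        raise ValueError("predict_mask expects a single 2-D frame")
    model.check_input(frame.shape)
    p = model.predict_proba(frame[None, None])[0, 0]
    return (p > threshold).astype(np.uint8)


def predict_stack(model: UNet, frames: np.ndarray, threshold: float = 0.5,
                  batch_size: int = 8) -> np.ndarray:
    """Vectorised predict_mask over a (n, H, W) stack."""
    frames = np.asarray(frames, dtype=np.float32)
    out = np.empty(frames.shape, dtype=np.uint8)
    for i in range(0, len(frames), batch_size):
        p = model.predict_proba(frames[i : i + batch_size, None])[:, 0]
        out[i : i + batch_size] = (p > threshold).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Overlap metrics
# ---------------------------------------------------------------------------

def _check_pair(pred, truth):
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return pred, truth


def dice(pred, truth) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1 when both masks are empty."""
    a, b = _check_pair(pred, truth)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def iou(pred, truth) -> float:
    """|A∩B| / |A∪B|; defined as 1 when both masks are empty."""
    a, b = _check_pair(pred, truth)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, b).sum() / union


def pixel_accuracy(pred, truth) -> float:
    a, b = _check_pair(pred, truth)
    return float((a == b).mean())


def evaluate(model: UNet, images: np.ndarray, masks: np.ndarray,
             threshold: float = 0.5) -> SegMetrics:
    """Macro-average pixel accuracy / Dice / IoU over a held-out image set."""
    preds = predict_stack(model, images, threshold)
    accs = [pixel_accuracy(p, t) for p, t in zip(preds, masks)]
    dices = [dice(p, t) for p, t in zip(preds, masks)]
    ious = [iou(p, t) for p, t in zip(preds, masks)]
    return SegMetrics(pixel_accuracy=float(np.mean(accs)),
                      dice=float(np.mean(dices)), iou=float(np.mean(ious)),
                      n_images=len(images))


# ---------------------------------------------------------------------------
# Checkpointing: npz weights + JSON config sidecar
# ---------------------------------------------------------------------------

def save_model(model: UNet, config: TrainConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, *model.get_weights())
    path.with_suffix(".json").write_text(json.dumps(asdict(config), indent=1))


def load_model(path: str | Path) -> tuple[UNet, TrainConfig]:
    path = Path(path)
    config = TrainConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = build_unet(config)
    with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
        model.set_weights([z[f"arr_{i}"] for i in range(len(z.files))])
    return model, config
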