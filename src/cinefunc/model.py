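"""Desk-scale encoder-decoder segmentation network and the two-step transfer schedule.

The network is a small U-Net-style convolutional encoder-decoder written
directly in numpy (forward and backward passes are explicit): one encoder
convolution, a 2x2 average-pool bottleneck convolution, nearest-neighbor
upsampling with a skip connection, a decoder convolution, and a 1x1
classification head over the three classes (background, LV cavity, LV
myocardium). The head is the designated "final parameter group": during the
frozen phase of transfer learning only the head trains, the unfrozen phase
then trains everything.

Training minimizes a soft Dice loss over the three softmax class maps with
the Adam optimizer under a one-cycle learning-rate policy capped at the
schedule's maximum learning rate. Checkpoints are taken every
``checkpoint_every`` epochs and scored by mean validation Dice over the
foreground classes; the best phase-1 checkpoint seeds phase 2, and the
overall best checkpoint is the selected model.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktf

from .metrics import dice as dice_score

BG, LV, MY = 0, 1, 2
N_CLASSES = 3


# --------------------------------------------------------------------------
# preprocessing and augmentation
# --------------------------------------------------------------------------

def preprocess(image: np.ndarray, mask: np.ndarray | None = None,
               input_size: int = 256, normalization: str = "minmax"):
    """Scale an image (and optionally its mask) to the model input size.

    Images are resampled bilinearly and intensity-normalized ("minmax" to
    [0, 1], "zscore", "center" = mean shift only, or "none"); masks use
    nearest-neighbor so the label set is preserved. Returns the image, or an (image, mask) tuple when a mask is
    given.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image intensities must be finite")
    if img.shape != (input_size, input_size):
        img = sktf.resize(img, (input_size, input_size), order=1,
                          preserve_range=True, anti_aliasing=True)
    if normalization == "minmax":
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    elif normalization == "zscore":
        sd = img.std()
        img = (img - img.mean()) / sd if sd > 0 else np.zeros_like(img)
    elif normalization == "center":
        # shift-only: keeps a common intensity scale across frames, so blank
        # frames stay near zero instead of having their noise stretched
        img = img - img.mean()
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    if mask is None:
        return img
    m = resize_mask(mask, (input_size, input_size))
    return img, m


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor mask resampling; the label set can only shrink."""
    m = np.asarray(mask)
    if m.shape == tuple(shape):
        return m.copy()
    out = sktf.resize(m.astype(float), shape, order=0, preserve_range=True,
                      anti_aliasing=False)
    return out.astype(m.dtype)


@dataclass(frozen=True)
class AugmentPolicy:
    """Stochastic augmentation: joint geometric, image-only photometric."""

    flip_lr: bool = True
    rotation_deg: float = 90.0
    lighting: float = 0.4
    zoom: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zoom <= 0:
            raise ValueError("zoom must be positive")


def flip_pair(image: np.ndarray, mask: np.ndarray):
    return np.fliplr(image), np.fliplr(mask)


def rotate_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float):
    """Rotate image (bilinear) and mask (nearest) jointly; exact for multiples of 90."""
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        return np.rot90(image, k), np.rot90(mask, k)
    img = sktf.rotate(image, angle_deg, order=1, preserve_range=True)
    m = sktf.rotate(mask.astype(float), angle_deg, order=0,
                    preserve_range=True).astype(mask.dtype)
    return img, m


def zoom_pair(image: np.ndarray, mask: np.ndarray, factor: float):
    """Center zoom-in by ``factor`` >= 1: crop the central window, resize back."""
    if factor <= 1.0:
        return image.copy(), mask.copy()
    h, w = image.shape
    ch, cw = int(round(h / factor)), int(round(w / factor))
    y0, x0 = (h - ch) // 2, (w - cw) // 2
    img = sktf.resize(image[y0:y0 + ch, x0:x0 + cw], (h, w), order=1,
                      preserve_range=True)
    m = resize_mask(mask[y0:y0 + ch, x0:x0 + cw], (h, w))
    return img, m


def augment(image: np.ndarray, mask: np.ndarray, policy: AugmentPolicy,
            rng: np.random.Generator | None = None):
    """One stochastic augmentation draw.

    Geometric transforms (flip, rotation, zoom) hit image and mask jointly;
    lighting (brightness/contrast jitter) hits the image only. Determinism:
    without an explicit ``rng`` the draw is a pure function of
    ``policy.seed``.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    img, m = image, mask
    if policy.flip_lr and rng.random() < 0.5:
        img, m = flip_pair(img, m)
    if policy.rotation_deg > 0:
        img, m = rotate_pair(img, m, rng.uniform(-policy.rotation_deg,
                                                 policy.rotation_deg))
    if policy.zoom > 1.0:
        img, m = zoom_pair(img, m, rng.uniform(1.0, policy.zoom))
    if policy.lighting > 0:
        contrast = 1.0 + rng.uniform(-policy.lighting, policy.lighting) / 2.0
        brightness = rng.uniform(-policy.lighting, policy.lighting) / 2.0
        img = img * contrast + brightness
    return img, m


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 2-D convolution, x (B,C,H,W), w (O,C,kh,kw)."""
    kh, kw = w.shape[2:]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    B, C, H, W = x.shape
    out = np.zeros((B, w.shape[0], H, W))
    for di in range(kh):
        for dj in range(kw):
            out += np.einsum("oc,bchw->bohw", w[:, :, di, dj],
                             xp[:, :, di:di + H, dj:dj + W], optimize=True)
    return out + b[None, :, None, None]


def _conv2d_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray):
    kh, kw = w.shape[2:]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    B, C, H, W = x.shape
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for di in range(kh):
        for dj in range(kw):
            dw[:, :, di, dj] = np.einsum("bohw,bchw->oc", dout,
                                         xp[:, :, di:di + H, dj:dj + W], optimize=True)
            dxp[:, :, di:di + H, dj:dj + W] += np.einsum(
                "oc,bohw->bchw", w[:, :, di, dj], dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dx = dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp
    return dx, dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    B, C, H, W = x.shape
    return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    B, C, H, W = dout.shape
    return dout.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class SegNet:
    """Tiny U-Net-style segmentation network with an explicit head group.

    Layers: conv3x3(1->c) / pool2 / conv3x3(c->2c) / upsample2 + skip-concat /
    conv3x3(3c->c) / head conv1x1(c->3). ReLU after every non-head
    convolution. The head ("final parameter group") is what the frozen
    transfer phase trains.
    """

    HEAD_KEYS = ("wh", "bh")

    def __init__(self, channels: int = 8, input_size: int = 64, seed: int = 0,
                 normalization: str = "minmax"):
        if input_size % 2:
            raise ValueError("input_size must be even")
        c = channels
        rng = np.random.default_rng(seed)

        def he(shape):
            fan_in = int(np.prod(shape[1:]))
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.channels = c
        self.input_size = input_size
        self.normalization = normalization
        self.params: dict[str, np.ndarray] = {
            "w1": he((c, 1, 3, 3)), "b1": np.zeros(c),
            "w2": he((2 * c, c, 3, 3)), "b2": np.zeros(2 * c),
            "w3": he((c, 3 * c, 3, 3)), "b3": np.zeros(c),
            "wh": he((N_CLASSES, c, 1, 1)), "bh": np.zeros(N_CLASSES),
        }

    def parameter_groups(self) -> dict[str, list[str]]:
        head = list(self.HEAD_KEYS)
        return {"body": [k for k in self.params if k not in head], "head": head}

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits (B, 3, H, W) from images (B, H, W)."""
        p = self.params
        x = x[:, None, :, :]
        a1 = np.maximum(_conv2d(x, p["w1"], p["b1"]), 0.0)
        pool = _avgpool2(a1)
        a2 = np.maximum(_conv2d(pool, p["w2"], p["b2"]), 0.0)
        up = _upsample2(a2)
        cat = np.concatenate([a1, up], axis=1)
        a3 = np.maximum(_conv2d(cat, p["w3"], p["b3"]), 0.0)
        logits = _conv2d(a3, p["wh"], p["bh"])
        if not want_cache:
            return logits
        return logits, {"x": x, "a1": a1, "pool": pool, "a2": a2, "cat": cat, "a3": a3}

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        g: dict[str, np.ndarray] = {}
        da3, g["wh"], g["bh"] = _conv2d_backward(cache["a3"], p["wh"], dlogits)
        da3 *= cache["a3"] > 0
        dcat, g["w3"], g["b3"] = _conv2d_backward(cache["cat"], p["w3"], da3)
        c = self.channels
        da1 = dcat[:, :c]
        da2 = _upsample2_backward(dcat[:, c:])
        da2 *= cache["a2"] > 0
        dpool, g["w2"], g["b2"] = _conv2d_backward(cache["pool"], p["w2"], da2)
        da1 = da1 + _avgpool2_backward(dpool)
        da1 *= cache["a1"] > 0
        _, g["w1"], g["b1"] = _conv2d_backward(cache["x"], p["w1"], da1)
        return g

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v).copy() for k, v in state.items()}


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def soft_dice_loss(logits: np.ndarray, labels: np.ndarray, eps: float = 1e-6):
    """Soft Dice loss over the softmax class maps, and its gradient w.r.t. logits.

    Per class c: D_c = 2 sum(p_c y_c) / (sum p_c + sum y_c + eps), summed over
    the whole batch; the loss is 1 - mean_c D_c. Empty-mask frames simply have
    all their mass in the background class.
    """
    probs = softmax(logits)
    B, K, H, W = probs.shape
    onehot = np.zeros_like(probs)
    for c in range(K):
        onehot[:, c] = labels == c
    inter = (probs * onehot).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3)) + eps
    dice_c = 2.0 * inter / denom
    loss = 1.0 - dice_c.mean()
    # d(loss)/d(probs), then chain through the softmax
    dprobs = np.empty_like(probs)
    for c in range(K):
        dprobs[:, c] = -(2.0 * onehot[:, c] * denom[c] - 2.0 * inter[c]) / denom[c] ** 2 / K
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    dlogits = probs * (dprobs - dot)
    return float(loss), dlogits


def predict(model: SegNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax label mask in the source image geometry.

    The image is scaled to the model input size, classified, and the mask is
    resampled back with nearest-neighbor. The result may be all background
    (no contour calculated), which downstream treats as a missing label.
    """
    src_shape = np.asarray(image).shape
    img = preprocess(image, input_size=model.input_size,
                     normalization=model.normalization)
    logits = model.forward(img[None])
    labels = np.argmax(logits[0], axis=0).astype(np.uint8)
    return resize_mask(labels, src_shape)


def validation_dice(model: SegNet, val_set: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Selection metric: mean Dice over foreground classes (cavity, myocardium).

    Per image and class, a pair with empty reference and empty prediction is
    excluded; a pair where exactly one side is empty scores 0.
    """
    scores: list[float] = []
    for image, mask in val_set:
        pred = predict(model, image)
        ref = resize_mask(np.asarray(mask), pred.shape)
        for c in (LV, MY):
            a, b = pred == c, ref == c
            if not a.any() and not b.any():
                continue
            scores.append(dice_score(a, b))
    if not scores:
        raise ValueError("validation Dice undefined: no foreground anywhere")
    return float(np.mean(scores))


# --------------------------------------------------------------------------
# transfer-learning schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainSchedule:
    """Two-step schedule: frozen (head only) then unfrozen (all parameters)."""

    frozen_epochs: int = 100
    frozen_max_lr: float = 1e-4
    unfrozen_epochs: int = 100
    unfrozen_max_lr: float = 1e-5
    checkpoint_every: int = 10
    batch_size: int = 8

    def __post_init__(self) -> None:
        if self.frozen_max_lr <= 0 or self.unfrozen_max_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.checkpoint_every < 1:
            raise ValueError("checkpoint_every must be >= 1")
        for n in (self.frozen_epochs, self.unfrozen_epochs):
            if n % self.checkpoint_every:
                raise ValueError("checkpoint_every must divide the epoch counts")


@dataclass
class CheckpointRecord:
    phase: str  # "frozen" | "unfrozen"
    epoch: int
    validation_dice: float
    state: dict[str, np.ndarray] = field(repr=False)


class _Adam:
    def __init__(self, keys, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params, grads, trainable):
        self.t += 1
        for k in trainable:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 warmup_frac: float = 0.3) -> float:
    """One-cycle policy capped at ``max_lr``: linear warmup, cosine decay."""
    if total_steps <= 1:
        return max_lr
    warm = max(1, int(warmup_frac * total_steps))
    if step < warm:
        return max_lr * (0.1 + 0.9 * step / warm)
    frac = (step - warm) / max(1, total_steps - warm)
    return max_lr * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * frac)))


def _train_phase(model: SegNet, phase: str, epochs: int, max_lr: float,
                 schedule: TrainSchedule,
                 train_set, val_set, policy: AugmentPolicy | None,
                 rng: np.random.Generator,
                 records: list[CheckpointRecord],
                 log_rows: list[dict]) -> None:
    groups = model.parameter_groups()
    trainable = groups["head"] if phase == "frozen" else groups["head"] + groups["body"]
    opt = _Adam(model.params.keys())
    n = len(train_set)
    bs = min(schedule.batch_size, n)
    steps_per_epoch = int(np.ceil(n / bs))
    total_steps = epochs * steps_per_epoch
    step = 0
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, bs):
            batch = [train_set[j] for j in order[i0:i0 + bs]]
            imgs, masks = [], []
            for img, m in batch:
                if policy is not None:
                    img, m = augment(img, m, policy, rng=rng)
                imgs.append(img)
                masks.append(m)
            x = np.stack(imgs)
            y = np.stack(masks)
            opt.lr = one_cycle_lr(step, total_steps, max_lr)
            logits, cache = model.forward(x, want_cache=True)
            loss, dlogits = soft_dice_loss(logits, y)
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads, trainable)
            losses.append(loss)
            step += 1
        if epoch % schedule.checkpoint_every == 0:
            vd = validation_dice(model, val_set)
            records.append(CheckpointRecord(phase, epoch, vd, model.state_dict()))
            log_rows.append({"phase": phase, "epoch": epoch,
                             "train_loss": float(np.mean(losses)),
                             "validation_dice": vd})


def train_transfer(model: SegNet,
                   train_set: list[tuple[np.ndarray, np.ndarray]],
                   val_set: list[tuple[np.ndarray, np.ndarray]],
                   schedule: TrainSchedule,
                   augment_policy: AugmentPolicy | None = None,
                   seed: int = 0,
                   run_dir: str | Path | None = None
                   ) -> tuple[SegNet, list[CheckpointRecord]]:
    """Two-step transfer training with checkpointing and best-Dice selection.

    Phase 1 freezes everything but the head for ``frozen_epochs`` at
    ``frozen_max_lr``; the phase-1 checkpoint with the highest validation
    Dice seeds phase 2, which trains all parameters at ``unfrozen_max_lr``.
    The returned model is the checkpoint (either phase) with the overall
    highest validation Dice. ``train_set``/``val_set`` are lists of
    (image, mask) pairs already at the model's input size.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    for img, m in train_set + val_set:
        if img.shape != (model.input_size, model.input_size) or img.shape != m.shape:
            raise ValueError("all images/masks must match the model input size")

    rng = np.random.default_rng(seed)
    records: list[CheckpointRecord] = []
    log_rows: list[dict] = []

    _train_phase(model, "frozen", schedule.frozen_epochs, schedule.frozen_max_lr,
                 schedule, train_set, val_set, augment_policy, rng, records, log_rows)
    best_frozen = max((r for r in records if r.phase == "frozen"),
                      key=lambda r: r.validation_dice)
    model.load_state_dict(best_frozen.state)
    _train_phase(model, "unfrozen", schedule.unfrozen_epochs, schedule.unfrozen_max_lr,
                 schedule, train_set, val_set, augment_policy, rng, records, log_rows)

    best = max(records, key=lambda r: r.validation_dice)
    selected = copy.deepcopy(model)
    selected.load_state_dict(best.state)

    if run_dir is not None:
        _save_run(Path(run_dir), records, log_rows, best)
    return selected, records


def _save_run(run_dir: Path, records: list[CheckpointRecord],
              log_rows: list[dict], best: CheckpointRecord) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, r in enumerate(records):
        fname = f"checkpoint_{r.phase}_{r.epoch:04d}.npz"
        np.savez(run_dir / fname, **r.state)
        manifest.append({"file": fname, "phase": r.phase, "epoch": r.epoch,
                         "validation_dice": r.validation_dice,
                         "selected": r is best})
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(run_dir / "training_log.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["phase", "epoch", "train_loss",
                                                "validation_dice"])
        writer.writeheader()
        writer.writerows(log_rows)
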