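"""Training harness: augmentation, cross-validation folds, optimisation.

The optimisation protocol is fixed: Adam (beta1=0.9, beta2=0.999) on plain
cross-entropy over randomly augmented patches sampled from the three naive
slicing sets, learning rate 3e-4 halved when the validation loss has not
improved for a patience window, early stopping after a longer window, and
validation on centre crops.  All sizes (iterations, patch size, validation
crop) are configurable so the same code path runs both at full scale and at
the desk scale used for phantom experiments.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .multi_axes import generate_plane_set, slice_volume
from .unet_factory import ModelSpec, UNet
from .volume_io import LabelVolume, Volume

logger = logging.getLogger("segscale")


@dataclass(frozen=True)
class TrainConfig:
    max_iterations: int = 1_500_000
    lr: float = 0.0003
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    plateau_patience_iters: int = 10_000
    lr_factor: float = 0.5
    early_stop_patience_iters: int = 30_000  # 3x the plateau patience
    val_interval: int = 100
    val_crop: int = 992
    max_val_slices: int = 8
    seed: int = 0
    loss: str = "cross-entropy"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")
        if self.plateau_patience_iters <= 0 or self.early_stop_patience_iters <= 0:
            raise ValueError("patience windows must be positive")
        if self.loss != "cross-entropy":
            raise ValueError("only cross-entropy loss is supported")


@dataclass(frozen=True)
class AugmentationConfig:
    area_fraction_range: tuple[float, float] = (0.85, 1.0)
    aspect_range: tuple[float, float] = (3.0 / 4.0, 4.0 / 3.0)
    hflip_prob: float = 0.5
    rotation_deg_range: tuple[float, float] = (-90.0, 90.0)
    rotation_prob: float = 1.0
    elastic_grid_spacing_px: int = 64
    elastic_sigma_px: float = 10.0
    elastic_prob: float = 0.3
    brightness_delta_range: tuple[float, float] = (-0.1, 0.1)
    contrast_factor_range: tuple[float, float] = (0.9, 1.1)
    photometric_prob: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (self.area_fraction_range, self.aspect_range,
                       self.rotation_deg_range, self.brightness_delta_range,
                       self.contrast_factor_range):
            if lo > hi:
                raise ValueError("augmentation ranges must be well ordered")
        for p in (self.hflip_prob, self.rotation_prob, self.elastic_prob,
                  self.photometric_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class FoldSplit:
    assignments: dict[str, int]

    @property
    def n_folds(self) -> int:
        return max(self.assignments.values()) + 1

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignments.items() if f == fold]


def make_folds(sample_ids, n_folds: int = 4, seed: int = 0) -> FoldSplit:
    """Seeded shuffle then round-robin assignment; fold sizes differ by <= 1."""
    ids = list(sample_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return FoldSplit({ids[j]: i % n_folds for i, j in enumerate(order)})


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def sample_patch(
    image: np.ndarray,
    label: np.ndarray,
    cfg: AugmentationConfig,
    out_size: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random patch with 85-100 % of the image area and an aspect ratio
    evenly distributed in [3:4, 4:3], resized to ``out_size`` (bilinear for
    the image, nearest for the label)."""
    if image.shape != label.shape:
        raise ValueError("image and label must be congruent")
    h, w = image.shape
    area = rng.uniform(*cfg.area_fraction_range) * h * w
    aspect = rng.uniform(*cfg.aspect_range)
    ph = min(h, max(1, int(round(np.sqrt(area * aspect)))))
    pw = min(w, max(1, int(round(np.sqrt(area / aspect)))))
    if ph > h or pw > w:
        raise ValueError("image smaller than the minimal patch")
    top = rng.integers(0, h - ph + 1)
    left = rng.integers(0, w - pw + 1)
    img_p = image[top:top + ph, left:left + pw]
    lab_p = label[top:top + ph, left:left + pw]
    img_r = resize(img_p.astype(np.float32), out_size, order=1,
                   anti_aliasing=False, preserve_range=True)
    lab_r = resize(lab_p, out_size, order=0, anti_aliasing=False,
                   preserve_range=True).astype(label.dtype)
    return img_r.astype(np.float32), lab_r


def _elastic_fields(shape, spacing, sigma, rng):
    coarse = (max(2, shape[0] // spacing + 1), max(2, shape[1] // spacing + 1))
    dy = resize(rng.standard_normal(coarse) * sigma, shape, order=1,
                anti_aliasing=False)
    dx = resize(rng.standard_normal(coarse) * sigma, shape, order=1,
                anti_aliasing=False)
    return dy, dx


def augment_pair(
    image: np.ndarray,
    label: np.ndarray,
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    rotation_deg: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Identical geometric transforms on image and label (flip, rotation,
    elastic deformation); photometric changes on the image only.

    ``rotation_deg`` forces a specific rotation angle (paired-transform
    checks); by default the angle is drawn from the configured range.
    """
    img, lab = image, label
    if rng.random() < cfg.hflip_prob:
        img, lab = img[:, ::-1].copy(), lab[:, ::-1].copy()
    if rotation_deg is not None or rng.random() < cfg.rotation_prob:
        theta = rotation_deg if rotation_deg is not None else rng.uniform(
            *cfg.rotation_deg_range
        )
        if theta != 0.0:
            img = ndimage.rotate(img, theta, reshape=False, order=1, mode="nearest")
            lab = ndimage.rotate(lab, theta, reshape=False, order=0, mode="nearest")
    if rng.random() < cfg.elastic_prob:
        dy, dx = _elastic_fields(img.shape, cfg.elastic_grid_spacing_px,
                                 cfg.elastic_sigma_px, rng)
        yy, xx = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                             indexing="ij")
        coords = np.stack([yy + dy, xx + dx])
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        lab = ndimage.map_coordinates(lab, coords, order=0, mode="nearest")
    if rng.random() < cfg.photometric_prob:
        delta = rng.uniform(*cfg.brightness_delta_range)
        factor = rng.uniform(*cfg.contrast_factor_range)
        m = img.mean()
        img = np.clip((img - m) * factor + m + delta, 0.0, 1.0)
    return img.astype(np.float32), lab


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------


@dataclass
class LRState:
    lr: float
    best_val_loss: float = float("inf")
    iters_since_improve: int = 0
    iters_since_improve_total: int = 0


def lr_schedule_step(state: LRState, val_loss: float, cfg: TrainConfig) -> LRState:
    """Plateau schedule: one call per validation (``val_interval`` iterations).

    A strict improvement resets both counters; once the plateau counter
    reaches the patience the learning rate is halved and the plateau counter
    resets.  The lr sequence is non-increasing by construction.
    """
    s = replace(state)
    if val_loss < s.best_val_loss:
        s.best_val_loss = val_loss
        s.iters_since_improve = 0
        s.iters_since_improve_total = 0
        return s
    s.iters_since_improve += cfg.val_interval
    s.iters_since_improve_total += cfg.val_interval
    if s.iters_since_improve >= cfg.plateau_patience_iters:
        s.lr *= cfg.lr_factor
        s.iters_since_improve = 0
        logger.info("plateau: learning rate halved to %.3g", s.lr)
    return s


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class TrainedModel:
    """Inference wrapper around a trained network (evaluation mode)."""

    def __init__(self, net: UNet):
        self.net = net
        self.spec = net.spec

    @property
    def divisor(self) -> int:
        return 2**self.spec.depth_d

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(x)

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.net.state())}
        spec = self.spec
        np.savez_compressed(
            path,
            __spec__=np.frombuffer(json.dumps({
                "width_c0": spec.width_c0, "depth_d": spec.depth_d,
                "input_size": list(spec.input_size), "n_classes": spec.n_classes,
                "in_channels": spec.in_channels,
            }).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__spec__"]).decode())
        meta["input_size"] = tuple(meta["input_size"])
        net = UNet(ModelSpec(**meta))
        n = len([k for k in data.files if k.startswith("arr_")])
        net.load_state([data[f"arr_{i}"] for i in range(n)])
        return cls(net)


def _training_pairs(samples: dict[str, tuple[Volume, LabelVolume]]):
    """All 2D (image, label) slice pairs from the three naive planes."""
    pairs = []
    for sid in sorted(samples):
        vol, lab = samples[sid]
        for t in generate_plane_set(3):
            imgs = slice_volume(vol, t).slices
            labs = slice_volume(Volume(lab.data.astype(np.float32), lab.geometry), t
                                ).slices.astype(lab.data.dtype)
            for i in range(imgs.shape[0]):
                pairs.append((imgs[i], labs[i]))
    return pairs


def _center_crop(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape
    ch, cw = min(size[0], h), min(size[1], w)
    top, left = (h - ch) // 2, (w - cw) // 2
    return arr[top:top + ch, left:left + cw]


def train_single(
    spec: ModelSpec,
    train_samples: dict[str, tuple[Volume, LabelVolume]],
    val_samples: dict[str, tuple[Volume, LabelVolume]],
    cfg: TrainConfig,
    aug: AugmentationConfig | None = None,
) -> tuple[TrainedModel, dict]:
    """Train one model on the 3 naive slicing sets of the training samples.

    Returns the best-validation-loss checkpoint and the loss history.
    """
    if not train_samples or not val_samples:
        raise ValueError("need at least one training and one validation sample")
    aug = aug or AugmentationConfig()
    rng = np.random.default_rng(cfg.seed)
    net = UNet(spec, seed=cfg.seed)
    opt = nn.Adam(net.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)

    pairs = _training_pairs(train_samples)
    val_pairs = _training_pairs(val_samples)
    # validation: centre crops of a fixed slice subset, divisible by 2^d
    div = 2**spec.depth_d
    crop = min(cfg.val_crop, min(min(p[0].shape) for p in val_pairs))
    crop -= crop % div
    if crop < div:
        raise ValueError("validation slices smaller than one pooling cell")
    stride = max(1, len(val_pairs) // cfg.max_val_slices)
    val_sel = val_pairs[::stride][:cfg.max_val_slices]
    val_x = np.stack([_center_crop(im, (crop, crop)) for im, _ in val_sel])[:, None]
    val_y = np.stack([_center_crop(lb, (crop, crop)) for _, lb in val_sel])
    val_y = val_y.astype(np.int64)

    out_hw = (spec.input_size[1], spec.input_size[0])  # (rows, cols)
    state = LRState(lr=cfg.lr)
    history = {"iteration": [], "train_loss": [], "val_loss": [], "lr": []}
    best_state = net.state()
    best_val = float("inf")
    t0 = time.time()
    running_loss = 0.0
    for it in range(1, cfg.max_iterations + 1):
        xb = np.empty((cfg.batch_size, 1) + out_hw, dtype=np.float32)
        yb = np.empty((cfg.batch_size,) + out_hw, dtype=np.int64)
        for b in range(cfg.batch_size):
            im, lb = pairs[rng.integers(len(pairs))]
            im_p, lb_p = sample_patch(im, lb, aug, out_hw, rng)
            im_p, lb_p = augment_pair(im_p, lb_p, aug, rng)
            xb[b, 0], yb[b] = im_p, lb_p
        logits = net.forward(xb, training=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, yb)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it} (loss={loss})")
        net.backward(dlogits)
        opt.lr = state.lr
        opt.step()
        running_loss += loss

        if it % cfg.val_interval == 0 or it == cfg.max_iterations:
            vloss = _eval_loss(net, val_x, val_y)
            state = lr_schedule_step(state, vloss, cfg)
            if vloss < best_val:
                best_val = vloss
                best_state = net.state()
            history["iteration"].append(it)
            history["train_loss"].append(running_loss / min(it, cfg.val_interval))
            history["val_loss"].append(vloss)
            history["lr"].append(state.lr)
            logger.info(
                "iter %d lr %.3g train %.4f val %.4f (%.0fs)",
                it, state.lr, history["train_loss"][-1], vloss, time.time() - t0,
            )
            running_loss = 0.0
            if state.iters_since_improve_total >= cfg.early_stop_patience_iters:
                logger.info("early stopping at iteration %d", it)
                break
    net.load_state(best_state)
    history["best_val_loss"] = best_val
    return TrainedModel(net), history


def _eval_loss(net: UNet, val_x: np.ndarray, val_y: np.ndarray) -> float:
    total, n = 0.0, 0
    for i in range(val_x.shape[0]):
        logits = net.forward(val_x[i:i + 1], training=False)
        loss, _ = nn.softmax_cross_entropy(logits, val_y[i:i + 1])
        total += loss
        n += 1
    return total / n


def train_model(
    spec: ModelSpec,
    samples: dict[str, tuple[Volume, LabelVolume]],
    cfg: TrainConfig,
    folds: FoldSplit | None = None,
    aug: AugmentationConfig | None = None,
) -> dict[int, tuple[TrainedModel, dict]]:
    """Cross-validated training: one model per fold (fold = validation set).

    With ``folds=None`` a single 'fold 0' is trained with the
    lexicographically last sample held out for validation.
    """
    if folds is None:
        ids = sorted(samples)
        folds = FoldSplit({sid: (0 if sid == ids[-1] else 1) for sid in ids})
        results = {}
        val_ids = folds.fold_ids(0)
        train_ids = [s for s in ids if s not in val_ids]
        results[0] = train_single(
            spec, {s: samples[s] for s in train_ids},
            {s: samples[s] for s in val_ids}, cfg, aug,
        )
        return results
    results = {}
    for f in range(folds.n_folds):
        val_ids = folds.fold_ids(f)
        train_ids = [s for s in samples if s not in val_ids]
        if not train_ids or not val_ids:
            raise ValueError(f"fold {f} has an empty train or validation set")
        cfg_f = replace(cfg, seed=cfg.seed + f)
        results[f] = train_single(
            spec, {s: samples[s] for s in train_ids},
            {s: samples[s] for s in val_ids}, cfg_f, aug,
        )
    return results
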