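"""Training and evaluation of the density regressor.

The loss is the per-pixel mean squared error between predicted and target
density maps. Optimization uses Adam (lr 1e-3, betas 0.9/0.99, weight
decay 1e-5) with early stopping on validation loss; the weights from the
best validation epoch are returned. One epoch is one pass over the
training patches with a fresh random rotation+crop per patch, targets
regenerated from the transformed points.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting_peaks import integrate_count
from .density_targets import (KernelConfig, PointAnnotationSet, augment,
                              gaussian_density_map, split_into_tiles)
from .unet_model import UNet, normalize_input

logger = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "CountMetrics", "Sample", "mse_loss", "train",
           "evaluate"]


@dataclass
class Sample:
    """One dataset entry: image plus its ground-truth points."""

    image_id: str
    image: np.ndarray  # (H, W, 3) uint8
    annotations: PointAnnotationSet


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    weight_decay: float = 1e-5
    batch_size: int = 20
    max_epochs: int = 1000
    early_stop_patience: int = 30
    sigma: float = 6.0
    crop_size: int = 256
    rotate: bool = True
    seed: int = 0
    # Internal optimization detail: the regressor is fit against targets
    # multiplied by this factor (density peaks are ~1e-3, so raw MSE
    # gradients drown in the weight-decay term); after training the factor
    # is folded into the final 1x1 conv (ReLU(x/s) == ReLU(x)/s), so the
    # returned model predicts true density and all reported losses are on
    # the unscaled maps.
    target_scale: float = 100.0

    def __post_init__(self):
        if min(self.learning_rate, self.beta1, self.beta2,
               self.weight_decay) <= 0:
            raise ValueError("rates and decays must be positive")
        if self.target_scale <= 0:
            raise ValueError("target_scale must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def kernel(self) -> KernelConfig:
        return KernelConfig(sigma=self.sigma)


@dataclass
class CountMetrics:
    mae: float
    mapd: float
    pixel_mse: float

    def __post_init__(self):
        if min(self.mae, self.mapd, self.pixel_mse) < 0:
            raise ValueError("metrics must be nonnegative")


def mse_loss(predicted, target) -> float:
    """Mean over all pixels of the squared difference."""
    p = np.asarray(predicted, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def _val_tiles(val_set, config: TrainingConfig):
    """Validation inputs: the non-overlapping crop_size sub-tiles of each
    patch (whole patch if not divisible), no rotation."""
    tiles = []
    for s in val_set:
        h, w = s.image.shape[:2]
        if h % config.crop_size == 0 and w % config.crop_size == 0:
            parts = split_into_tiles(s.image, config.crop_size)
        else:
            parts = [(s.image, (0, 0))]
        for img, (r0, c0) in parts:
            th, tw = img.shape[:2]
            pts = s.annotations.points - [r0, c0]
            keep = ((pts[:, 0] >= 0) & (pts[:, 0] < th)
                    & (pts[:, 1] >= 0) & (pts[:, 1] < tw)) if len(pts) \
                else np.zeros(0, dtype=bool)
            ann = PointAnnotationSet(s.image_id, pts[keep])
            target = gaussian_density_map(ann, (th, tw), config.kernel)
            tiles.append((normalize_input(img),
                          (config.target_scale
                           * target.values).astype(np.float32)))
    return tiles


def _validation_mse(model: UNet, tiles, batch_size: int) -> float:
    total, n_px = 0.0, 0
    for i in range(0, len(tiles), batch_size):
        chunk = tiles[i:i + batch_size]
        x = np.stack([t[0] for t in chunk])
        y = np.stack([t[1] for t in chunk])[..., None]
        pred = model.forward(x, train=False)
        total += float(np.sum((pred - y) ** 2))
        n_px += y.size
    return total / n_px


def train(model: UNet, train_set, val_set, config: TrainingConfig, *,
          val_fn=None):
    """Fit the model; returns ``(best_weights, history)``.

    ``history`` is a list of ``{"epoch", "train_mse", "val_mse"}`` dicts.
    Training halts when validation loss has not improved for
    ``early_stop_patience`` consecutive epochs, or at ``max_epochs``; the
    model is left holding (and ``best_weights`` contains) the weights of
    the best validation epoch. ``val_fn(model) -> float`` overrides the
    built-in tiled validation (used by tests).
    """
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(lr=config.learning_rate, beta1=config.beta1,
                               beta2=config.beta2,
                               weight_decay=config.weight_decay)
    if val_fn is None:
        tiles = _val_tiles(val_set, config)
        val_fn = lambda m: _validation_mse(m, tiles, config.batch_size)

    history = []
    best_val = np.inf
    best_weights = None
    best_epoch = -1
    bad_epochs = 0
    n = len(train_set)
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xs, ts = [], []
            for j in idx:
                s = train_set[j]
                patch, ann = augment(s.image, s.annotations,
                                     config.crop_size, rng,
                                     rotate=config.rotate)
                target = gaussian_density_map(
                    ann, (config.crop_size, config.crop_size), config.kernel)
                xs.append(normalize_input(patch))
                ts.append((config.target_scale
                           * target.values).astype(np.float32))
            x = np.stack(xs)
            t = np.stack(ts)[..., None]
            pred = model.forward(x, train=True)
            diff = pred - t
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {epoch}; "
                    "try a lower learning rate")
            losses.append(loss)
            model.backward((2.0 / diff.size) * diff)
            opt.step()
        unscale = config.target_scale ** 2
        val_mse = float(val_fn(model)) / unscale
        history.append({"epoch": epoch,
                        "train_mse": float(np.mean(losses)) / unscale,
                        "val_mse": val_mse})
        improved = val_mse < best_val
        logger.info("epoch %d train_mse=%.6g val_mse=%.6g%s", epoch,
                    history[-1]["train_mse"], val_mse,
                    " *" if improved else "")
        if improved:
            best_val = val_mse
            best_weights = model.get_weights()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                logger.info("early stop at epoch %d (best epoch %d)",
                            epoch, best_epoch)
                break
    model.set_weights(best_weights)
    if config.target_scale != 1.0 and hasattr(model, "head"):
        # fold the training-time target scale into the linear head so the
        # model predicts true (unit-mass) density from here on
        model.head.w /= config.target_scale
        model.head.b /= config.target_scale
        best_weights = model.get_weights()
    return best_weights, history


def evaluate(model: UNet, eval_set, sigma: float = 6.0):
    """Count and pixel metrics on a dataset; returns (metrics, table).

    The table has one row per patch: actual count, integrated predicted
    count, and per-patch pixel MSE. MAE averages |predicted - actual| over
    all patches; MAPD averages the percent deviation over patches with
    actual > 0 only (zero-count patches still contribute to MAE).
    """
    if not len(eval_set):
        raise ValueError("eval set is empty")
    kernel = KernelConfig(sigma=sigma)
    rows = []
    for s in eval_set:
        h, w = s.image.shape[:2]
        pred = model.forward(normalize_input(s.image)[None],
                             train=False)[0, :, :, 0]
        target = gaussian_density_map(s.annotations, (h, w), kernel).values
        rows.append({
            "image_id": s.image_id,
            "actual": s.annotations.count,
            "predicted": integrate_count(pred),
            "pixel_mse": mse_loss(pred, target),
        })
    table = pd.DataFrame(rows)
    err = (table["predicted"] - table["actual"]).abs()
    pos = table["actual"] > 0
    mapd = float((err[pos] / table.loc[pos, "actual"]).mean() * 100.0) \
        if pos.any() else 0.0
    metrics = CountMetrics(mae=float(err.mean()), mapd=mapd,
                           pixel_mse=float(table["pixel_mse"].mean()))
    return metrics, table


def samples_from_manifest(manifest: pd.DataFrame, split: str | None = None):
    """Materialize Sample objects from a manifest (in-memory or on-disk)."""
    from PIL import Image as PILImage

    from .annotation_io import read_annotations

    rows = manifest if split is None else manifest[manifest["split"] == split]
    out = []
    for _, row in rows.iterrows():
        if "image" in row.index and isinstance(row.get("image"), np.ndarray):
            img = row["image"]
            ann = row["points"]
        else:
            img = np.asarray(PILImage.open(row["path"]).convert("RGB"))
            registry = {row["image_id"]: img.shape[:2]}
            ann = read_annotations(row["annotation_path"],
                                   registry)[row["image_id"]]
        out.append(Sample(row["image_id"], img, ann))
    return out
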