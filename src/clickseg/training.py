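"""Training loop for the interactive segmentation model.

The regime follows the standard recipe for this model family: per-pixel
2-class cross-entropy, SGD with momentum 0.9, batch size 8, aspect-preserving
resize of the shorter side to 512 followed by a random 512x512 crop, a
polynomial learning-rate decay over the first 30 of 33 epochs and a constant
rate (the last poly value) for the final epochs. Clicks are re-simulated for
every sample each epoch by default, with the margin parameters freshly drawn
from their pools, so the network sees a different interaction pattern on each
pass; a fixed-clicks mode (one centred positive click) is available for
controlled overfitting experiments.

All sizes and the epoch budget are configurable, so the same loop drives both
full-scale runs and CPU-size smoke experiments.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .clicks import (
    ClickGenParams,
    ClickSet,
    DEFAULT_TRUNCATION,
    UnclickableInstanceError,
    centered_click,
    simulate_clicks,
)
from .network import InteractiveSegModel, NetworkConfig, build_input, build_model
from .nn import Tensor
from .nn import autograd as ag
from .evaluation import iou

__all__ = ["TrainConfig", "preprocess", "poly_lr", "train"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimisation and data-pipeline settings."""

    batch_size: int = 8
    epochs: int = 33
    poly_epochs: int = 30
    base_lr: float = 0.007
    poly_power: float = 0.9
    momentum: float = 0.9
    crop: int = 512
    shorter_side: int = 512
    seed: int = 0
    n_pos_range: tuple[int, int] = (1, 10)
    n_neg_range: tuple[int, int] = (0, 10)
    click_mode: str = "simulated"  # "simulated" | "fixed_center"
    truncation: float = DEFAULT_TRUNCATION

    def __post_init__(self):
        if not self.poly_epochs < self.epochs:
            raise ValueError("poly_epochs must be < epochs (constant tail phase)")
        if self.click_mode not in ("simulated", "fixed_center"):
            raise ValueError(f"unknown click_mode {self.click_mode!r}")


def _resize_image(image: np.ndarray, h: int, w: int) -> np.ndarray:
    return np.asarray(Image.fromarray(image).resize((w, h), Image.BILINEAR))


def _resize_mask(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    return np.asarray(
        Image.fromarray(mask.astype(np.uint8)).resize((w, h), Image.NEAREST)
    )


def preprocess(
    image: np.ndarray,
    mask: np.ndarray,
    crop: int,
    shorter_side: int,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Aspect-preserving resize + random crop, applied identically to both.

    The shorter side is scaled to ``shorter_side`` (bilinear for the image,
    nearest-neighbour for the mask so it stays binary), then a random
    ``crop x crop`` patch is taken. Crops that lose all foreground are
    redrawn a bounded number of times, after which the last crop is accepted.
    """
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must be at least 1x1")
    scale = shorter_side / min(h, w)
    if h <= w:
        nh, nw = shorter_side, int(round(w * scale))
    else:
        nh, nw = int(round(h * scale)), shorter_side
    if (nh, nw) != (h, w):
        image = _resize_image(image, nh, nw)
        mask = _resize_mask(mask, nh, nw)
    ch = min(crop, nh)
    cw = min(crop, nw)
    for _ in range(max_retries):
        top = int(rng.integers(0, nh - ch + 1))
        left = int(rng.integers(0, nw - cw + 1))
        m = mask[top : top + ch, left : left + cw]
        if m.any():
            break
    img_c = image[top : top + ch, left : left + cw]
    return img_c, mask[top : top + ch, left : left + cw].astype(np.uint8)


def poly_lr(
    iteration: int,
    max_poly_iterations: int,
    base_lr: float,
    power: float = 0.9,
) -> float:
    """Polynomial decay, frozen after the poly phase.

    lr(t) = base_lr * (1 - t / T)^power for t < T; every iteration in the
    constant tail (t >= T, the final epochs) returns the value reached at
    the last poly iteration t = T - 1.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    t = min(iteration, max_poly_iterations - 1)
    return base_lr * (1.0 - t / max_poly_iterations) ** power


def _sample_clicks(
    mask: np.ndarray, cfg: TrainConfig, rng: np.random.Generator
) -> ClickSet:
    if cfg.click_mode == "fixed_center":
        return centered_click(mask)
    params = ClickGenParams.draw(rng)
    n_pos = int(rng.integers(cfg.n_pos_range[0], cfg.n_pos_range[1] + 1))
    n_neg = int(rng.integers(cfg.n_neg_range[0], cfg.n_neg_range[1] + 1))
    try:
        return simulate_clicks(mask, params, n_pos, n_neg, rng)
    except UnclickableInstanceError:
        # Small object stricter than every P1 in the pool: fall back to the
        # interior-most pixel so the sample still contributes.
        return centered_click(mask)


def train(
    samples: list[tuple[np.ndarray, np.ndarray]],
    train_cfg: TrainConfig,
    net_cfg: NetworkConfig | None = None,
    model: InteractiveSegModel | None = None,
    log_path: str | Path | None = None,
) -> tuple[InteractiveSegModel, list[dict]]:
    """Train on (image, mask) pairs; returns the model and per-epoch metrics.

    Deterministic given ``train_cfg.seed`` (pure-numpy backend). Raises on a
    non-finite loss with the offending learning rate and batch index.
    """
    if not samples:
        raise ValueError("training set is empty")
    if model is None:
        model = build_model(net_cfg or NetworkConfig(), seed=train_cfg.seed)
    model.train()
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.SGD(model.parameters(), lr=train_cfg.base_lr, momentum=train_cfg.momentum)

    n = len(samples)
    steps_per_epoch = (n + train_cfg.batch_size - 1) // train_cfg.batch_size
    max_poly_iters = train_cfg.poly_epochs * steps_per_epoch

    history: list[dict] = []
    iteration = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_iou = 0.0
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            batch_idx = order[start : start + train_cfg.batch_size]
            xs, ts = [], []
            for i in batch_idx:
                image, mask = samples[int(i)]
                img_c, mask_c = preprocess(
                    image, mask, train_cfg.crop, train_cfg.shorter_side, rng
                )
                clicks = _sample_clicks(mask_c, train_cfg, rng)
                xs.append(
                    build_input(
                        img_c,
                        clicks,
                        train_cfg.truncation,
                        normalize=model.config.normalize_inputs,
                    )
                )
                ts.append(mask_c.astype(np.int64))
            x = Tensor(np.stack(xs))
            target = np.stack(ts)
            logits = model(x)
            loss = ag.softmax_cross_entropy(logits, target)
            lr = poly_lr(
                iteration, max_poly_iters, train_cfg.base_lr, train_cfg.poly_power
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} (lr={lr:g})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            iteration += 1
            with nn.no_grad():
                pred = ag.softmax2d(logits.data).argmax(axis=1)
            batch_iou = float(
                np.mean([iou(pred[j], target[j]) for j in range(pred.shape[0])])
            )
            epoch_loss += float(loss.data)
            epoch_iou += batch_iou
            n_batches += 1
        record = {
            "epoch": epoch,
            "loss": epoch_loss / n_batches,
            "train_iou": epoch_iou / n_batches,
            "lr": poly_lr(
                iteration - 1, max_poly_iters, train_cfg.base_lr, train_cfg.poly_power
            ),
        }
        history.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
    return model, history
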