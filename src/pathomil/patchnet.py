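"""Patch-level likelihood learning with weak (slide-inherited) labels.

Every tile of a slide inherits the slide's ER status as its training label;
the classifier learns tile appearance -> class likelihood, and slide-level
stages aggregate those likelihoods.  Training uses plain SGD on the softmax
cross-entropy with the cosine-decay learning-rate schedule

    eta(t) = eta_min + 1/2 (eta_max - eta_min) (1 + cos(pi t / T_i)),

with defaults eta_max = 0.01, eta_min = 0, T_i = 50 epochs.

The default ``tiny_cnn`` backbone is a compact two-layer softmax network over
2x block-downsampled, per-tile Z-scored RGB input — small enough to train on a
CPU in seconds while still recovering blob-density/texture signal.  The large
ImageNet backbones (densenet121, resnet50, inception_v3) are accepted in the
config for interface compatibility but are not implemented in this build.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .tiling import Tile

logger = logging.getLogger(__name__)

BACKBONES = ("tiny_cnn", "densenet121", "resnet50", "inception_v3")


@dataclass
class TrainConfig:
    backbone: str = "tiny_cnn"
    epochs: int = 50           # T_i of the cosine schedule
    eta_max: float = 0.01
    eta_min: float = 0.0
    batch_size: int = 32
    seed: int = 0
    augment: bool = True
    input_size: int = 32       # network input resolution (tiles are resized)
    hidden_units: int = 64
    crop_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.epochs < 1:
            raise ValueError("epochs (T_i) must be >= 1")
        if self.eta_min > self.eta_max:
            raise ValueError("eta_min must not exceed eta_max")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must lie in (0, 1]")


def cosine_lr(t_cur: int, cfg: TrainConfig) -> float:
    """Cosine-decay learning rate at epoch ``t_cur`` in [0, T_i]."""
    if not 0 <= t_cur <= cfg.epochs:
        raise ValueError(f"t_cur must lie in [0, {cfg.epochs}], got {t_cur}")
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (
        1.0 + math.cos(math.pi * t_cur / cfg.epochs)
    )


def zscore_input(tile: Tile | np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-tile, per-channel Z-score; a constant channel maps to zeros."""
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    x = pixels.astype(np.float64)
    mean = x.mean(axis=(0, 1), keepdims=True)
    std = x.std(axis=(0, 1), keepdims=True)
    return (x - mean) / np.maximum(std, eps)


def _resize(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels
    return np.asarray(Image.fromarray(pixels).resize((size, size), Image.BILINEAR))


def augment_tile(tile: Tile | np.ndarray, rng: np.random.Generator,
                 crop_fraction: float = 0.9, flips: bool = True) -> np.ndarray:
    """Random crop (resized back to the original frame) plus independent H/V flips.

    With ``crop_fraction=1.0`` and ``flips=False`` this is the identity; the
    test-time path applies no augmentation at all.
    """
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    size = pixels.shape[0]
    crop = int(round(crop_fraction * size))
    if crop < size:
        r0 = int(rng.integers(0, size - crop + 1))
        c0 = int(rng.integers(0, size - crop + 1))
        pixels = _resize(np.ascontiguousarray(pixels[r0:r0 + crop, c0:c0 + crop]), size)
    if flips:
        if rng.random() < 0.5:
            pixels = pixels[:, ::-1]
        if rng.random() < 0.5:
            pixels = pixels[::-1, :]
    return np.ascontiguousarray(pixels)


class TinyPatchNet:
    """Two-layer (ReLU hidden, softmax output) network trained with SGD.

    Input is the flattened ``input_size`` x ``input_size`` x 3 Z-scored tile.
    """

    def __init__(self, cfg: TrainConfig, n_classes: int = 2):
        self.cfg = cfg
        self.n_classes = n_classes
        d = cfg.input_size * cfg.input_size * 3
        rng = np.random.default_rng(cfg.seed)
        self.W1 = rng.normal(0.0, math.sqrt(2.0 / d), (d, cfg.hidden_units))
        self.b1 = np.zeros(cfg.hidden_units)
        self.W2 = rng.normal(0.0, math.sqrt(2.0 / cfg.hidden_units),
                             (cfg.hidden_units, n_classes))
        self.b2 = np.zeros(n_classes)

    def _features(self, tiles: np.ndarray) -> np.ndarray:
        out = np.empty((len(tiles), self.W1.shape[0]))
        for i, t in enumerate(tiles):
            out[i] = zscore_input(_resize(t, self.cfg.input_size)).ravel()
        return out

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hidden = np.maximum(x @ self.W1 + self.b1, 0.0)
        logits = hidden @ self.W2 + self.b2
        return hidden, logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def sgd_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        hidden, logits = self._forward(x)
        probs = self._softmax(logits)
        n = len(y)
        loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean()
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        g_w2 = hidden.T @ grad
        g_b2 = grad.sum(axis=0)
        g_hidden = grad @ self.W2.T
        g_hidden[hidden <= 0.0] = 0.0
        g_w1 = x.T @ g_hidden
        g_b1 = g_hidden.sum(axis=0)
        self.W2 -= lr * g_w2
        self.b2 -= lr * g_b2
        self.W1 -= lr * g_w1
        self.b1 -= lr * g_b1
        return float(loss)

    def predict_proba(self, tiles: np.ndarray | list) -> np.ndarray:
        """Class probabilities (rows sum to 1); evaluation path, no augmentation."""
        x = self._features(np.asarray(tiles) if not isinstance(tiles, np.ndarray) else tiles)
        _, logits = self._forward(x)
        return self._softmax(logits)

    def save(self, path: str | Path) -> None:
        np.savez(
            path, W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            input_size=self.cfg.input_size, hidden_units=self.cfg.hidden_units,
            n_classes=self.n_classes, seed=self.cfg.seed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TinyPatchNet":
        d = np.load(path)
        cfg = TrainConfig(input_size=int(d["input_size"]), hidden_units=int(d["hidden_units"]),
                          seed=int(d["seed"]))
        net = cls(cfg, n_classes=int(d["n_classes"]))
        net.W1, net.b1, net.W2, net.b2 = d["W1"], d["b1"], d["W2"], d["b2"]
        return net


def train_patch_model(
    tiles: np.ndarray | list,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> tuple[TinyPatchNet, pd.DataFrame]:
    """Train the patch classifier on weakly labelled tiles.

    Returns the fitted model and a per-epoch history frame with columns
    ``epoch, lr, loss, accuracy``.  The recorded ``lr`` of epoch 0 equals
    ``eta_max``.  Raises on single-class input or a NaN loss.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training tiles contain a single class; need both labels present")
    if cfg.backbone != "tiny_cnn":
        raise NotImplementedError(
            f"backbone {cfg.backbone!r} is not implemented in this build; use 'tiny_cnn'"
        )
    tiles = np.asarray(tiles)
    net = TinyPatchNet(cfg, n_classes=len(classes))
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        if cfg.augment:
            views = np.stack(
                [augment_tile(t, rng, crop_fraction=cfg.crop_fraction) for t in tiles]
            )
        else:
            views = tiles
        x = net._features(views)
        order = rng.permutation(len(labels))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses.append(net.sgd_step(x[idx], labels[idx], lr))
        loss = float(np.mean(losses))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch} (lr={lr:.4g}); "
                "lower eta_max or check the input scaling"
            )
        acc = float((net.predict_proba(tiles).argmax(axis=1) == labels).mean())
        history.append({"epoch": epoch, "lr": lr, "loss": loss, "accuracy": acc})
    return net, pd.DataFrame(history)


def predict_patches(
    model: TinyPatchNet, tiles: np.ndarray | list, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-tile positive-class likelihoods and hard labels.

    ``meta`` carries one row per tile with columns slide_id, row, col (same
    order as ``tiles``).  Returns those columns plus ``likelihood`` and
    ``pred_label`` (1 iff likelihood >= 0.5).
    """
    if len(meta) != len(tiles):
        raise ValueError(f"{len(tiles)} tiles but {len(meta)} metadata rows")
    probs = model.predict_proba(tiles)
    out = meta.loc[:, ["slide_id", "row", "col"]].reset_index(drop=True).copy()
    out["likelihood"] = probs[:, 1]
    out["pred_label"] = (out["likelihood"] >= 0.5).astype(int)
    return out


def probability_map(preds: pd.DataFrame, slide_id: str) -> np.ndarray:
    """Grid of patch likelihoods for one slide; cells with no tile are NaN."""
    sub = preds[preds["slide_id"] == slide_id]
    if sub.empty:
        raise ValueError(f"no predictions for slide {slide_id!r}")
    grid = np.full((int(sub["row"].max()) + 1, int(sub["col"].max()) + 1), np.nan)
    grid[sub["row"].to_numpy(int), sub["col"].to_numpy(int)] = sub["likelihood"].to_numpy()
    return grid


def render_probability_map(grid: np.ndarray, path: str | Path, title: str = "") -> None:
    """Save the likelihood grid as a blue-to-red heatmap PNG (higher = redder)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap="coolwarm", vmin=0.0, vmax=1.0)
    ax.set_title(title)
    ax.set_xlabel("tile column")
    ax.set_ylabel("tile row")
    fig.colorbar(im, ax=ax, label="patch likelihood")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def load_tiles_from_index(index: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Read the PNGs of a tiles.csv index; returns (tile stack, metadata rows)."""
    ok = index[index.get("status", "ok") == "ok"].reset_index(drop=True)
    tiles = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in ok["path"]])
    return tiles, ok.loc[:, ["slide_id", "row", "col"]]
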