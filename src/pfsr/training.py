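"""Patch-pair extraction and the optimisation recipe for the PF-SR model.

Training minimises the L1 loss between the network output and the
high-resolution target with decoupled weight decay (AdamW, β1=0.9, β2=0.999,
weight decay 0.01), an initial learning rate of 1e-4 decayed by 0.8 every
100 epochs, 350 epochs and batch size 8 at paper scale.  Patches of 32³ are
drawn uniformly from the low-resolution inputs, paired with the aligned 64³
patch of the target (high-res corner = upscale x low-res corner).

Desk-scale runs use the same recipe with a smaller model, fewer epochs, a
larger learning rate and smaller patches; see docs/methods.md.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import VolumeGrid
from .nn.autograd import Tensor, l1_loss, no_grad
from .nn.layers import Parameter
from .nn.model import PFSRNet, save_checkpoint


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-4
    lr_decay: float = 0.8
    lr_step_epochs: int = 100
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    epochs: int = 350
    batch: int = 8
    patch_lo: int = 32
    upscale: int = 2
    loss: str = "l1"
    seed: int = 0
    #: reject patches whose target mean is below this (mostly background);
    #: disabled when None
    foreground_threshold: float | None = 0.02
    #: random patches drawn per volume per epoch
    patches_per_volume: int = 1
    #: fraction of pairs held out for validation (split by seed)
    val_fraction: float = 0.1

    @property
    def patch_hi(self) -> int:
        return self.upscale * self.patch_lo

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "l1":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class PatchPair:
    """An aligned (low-res, high-res) training patch pair."""

    lo: np.ndarray
    hi: np.ndarray
    origin: tuple[int, int, int]  # low-res corner index


def extract_patch_pair(
    pair: tuple[VolumeGrid, VolumeGrid],
    cfg: TrainConfig,
    rng: np.random.Generator,
    corner: tuple[int, int, int] | None = None,
) -> PatchPair:
    """Draw one aligned patch pair; the corner is uniform over valid positions.

    The high-resolution patch corner is ``upscale`` times the low-resolution
    corner, so the two patches cover the same physical field of view.
    """
    lo_vol, hi_vol = pair
    p, r = cfg.patch_lo, cfg.upscale
    if any(n < p for n in lo_vol.shape):
        raise ValueError(f"volume shape {lo_vol.shape} is smaller than patch size {p}")
    if tuple(n * r for n in lo_vol.shape) != tuple(hi_vol.shape):
        raise ValueError(
            f"target shape {hi_vol.shape} is not upscale x input shape {lo_vol.shape}"
        )
    if corner is None:
        corner = tuple(int(rng.integers(0, n - p + 1)) for n in lo_vol.shape)
    z, y, x = corner
    lo = lo_vol.values[z : z + p, y : y + p, x : x + p]
    hi = hi_vol.values[r * z : r * z + r * p, r * y : r * y + r * p, r * x : r * x + r * p]
    return PatchPair(lo=lo, hi=hi, origin=corner)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: lr0 x decay^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)


class AdamW:
    """Adam with decoupled weight decay (biases are not decayed)."""

    def __init__(self, params: list[Parameter], cfg: TrainConfig):
        self.params = params
        self.beta1, self.beta2 = cfg.betas
        self.weight_decay = cfg.weight_decay
        self.eps = 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and p.data.ndim > 1:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _draw_patch(pair, cfg, rng) -> PatchPair:
    """One patch, with optional rejection of near-empty target regions."""
    patch = extract_patch_pair(pair, cfg, rng)
    if cfg.foreground_threshold is not None:
        for _ in range(20):
            if patch.hi.mean() >= cfg.foreground_threshold:
                break
            patch = extract_patch_pair(pair, cfg, rng)
    return patch


def train_model(
    model: PFSRNet,
    pairs: list[tuple[VolumeGrid, VolumeGrid]],
    cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
    log_path: str | Path | None = None,
) -> tuple[PFSRNet, list[dict]]:
    """Optimise ``model`` on (input, target) volume pairs; returns loss history.

    Fully seeded: the validation split, per-epoch volume order and patch
    corners all derive from ``cfg.seed``, so two runs with the same arguments
    produce identical loss histories and final weights.
    """
    cfg.validate()
    if not pairs:
        raise ValueError("training requires a non-empty dataset")
    if model.cfg.upscale != cfg.upscale:
        raise ValueError(
            f"model upscale {model.cfg.upscale} does not match training config {cfg.upscale}"
        )

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(pairs)))
    order = rng.permutation(len(pairs))
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split left no training pairs")

    params = model.parameters()
    opt = AdamW(params, cfg)
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        draws = np.repeat(train_idx, cfg.patches_per_volume)
        rng.shuffle(draws)
        losses = []
        for start in range(0, len(draws), cfg.batch):
            batch = draws[start : start + cfg.batch]
            model.zero_grad()
            batch_loss = 0.0
            for idx in batch:
                patch = _draw_patch(pairs[idx], cfg, rng)
                out = model(Tensor(patch.lo[None]))
                loss = l1_loss(out, patch.hi[None])
                # scale the seed so parameter grads average over the batch
                loss.backward(np.asarray(1.0 / len(batch), dtype=loss.dtype))
                batch_loss += float(loss.data)
            batch_loss /= len(batch)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite training loss {batch_loss} at epoch {epoch}; "
                    "reduce the learning rate or check the input data"
                )
            opt.step(lr)
            losses.append(batch_loss)

        record = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))}
        if len(val_idx):
            record["val_loss"] = _validation_loss(model, [pairs[i] for i in val_idx], cfg)
        history.append(record)
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, ckpt / "last.npz", seed=cfg.seed, epoch=epoch)

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return model, history


def _validation_loss(model: PFSRNet, val_pairs, cfg: TrainConfig) -> float:
    """Mean L1 on the central patch of each held-out pair (cheap, deterministic)."""
    losses = []
    for pair in val_pairs:
        centre = tuple((n - cfg.patch_lo) // 2 for n in pair[0].shape)
        patch = extract_patch_pair(pair, cfg, rng=np.random.default_rng(0), corner=centre)
        with no_grad():
            out = model(Tensor(patch.lo[None]))
        losses.append(float(np.abs(out.data - patch.hi[None]).mean()))
    return float(np.mean(losses))
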