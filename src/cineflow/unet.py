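"""2D U-Net segmentation of cine frames into four classes, plus pseudo-label
generation by motion-warping sparse manual masks.

Classes: 0 background, 1 LV blood pool, 2 myocardium, 3 RV blood pool.
The default profile uses five resolution levels with filter widths doubling
from 32 to 512 and eight convolutional blocks along the contracting path;
skips are channel concatenations and upsampling is by transposed convolution.
Inputs are min-max normalized to [-1, 1] per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .containers import N_CLASSES, CineSequence, SegMask
from .nn import functional as F
from .nn.tensor import Tensor, concatenate, softmax

__all__ = ["UnetConfig", "UNet", "build_unet", "segment", "soft_dice_loss",
           "generate_pseudo_labels", "normalize_image", "TINY_PROFILE",
           "save_checkpoint", "load_checkpoint"]

DICE_EPS = 1e-5


@dataclass
class UnetConfig:
    n_levels: int = 5
    base_filters: int = 32
    max_filters: int = 512
    encoder_blocks: tuple = (2, 2, 1, 1, 2)   # 8 conv blocks over 5 levels
    seed: int = 0

    def widths(self) -> list[int]:
        return [min(self.base_filters * 2**i, self.max_filters)
                for i in range(self.n_levels)]


TINY_PROFILE = dict(n_levels=3, base_filters=8, max_filters=32,
                    encoder_blocks=(1, 1, 1))


def _pad_rb(x: Tensor, ph: int, pw: int) -> Tensor:
    """Edge-pad bottom/right so spatial dims divide the pooling factor."""
    H, W = x.shape[2], x.shape[3]
    out_data = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")

    def backward(g):
        if not x.requires_grad:
            return
        gg = g.copy()
        if ph:
            gg[..., H - 1, :] += gg[..., H:, :].sum(axis=-2)
            gg = gg[..., :H, :]
        if pw:
            gg[..., :, W - 1] += gg[..., :, W:].sum(axis=-1)
            gg = gg[..., :, :W]
        x._accumulate(gg)

    return x._make(out_data, (x,), backward)


class _ConvBlock(nn.Module):
    """3x3 convolution + ReLU + batch normalization."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x).relu())


class UNet(nn.Module):
    def __init__(self, cfg: UnetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.widths()
        blocks = cfg.encoder_blocks
        if len(blocks) != cfg.n_levels:
            raise ValueError("encoder_blocks must list one count per level")
        self.enc_levels: list[list[nn.Module]] = []
        in_ch = 1
        for lvl, w in enumerate(widths):
            level = []
            for b in range(blocks[lvl]):
                blk = _ConvBlock(in_ch, w, rng)
                setattr(self, f"enc{lvl}_{b}", blk)
                level.append(blk)
                in_ch = w
            self.enc_levels.append(level)
        self.dec_ups: list[nn.Module] = []
        self.dec_convs: list[nn.Module] = []
        for lvl in range(cfg.n_levels - 2, -1, -1):
            up = nn.ConvTranspose2d(in_ch, widths[lvl], 2, rng, stride=2)
            conv = _ConvBlock(widths[lvl] * 2, widths[lvl], rng)
            setattr(self, f"up{lvl}", up)
            setattr(self, f"dec{lvl}", conv)
            self.dec_ups.append(up)
            self.dec_convs.append(conv)
            in_ch = widths[lvl]
        self.head = nn.Conv2d(in_ch, N_CLASSES, 1, rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """(N, 1, H, W) -> (N, 4, H, W) class probabilities (softmax)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        N, C, H, W = x.shape
        div = 2 ** (self.cfg.n_levels - 1)
        ph = (-H) % div
        pw = (-W) % div
        if ph or pw:
            x = _pad_rb(x, ph, pw)
        skips = []
        for lvl, level in enumerate(self.enc_levels):
            for blk in level:
                x = blk(x)
            if lvl < self.cfg.n_levels - 1:
                skips.append(x)
                x = F.max_pool2d(x, 2)
        for up, conv, skip in zip(self.dec_ups, self.dec_convs,
                                  reversed(skips)):
            x = up(x)
            x = conv(concatenate([skip, x], axis=1))
        logits = self.head(x)
        if ph or pw:
            logits = logits[:, :, :H, :W]
        return softmax(logits, axis=1)


def build_unet(cfg: UnetConfig | None = None, **kwargs) -> UNet:
    return UNet(cfg or UnetConfig(**kwargs))


def normalize_image(img: np.ndarray) -> np.ndarray:
    """Min-max normalize a single image to [-1, 1]."""
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img, dtype=np.float32)
    return (2.0 * (img - lo) / (hi - lo) - 1.0).astype(np.float32)


def segment(images: CineSequence | np.ndarray, model: UNet) -> list[SegMask]:
    """Per-frame segmentation; deterministic in eval mode."""
    frames = images.magnitude() if isinstance(images, CineSequence) \
        else np.asarray(images)
    if frames.ndim == 2:
        frames = frames[None]
    if not np.isfinite(frames).all():
        raise ValueError("non-finite input image")
    model.eval()
    batch = np.stack([normalize_image(f) for f in frames])[:, None]
    with nn.no_grad():
        probs = model(batch).data
    return [SegMask(labels=np.argmax(p, axis=0).astype(np.int16), probs=p)
            for p in probs]


def soft_dice_loss(probs: Tensor | np.ndarray, target_onehot: np.ndarray,
                   eps: float = DICE_EPS) -> Tensor:
    """1 - mean_c (2 sum pq + eps) / (sum p + sum q + eps).

    probs: (N, 4, H, W) predicted probabilities; target_onehot same shape.
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    t = np.asarray(target_onehot, dtype=np.float32)
    axes = (0, 2, 3)
    inter = (probs * Tensor(t)).sum(axis=axes)
    denom = probs.sum(axis=axes) + Tensor(t.sum(axis=axes))
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice.mean()


def generate_pseudo_labels(manual_labels: np.ndarray, flow_table,
                           source_frame: int,
                           target_frames: list[int]) -> dict[int, np.ndarray]:
    """Warp a manual label map to unlabeled frames via estimated motion.

    For target frame f, the pseudo-label is the nearest-neighbour warp of the
    source labels by flow(f, source): label_f(p) = label_src(p + u(p)).
    """
    from . import flow_ops

    out = {}
    for f in target_frames:
        if f == source_frame:
            out[f] = manual_labels.copy()
            continue
        u = flow_table.flow(f, source_frame)
        out[f] = flow_ops.warp_image(manual_labels, u, mode="nearest")
    return out


def save_checkpoint(model: UNet, path: str | Path) -> None:
    sd = model.state_dict()
    np.savez(Path(path), __config__=json.dumps(asdict(model.cfg)), **sd)


def load_checkpoint(path: str | Path) -> UNet:
    data = np.load(Path(path), allow_pickle=False)
    raw = json.loads(str(data["__config__"]))
    raw["encoder_blocks"] = tuple(raw["encoder_blocks"])
    model = UNet(UnetConfig(**raw))
    model.load_state_dict({k: data[k] for k in data.files
                           if k != "__config__"})
    return model
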