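"""Training losses and the three-stage optimization schedule.

Losses
------
* photometric: L1 between the fixed triplet and the backward/forward triplets
  warped by the current bidirectional flows;
* smoothness: L1 of the spatial finite-difference gradients of both flows,
  weighted by ``lambda1`` (default 0.04);
* registration loss: plain (undiscounted) sum of photometric + smoothness over
  all K refinement iterations;
* joint loss: registration + ``lambda2``·Dice on labeled frames +
  ``lambda3``·Dice on pseudo-labeled frames (0.05 and 0.04).

Stages run in the order registration → segmentation → joint.  In the joint
stage the motion-compensated reconstruction sits between registration and
segmentation; the solver is treated as a fixed operator (no gradients flow
through it) and its output is refreshed from the current motion estimates at
the start of the stage.  Window sampling in the joint stage always places a
labeled frame first or last in the 5-frame window, with the intermediate
frames drawn in increasing temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .containers import N_CLASSES
from .nn import functional as F
from .nn.optim import AdamW, cosine_lr
from .nn.tensor import Tensor

__all__ = ["LossConfig", "TrainConfig", "photometric_loss", "smoothness_loss",
           "registration_loss", "joint_loss", "run_training_stage",
           "sample_joint_window", "TINY_TRAIN_PROFILE"]


@dataclass
class LossConfig:
    lambda1: float = 0.04   # smoothness weight
    lambda2: float = 0.05   # Dice weight (labeled)
    lambda3: float = 0.04   # warped-Dice weight (pseudo-labels)
    K: int = 6              # iterations summed in the registration loss

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    steps: int = 1000
    seed: int = 0
    log_every: int = 50


# Desk-scale profile: far fewer steps than a full run, so the learning rate
# is raised accordingly (cosine-annealed to zero either way).
TINY_TRAIN_PROFILE = dict(batch_size=4, learning_rate=1e-3, weight_decay=5e-4)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def photometric_loss(i_fixed, i_bwd, i_fwd, u_bwd, u_fwd) -> Tensor:
    """Mean L1 between fixed frames and their motion-warped neighbours.

    Images: (N, 3, H, W) triplets (or (3, H, W)); flows: (N*3, H, W, 2).
    """
    i_fixed, i_bwd, i_fwd = map(_as_tensor, (i_fixed, i_bwd, i_fwd))
    u_bwd, u_fwd = map(_as_tensor, (u_bwd, u_fwd))
    if i_fixed.ndim == 3:
        i_fixed, i_bwd, i_fwd = (t.reshape(1, *t.shape)
                                 for t in (i_fixed, i_bwd, i_fwd))
    N, Tf, H, W = i_fixed.shape
    fx = i_fixed.reshape(N * Tf, 1, H, W)
    bw = i_bwd.reshape(N * Tf, 1, H, W)
    fw = i_fwd.reshape(N * Tf, 1, H, W)
    warped_b = F.warp(bw, u_bwd.reshape(N * Tf, H, W, 2))
    warped_f = F.warp(fw, u_fwd.reshape(N * Tf, H, W, 2))
    return (fx - warped_b).abs().mean() + (fx - warped_f).abs().mean()


def smoothness_loss(u_bwd, u_fwd) -> Tensor:
    """Mean L1 of spatial forward differences of both flow fields."""
    total = None
    for u in (u_bwd, u_fwd):
        u = _as_tensor(u)
        if u.ndim == 3:
            u = u.reshape(1, *u.shape)
        dr = (u[:, 1:, :, :] - u[:, :-1, :, :]).abs().mean()
        dc = (u[:, :, 1:, :] - u[:, :, :-1, :]).abs().mean()
        term = dr + dc
        total = term if total is None else total + term
    return total * 0.5


def registration_loss(snapshots: Sequence[tuple], i_fixed, i_bwd, i_fwd,
                      cfg: LossConfig) -> Tensor:
    """Unweighted sum over refinement iterations of photometric + λ1·smooth."""
    if len(snapshots) != cfg.K:
        raise ValueError(f"expected {cfg.K} flow snapshots, got {len(snapshots)}")
    loss = None
    for (u_bwd, u_fwd) in snapshots:
        term = photometric_loss(i_fixed, i_bwd, i_fwd, u_bwd, u_fwd) \
            + cfg.lambda1 * smoothness_loss(u_bwd, u_fwd)
        loss = term if loss is None else loss + term
    return loss


def joint_loss(reg: Tensor | float, dice_labeled: Tensor | float,
               dice_warp: Tensor | float, cfg: LossConfig) -> Tensor:
    """reg + λ2·Dice(labeled) + λ3·Dice(pseudo-labeled)."""
    return _as_tensor(reg) + cfg.lambda2 * _as_tensor(dice_labeled) \
        + cfg.lambda3 * _as_tensor(dice_warp)


def sample_joint_window(rng: np.random.Generator, labeled_frames: Sequence[int],
                        n_frames: int) -> tuple[list[int], int, int]:
    """A 5-frame window with a labeled frame first or last.

    Returns (window indices, labeled frame, its position 0 or 4).  The three
    intermediate frames are drawn without replacement between the endpoints
    and sorted (increasing temporal order).
    """
    lab = int(rng.choice(list(labeled_frames)))
    as_first = bool(rng.integers(2))
    span = int(rng.integers(4, max(4, n_frames // 2) + 1))  # window extent
    if span > 4:
        offs = sorted(int(o) for o in
                      rng.choice(np.arange(1, span), size=3, replace=False))
    else:
        offs = [1, 2, 3]
    if as_first:
        window = [lab] + [(lab + o) % n_frames for o in offs] \
            + [(lab + span) % n_frames]
        return window, lab, 0
    window = [(lab - span) % n_frames] \
        + [(lab - o) % n_frames for o in reversed(offs)] + [lab]
    return window, lab, 4


@dataclass
class StageResult:
    model: object
    log: list[dict] = field(default_factory=list)


# Temporal strides of the sampled training windows.  Larger offsets carry
# motion well above the sub-pixel photometric ambiguity at desk-scale image
# sizes; strides 3-5 span up to a full half-cycle within one window.
REG_WINDOW_STRIDES = (3, 4, 5)


def _reg_batch(rng, sequences, batch_size, n_frames_each,
               strides=REG_WINDOW_STRIDES):
    """Random cyclic 5-frame windows at the configured temporal strides."""
    batch = []
    for _ in range(batch_size):
        s = int(rng.integers(len(sequences)))
        T = n_frames_each[s]
        stride = int(strides[int(rng.integers(len(strides)))])
        start = int(rng.integers(T))
        idx = [(start + k * stride) % T for k in range(5)]
        batch.append(sequences[s][idx])
    return np.stack(batch)


def run_training_stage(stage: str, data: dict, train_cfg: TrainConfig,
                       loss_cfg: LossConfig | None = None,
                       models: dict | None = None) -> StageResult:
    """Run one optimization stage; returns the trained model and a loss log.

    ``data`` keys by stage:
      registration: sequences -> list of (T, H, W) arrays
      segmentation: images -> (N, H, W), onehot -> (N, 4, H, W)
      joint:        sequences, labels (list of (T, H, W) int),
                    labeled_frames (list of frame-index lists),
                    recon_images (list of (T, H, W)) — reconstructed inputs
    ``models``: {'mopnet': Mopnet} and/or {'unet': UNet} as required.
    """
    from .mopnet import Mopnet  # noqa: F401  (type reference)
    from .unet import normalize_image, soft_dice_loss

    loss_cfg = loss_cfg or LossConfig()
    models = models or {}
    rng = np.random.default_rng(train_cfg.seed)
    log: list[dict] = []

    if stage == "registration":
        model = models["mopnet"]
        model.train()
        opt = AdamW(model.parameters(), lr=train_cfg.learning_rate,
                    weight_decay=train_cfg.weight_decay)
        seqs = [np.stack([normalize_image(f) for f in s])
                for s in data["sequences"]]
        n_frames = [s.shape[0] for s in seqs]
        lcfg = LossConfig(lambda1=loss_cfg.lambda1, K=model.cfg.K)
        for step in range(train_cfg.steps):
            frames = _reg_batch(rng, seqs, train_cfg.batch_size, n_frames)
            out = model(frames, keep_snapshots=True)
            loss = registration_loss(out["snapshots"], frames[:, 1:4],
                                     frames[:, 0:3], frames[:, 2:5], lcfg)
            opt.zero_grad()
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"NaN loss at step {step}")
            opt.clip_grad_norm(1.0)
            opt.step(lr=cosine_lr(train_cfg.learning_rate, step,
                                  train_cfg.steps))
            if step % train_cfg.log_every == 0 or step == train_cfg.steps - 1:
                log.append({"step": step, "loss": float(loss.data)})
        return StageResult(model=model, log=log)

    if stage == "segmentation":
        model = models["unet"]
        model.train()
        opt = AdamW(model.parameters(), lr=train_cfg.learning_rate,
                    weight_decay=train_cfg.weight_decay)
        images = data["images"]
        onehot = data["onehot"]
        n = images.shape[0]
        for step in range(train_cfg.steps):
            idx = rng.choice(n, size=min(train_cfg.batch_size, n),
                             replace=False)
            x = np.stack([normalize_image(images[i]) for i in idx])[:, None]
            probs = model(x)
            loss = soft_dice_loss(probs, onehot[idx])
            opt.zero_grad()
            loss.backward()
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"NaN loss at step {step}")
            opt.clip_grad_norm(1.0)
            opt.step(lr=cosine_lr(train_cfg.learning_rate, step,
                                  train_cfg.steps))
            if step % train_cfg.log_every == 0 or step == train_cfg.steps - 1:
                log.append({"step": step, "loss": float(loss.data)})
        return StageResult(model=model, log=log)

    if stage == "joint":
        return _run_joint_stage(data, train_cfg, loss_cfg, models, rng, log)

    raise ValueError(f"unknown stage '{stage}'")


def _run_joint_stage(data, train_cfg, loss_cfg, models, rng, log):
    from .unet import normalize_image, soft_dice_loss

    mopnet = models["mopnet"]
    unet = models["unet"]
    seq_raw = data["recon_images"]
    seqs = [np.stack([normalize_image(f) for f in s]) for s in seq_raw]
    labels = data["labels"]
    labeled_frames = data["labeled_frames"]
    pseudo = data.get("pseudo_labels")  # list of {frame: (H, W) labels}
    params = mopnet.parameters() + unet.parameters()
    opt = AdamW(params, lr=train_cfg.learning_rate,
                weight_decay=train_cfg.weight_decay)
    mopnet.train()
    unet.train()
    lcfg = LossConfig(lambda1=loss_cfg.lambda1, lambda2=loss_cfg.lambda2,
                      lambda3=loss_cfg.lambda3, K=mopnet.cfg.K)
    for step in range(train_cfg.steps):
        frames_b, lab_imgs, lab_oh, ps_imgs, ps_oh = [], [], [], [], []
        for _ in range(train_cfg.batch_size):
            s = int(rng.integers(len(seqs)))
            T = seqs[s].shape[0]
            window, lab, pos = sample_joint_window(rng, labeled_frames[s], T)
            frames_b.append(seqs[s][window])
            lab_imgs.append(seqs[s][lab])
            lab_oh.append(_onehot(labels[s][lab]))
            if pseudo is not None:
                inner = window[1:4]
                f = inner[int(rng.integers(3))]
                if f in pseudo[s]:
                    ps_imgs.append(seqs[s][f])
                    p = np.asarray(pseudo[s][f])
                    # hard label map or already-soft (4, H, W) target
                    ps_oh.append(_onehot(p) if p.ndim == 2 else p)
        frames = np.stack(frames_b)
        out = mopnet(frames, keep_snapshots=True)
        reg = registration_loss(out["snapshots"], frames[:, 1:4],
                                frames[:, 0:3], frames[:, 2:5], lcfg)
        probs_lab = unet(np.stack(lab_imgs)[:, None])
        dice_lab = soft_dice_loss(probs_lab, np.stack(lab_oh))
        if ps_imgs:
            probs_ps = unet(np.stack(ps_imgs)[:, None])
            dice_ps = soft_dice_loss(probs_ps, np.stack(ps_oh))
        else:
            dice_ps = Tensor(np.zeros(()))
        loss = joint_loss(reg, dice_lab, dice_ps, lcfg)
        opt.zero_grad()
        loss.backward()
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"NaN loss at step {step}")
        opt.clip_grad_norm(1.0)
        opt.step(lr=cosine_lr(train_cfg.learning_rate, step, train_cfg.steps))
        if step % train_cfg.log_every == 0 or step == train_cfg.steps - 1:
            log.append({"step": step, "loss": float(loss.data),
                        "reg": float(reg.data), "dice": float(dice_lab.data),
                        "dice_warp": float(dice_ps.data)})
    return StageResult(model={"mopnet": mopnet, "unet": unet}, log=log)


def _onehot(lab: np.ndarray) -> np.ndarray:
    oh = np.zeros((N_CLASSES,) + lab.shape, dtype=np.float32)
    for c in range(N_CLASSES):
        oh[c] = lab == c
    return oh
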