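"""Multi-frame recurrent registration network with temporal motion propagation.

The model follows a tri-frame optical-flow layout.  Five consecutive frames
``I1..I5`` form three overlapping triplets — backward ``(I1, I2, I3)``, fixed
``(I2, I3, I4)`` and forward ``(I3, I4, I5)``.  The network matches each fixed
frame to its temporal neighbours in both directions and returns two dense
displacement sets ``ubwd``/``ufwd`` of shape ``(3, H, W, 2)``:
``ufwd[m] = flow(fixed[m], fwd[m])`` (each fixed frame to its successor) and
``ubwd[m] = flow(fixed[m], bwd[m])`` (to its predecessor).

Pipeline per refinement iteration:

1. all-pairs dot-product correlation volumes (one per direction) with an
   average-pooled pyramid, looked up in a window around the flow-displaced
   position;
2. motion propagation: per-triplet hidden motion states are warped into the
   fixed frame's domain by the current flow estimates, concatenated, and
   re-encoded, so temporal context accumulates across iterations;
3. a convolutional GRU decodes residual bidirectional flows, which are
   accumulated from a zero initialization (so zero iterations mean exactly
   zero flow) and upsampled to full resolution.

A self-attention map computed from the context features aggregates motion
features globally before the GRU, which helps distinguish coherent cardiac
motion from incoherent aliasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .containers import CineSequence
from .nn import functional as F
from .nn.tensor import Tensor, concatenate, softmax

__all__ = ["MopnetConfig", "TriFrameGroups", "FlowPair", "Mopnet",
           "build_tri_frame_groups", "estimate_motion", "full_cycle_inference",
           "FlowTable", "save_checkpoint", "load_checkpoint", "TINY_PROFILE",
           "DEFAULT_PROFILE"]


@dataclass
class MopnetConfig:
    K: int = 6                      # refinement iterations
    feature_downsample: int = 8     # power of two
    feature_channels: int = 64
    context_channels: int = 64      # split into GRU init + context input
    hidden_channels: int = 64       # motion state / GRU hidden width
    corr_levels: int = 4
    corr_radius: int = 4
    superkernel_size: int = 7
    attention_channels: int = 16
    max_corr_grid: int = 64         # memory guard on the feature grid side
    seed: int = 0

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be >= 0")
        ds = self.feature_downsample
        if ds < 1 or (ds & (ds - 1)) != 0:
            raise ValueError("feature_downsample must be a power of two")


TINY_PROFILE = dict(K=4, feature_downsample=4, feature_channels=16,
                    context_channels=16, hidden_channels=16, corr_levels=2,
                    corr_radius=3, superkernel_size=7, attention_channels=8)
DEFAULT_PROFILE = dict()


@dataclass
class TriFrameGroups:
    bwd: np.ndarray    # (3, H, W) = (I1, I2, I3)
    fixed: np.ndarray  # (3, H, W) = (I2, I3, I4)
    fwd: np.ndarray    # (3, H, W) = (I3, I4, I5)


@dataclass
class FlowPair:
    """Bidirectional estimates at full resolution, (3, H, W, 2), pixel units."""

    ubwd: np.ndarray
    ufwd: np.ndarray
    snapshots: list = field(default_factory=list)  # per-iteration (ubwd, ufwd)


def build_tri_frame_groups(frames: np.ndarray) -> TriFrameGroups:
    """Slice 5 frames into the three overlapping triplets."""
    frames = np.asarray(frames)
    if frames.shape[0] != 5:
        raise ValueError(f"exactly 5 frames required, got {frames.shape[0]}")
    return TriFrameGroups(bwd=frames[0:3], fixed=frames[1:4], fwd=frames[2:5])


class SuperKernelBlock(nn.Module):
    """Large-receptive-field block: depth-wise k x k convolution, point-wise
    mixing, and a funneling 1x1 skip projection."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng):
        super().__init__()
        self.dw = nn.Conv2d(in_ch, in_ch, k, rng, groups=in_ch)
        self.pw = nn.Conv2d(in_ch, out_ch, 1, rng)
        self.skip = nn.Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, x):
        return (self.pw(self.dw(x)) + self.skip(x)).relu()


class Encoder(nn.Module):
    """Strided convolutional encoder shared by all triplets (temporal axis
    folded into the batch axis before 2D convolution)."""

    def __init__(self, out_ch: int, n_down: int, rng):
        super().__init__()
        chans = [max(out_ch // 2 ** (n_down - 1 - i), 4) for i in range(n_down)]
        layers = []
        prev = 1
        for c in chans:
            layers.append(nn.Conv2d(prev, c, 3, rng, stride=2))
            layers.append(nn.InstanceNorm2d(c))
            layers.append(nn.ReLU())
            prev = c
        layers.append(nn.Conv2d(prev, out_ch, 1, rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        return self.net(x)


class Mopnet(nn.Module):
    """The registration network; processes (B, 5, H, W) frame stacks."""

    def __init__(self, cfg: MopnetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        n_down = int(np.log2(cfg.feature_downsample))
        C = cfg.feature_channels
        Ch = cfg.hidden_channels
        Cc = cfg.context_channels
        self.fnet = Encoder(C, n_down, rng)
        self.cnet = Encoder(Cc + Ch, n_down, rng)
        self.wq = nn.Conv2d(Cc, cfg.attention_channels, 1, rng)
        self.wk = nn.Conv2d(Cc, cfg.attention_channels, 1, rng)
        n_look = 2 * cfg.corr_levels * (2 * cfg.corr_radius + 1) ** 2
        self.corr_enc = SuperKernelBlock(n_look, Ch, cfg.superkernel_size, rng)
        self.flow_enc = SuperKernelBlock(4, Ch, cfg.superkernel_size, rng)
        self.mop_enc = SuperKernelBlock(3 * Ch, Ch, cfg.superkernel_size, rng)
        self.motion_enc = nn.Conv2d(3 * Ch, 2 * Ch, 3, rng)
        self.gru = nn.ConvGRUCell(Ch, 2 * Ch + Cc, rng)
        self.flow_head = nn.Sequential(
            nn.Conv2d(Ch, Ch, 3, rng), nn.ReLU(),
            nn.Conv2d(Ch, 4, 3, rng, zero_init=True))
        self._minit_rng_seed = cfg.seed + 1

    # ------------------------------------------------------------------ parts
    def extract_features(self, groups_b: np.ndarray):
        """groups_b: (B, 3 groups, 3 frames, H, W) -> feature dict.

        The shared encoder sees every frame of every triplet as one batch
        entry; the context encoder runs on the fixed triplet only.
        """
        B, G, Tf, H, W = groups_b.shape
        x = Tensor(groups_b.reshape(B * G * Tf, 1, H, W))
        feats = self.fnet(x)
        h, w = feats.shape[-2:]
        feats = feats.reshape(B, G, Tf, -1, h, w)
        ctx_raw = self.cnet(Tensor(groups_b[:, 1].reshape(B * Tf, 1, H, W)))
        Cc = self.cfg.context_channels
        ctx = ctx_raw[:, :Cc].relu()
        h_init = ctx_raw[:, Cc:].tanh()
        q = self.wq(ctx).reshape(B * Tf, self.cfg.attention_channels, h * w)
        k = self.wk(ctx).reshape(B * Tf, self.cfg.attention_channels, h * w)
        att = softmax((q.transpose(0, 2, 1) @ k)
                      * (1.0 / np.sqrt(self.cfg.attention_channels)), axis=-1)
        return feats, ctx, h_init, att

    @staticmethod
    def build_correlation_volumes(f_fixed: Tensor, f_target: Tensor,
                                  n_levels: int, max_grid: int = 64):
        """All-pairs scaled dot products per matched frame, with a pyramid.

        f_fixed, f_target: (N, C, h, w).  Level 0 is (N, h, w, h, w); deeper
        levels average-pool the last two (target) dimensions.
        """
        N, C, h, w = f_fixed.shape
        if max(h, w) > max_grid:
            raise MemoryError(
                f"correlation grid {h}x{w} exceeds the configured limit "
                f"({max_grid}); increase feature_downsample")
        a = f_fixed.reshape(N, C, h * w).transpose(0, 2, 1)   # (N, hw, C)
        b = f_target.reshape(N, C, h * w)                     # (N, C, hw)
        corr = (a @ b) * (1.0 / np.sqrt(C))
        corr = corr.reshape(N, h, w, h, w)
        pyramid = [corr]
        for _ in range(n_levels - 1):
            pyramid.append(F.avg_pool2d(pyramid[-1], 2))
        return pyramid

    @staticmethod
    def lookup_correlation(pyramid: list[Tensor], flow: Tensor,
                           radius: int) -> Tensor:
        """Gather (2r+1)^2 windows at every level around p + flow(p).

        flow: (N, h, w, 2) at feature resolution; returns
        (N, L*(2r+1)^2, h, w).  Out-of-volume entries are edge-clamped.
        """
        N, h, w, _ = flow.shape
        rr, cc = np.meshgrid(np.arange(h, dtype=np.float32),
                             np.arange(w, dtype=np.float32), indexing="ij")
        base = Tensor(np.broadcast_to(np.stack([rr, cc], -1), flow.shape).copy())
        centers = (base + flow).reshape(N * h * w, 1, 2)
        dy, dx = np.meshgrid(np.arange(-radius, radius + 1),
                             np.arange(-radius, radius + 1), indexing="ij")
        offsets = np.stack([dy, dx], -1).reshape(1, -1, 2).astype(np.float32)
        P = offsets.shape[1]
        out = []
        for lvl, corr in enumerate(pyramid):
            hl, wl = corr.shape[-2:]
            vol = corr.reshape(N * h * w, 1, hl, wl)
            pos = centers * (1.0 / 2**lvl) + Tensor(offsets)
            sampled = F.sample_points(vol, pos)          # (Nhw, 1, P)
            out.append(sampled.reshape(N, h, w, P))
        stacked = concatenate(out, axis=-1)              # (N, h, w, L*P)
        return stacked.transpose(0, 3, 1, 2)

    def mop_update(self, states: dict, flow_bwd: Tensor, flow_fwd: Tensor,
                   f_corr: Tensor, f_flow: Tensor):
        """Warp neighbour motion states into the fixed domain, fuse, update.

        Returns the motion features; mutates ``states`` in place (the warped
        states become the next iteration's forward/backward states).
        """
        m_plus = F.warp(states["fwd"], flow_fwd)
        m_minus = F.warp(states["bwd"], flow_bwd)
        f_mop = self.mop_enc(concatenate([states["fixed"], m_plus, m_minus],
                                         axis=1))
        fused = self.motion_enc(concatenate([f_corr, f_flow, f_mop], axis=1))
        Ch = self.cfg.hidden_channels
        states["fixed"] = fused[:, :Ch].tanh()
        f_motion = fused[:, Ch:].relu()
        states["fwd"] = m_plus
        states["bwd"] = m_minus
        return f_motion

    # ---------------------------------------------------------------- forward
    def forward(self, frames: np.ndarray, K: int | None = None,
                keep_snapshots: bool = False):
        """frames: (B, 5, H, W) -> dict with accumulated full-res flows.

        Residual flows accumulate from zero, so K=0 returns exactly zero.
        """
        frames = np.asarray(frames, dtype=np.float32)
        if frames.ndim == 3:
            frames = frames[None]
        B, T5, H, W = frames.shape
        if T5 != 5:
            raise ValueError("expected 5 frames")
        cfg = self.cfg
        K = cfg.K if K is None else K
        ds = cfg.feature_downsample
        groups_b = np.stack([frames[:, 0:3], frames[:, 1:4], frames[:, 2:5]],
                            axis=1)  # (B, 3, 3, H, W)
        snapshots: list[tuple[Tensor, Tensor]] = []
        N = B * 3
        h, w = H // ds, W // ds
        zero_full = Tensor(np.zeros((N, H, W, 2), dtype=np.float32))
        if K == 0:
            return {"ubwd": zero_full, "ufwd": zero_full, "snapshots": snapshots}

        feats, ctx, h_init, att = self.extract_features(groups_b)
        f_bwd = feats[:, 0].reshape(N, -1, h, w)
        f_fixed = feats[:, 1].reshape(N, -1, h, w)
        f_fwd = feats[:, 2].reshape(N, -1, h, w)
        pyr_bwd = self.build_correlation_volumes(f_fixed, f_bwd,
                                                 cfg.corr_levels,
                                                 cfg.max_corr_grid)
        pyr_fwd = self.build_correlation_volumes(f_fixed, f_fwd,
                                                 cfg.corr_levels,
                                                 cfg.max_corr_grid)
        minit_rng = np.random.default_rng(self._minit_rng_seed)
        minit = Tensor(minit_rng.standard_normal(
            (1, cfg.hidden_channels, h, w)).astype(np.float32)
            * np.ones((N, 1, 1, 1), dtype=np.float32))
        states = {"fixed": minit, "fwd": minit, "bwd": minit}
        hidden = h_init
        flow_bwd = Tensor(np.zeros((N, h, w, 2), dtype=np.float32))
        flow_fwd = Tensor(np.zeros((N, h, w, 2), dtype=np.float32))
        for _ in range(K):
            look_b = self.lookup_correlation(pyr_bwd, flow_bwd, cfg.corr_radius)
            look_f = self.lookup_correlation(pyr_fwd, flow_fwd, cfg.corr_radius)
            f_corr = self.corr_enc(concatenate([look_b, look_f], axis=1))
            flow_feat = concatenate(
                [flow_bwd.transpose(0, 3, 1, 2), flow_fwd.transpose(0, 3, 1, 2)],
                axis=1)
            f_flow = self.flow_enc(flow_feat)
            f_motion = self.mop_update(states, flow_bwd, flow_fwd, f_corr,
                                       f_flow)
            fm_flat = f_motion.reshape(N, -1, h * w)
            f_agg = (fm_flat @ att.transpose(0, 2, 1)).reshape(f_motion.shape)
            gru_in = concatenate([f_motion, f_agg, ctx], axis=1)
            hidden = self.gru(hidden, gru_in)
            delta = self.flow_head(hidden)               # (N, 4, h, w)
            flow_bwd = flow_bwd + delta[:, 0:2].transpose(0, 2, 3, 1)
            flow_fwd = flow_fwd + delta[:, 2:4].transpose(0, 2, 3, 1)
            if keep_snapshots:
                snapshots.append((self._upsample_flow(flow_bwd, ds, H, W),
                                  self._upsample_flow(flow_fwd, ds, H, W)))
        return {"ubwd": self._upsample_flow(flow_bwd, ds, H, W),
                "ufwd": self._upsample_flow(flow_fwd, ds, H, W),
                "snapshots": snapshots}

    @staticmethod
    def _upsample_flow(flow: Tensor, ds: int, H: int, W: int) -> Tensor:
        f = flow.transpose(0, 3, 1, 2)
        up = F.upsample_bilinear(f, ds) * float(ds)
        return up[:, :, :H, :W].transpose(0, 2, 3, 1)


def estimate_motion(frames: np.ndarray, model: Mopnet,
                    K: int | None = None) -> FlowPair:
    """Run the network on one 5-frame sequence and return numpy flows."""
    frames = np.asarray(frames, dtype=np.float32)
    if not np.isfinite(frames).all():
        raise ValueError("non-finite input frames")
    model.eval()
    with nn.no_grad():
        out = model(frames[None], K=K)
    ub = out["ubwd"].data.reshape(3, *frames.shape[1:], 2)
    uf = out["ufwd"].data.reshape(3, *frames.shape[1:], 2)
    if not (np.isfinite(ub).all() and np.isfinite(uf).all()):
        raise FloatingPointError("non-finite flow activations")
    return FlowPair(ubwd=ub, ufwd=uf)


class FlowTable:
    """Frame-pair flow store with composition to a reference frame."""

    def __init__(self, n_frames: int):
        self.n_frames = n_frames
        self.flows: dict[tuple[int, int], np.ndarray] = {}

    def add(self, i: int, j: int, u: np.ndarray) -> bool:
        if (i, j) in self.flows:
            return False
        self.flows[(i, j)] = u
        return True

    def pairs(self) -> list[tuple[int, int]]:
        return list(self.flows.keys())

    def flow(self, i: int, j: int) -> np.ndarray:
        """flow(i, j), composing along the shortest stored path if needed."""
        from collections import deque

        from . import flow_ops

        if i == j:
            shape = next(iter(self.flows.values())).shape
            return np.zeros(shape, dtype=np.float32)
        if (i, j) in self.flows:
            return self.flows[(i, j)]
        # BFS over stored directed edges (a -> b meaning flow(a, b) exists)
        prev: dict[int, tuple[int, tuple[int, int]]] = {}
        seen = {i}
        dq = deque([i])
        while dq:
            a = dq.popleft()
            if a == j:
                break
            for (p, q) in self.flows:
                if p == a and q not in seen:
                    seen.add(q)
                    prev[q] = (a, (p, q))
                    dq.append(q)
        if j not in seen:
            raise KeyError(f"no flow path from {i} to {j}")
        path = []
        node = j
        while node != i:
            a, edge = prev[node]
            path.append(edge)
            node = a
        path.reverse()
        u = self.flows[path[0]]
        for edge in path[1:]:
            # chain: f_ik = compose(f_jk, f_ij)
            u = flow_ops.compose_flows(self.flows[edge], u)
        return u

    def to_reference(self, reference: int) -> np.ndarray:
        """(T, H, W, 2) array of flow(t, reference) for every t."""
        return np.stack([self.flow(t, reference)
                         for t in range(self.n_frames)])


def plan_windows(T: int, max_stride: int = 5) -> list[tuple[int, int]]:
    """Sliding-window schedule: (start, stride) windows over the cyclic cycle.

    For each stride 1..max_stride (progressively increased, capped so a
    window never wraps past a full cycle), window starts advance by 3 fixed
    frames until every cyclic pair at that temporal offset is covered.  Pair
    emission is deduplicated by the caller, so each frame pair is produced
    exactly once.  Long-offset mappings then compose from a handful of
    large-stride direct estimates instead of many small hops.
    """
    if T < 5:
        raise ValueError("full-cycle inference needs at least 5 frames")
    windows = []
    for stride in range(1, min(max_stride, (T - 1) // 4) + 1):
        covered: set[int] = set()
        for start in range(T):           # greedy: skip redundant windows
            firsts = [(start + (1 + m) * stride) % T for m in range(3)]
            if any(f not in covered for f in firsts):
                windows.append((start, stride))
                covered.update(firsts)
            if len(covered) == T:
                break
    return windows


def full_cycle_inference(sequence: CineSequence | np.ndarray, model: Mopnet,
                         K: int | None = None) -> FlowTable:
    """Estimate a complete frame-to-frame mapping over the cyclic sequence.

    Only the forward estimates of each window are used; each frame pair is
    emitted once.  Missing pairs are obtained by composition along stored
    edges (the cyclic forward chain guarantees reachability).
    """
    frames = sequence.frames if isinstance(sequence, CineSequence) \
        else np.asarray(sequence)
    T = frames.shape[0]
    table = FlowTable(T)
    for start, stride in plan_windows(T):
        idx = [(start + m * stride) % T for m in range(5)]
        pair = estimate_motion(frames[idx], model, K=K)
        for m in range(3):
            i, j = idx[1 + m], idx[2 + m]
            if (i, j) not in table.flows and i != j:
                table.add(i, j, pair.ufwd[m])
    return table


def save_checkpoint(model: Mopnet, path: str | Path) -> None:
    path = Path(path)
    sd = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.cfg)), **sd)


def load_checkpoint(path: str | Path) -> Mopnet:
    data = np.load(Path(path), allow_pickle=False)
    cfg = MopnetConfig(**json.loads(str(data["__config__"])))
    model = Mopnet(cfg)
    model.load_state_dict({k: data[k] for k in data.files
                           if k != "__config__"})
    return model
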