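"""Synthetic 2D+t cardiac cine phantom with analytically known ground truth.

The phantom emulates a short-axis slice: a bright LV blood pool inside a
contracting myocardial annulus, an adjacent crescent-shaped RV blood pool,
and a static background.  The deformation is radially organised around the
LV centre and chosen so that its forward map, inverse map and Green–Lagrange
strain are all closed form:

* LV blood pool (``r <= r_endo``): uniform radial scaling matching the
  endocardial boundary (blood leaves the slice, so in-plane area shrinks).
* Myocardium and a margin beyond (``r_endo < r <= a``): area-preserving
  (incompressible) map ``r' = sqrt(r^2 - delta(t))`` — the wall thickens as
  it contracts, giving positive radial and negative circumferential strain,
  as in real systole.
* Transition band (``a < r < b``): the area deficit tapers linearly to zero,
  which keeps the inverse a quadratic root.
* Beyond ``b``: identity (static background).

A rigid rotation (twist) with the same taper is superposed; rotation does not
contribute to Green–Lagrange strain inside the uniformly rotating core.  The
temporal profile is ``alpha(t) = alpha_max (1 - cos(2 pi t / T)) / 2`` so frame
0 is end-diastole and frame ``T//2`` end-systole.

Intensity model: piecewise-constant tissue intensities with anti-aliased
(smoothstep) boundaries, a low-frequency material texture that advects with
the tissue, a static multiplicative bias field, and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .containers import (LABEL_LV_POOL, LABEL_MYOCARDIUM, LABEL_RV_POOL,
                         CineSequence, KSpaceBundle, VolumeCurve)
from .forward_model import fft2c

__all__ = [
    "PhantomConfig", "PhantomGroundTruth", "AnnulusDeformation",
    "generate_cine_phantom", "generate_coil_maps", "generate_kt_mask",
    "simulate_kspace", "generate_slice_stack",
]


@dataclass
class PhantomConfig:
    grid_size: tuple[int, int] = (64, 64)
    n_frames: int = 25
    pixel_spacing: tuple[float, float] = (1.9, 1.9)   # mm
    slice_thickness: float = 8.0                       # mm
    n_slices: int = 1
    contraction_amplitude: float = 0.35  # peak endocardial radial shrink
    rotation_amplitude: float = 0.08     # peak twist, radians
    noise_sigma: float = 0.01            # image-domain noise, relative
    texture_amplitude: float = 0.15      # material texture contrast
    bias_amplitude: float = 0.15         # static receive-bias modulation
    n_coils: int = 8
    dt: float = 40.0                     # ms per cardiac phase
    seed: int = 0
    slice_taper: float = 0.5             # apex radius shrink across the stack

    def __post_init__(self):
        H, W = self.grid_size
        if H < 32 or W < 32:
            raise ValueError("grid_size must be at least 32 in each dimension")
        if not (0.0 <= self.contraction_amplitude < 0.5):
            raise ValueError(
                "contraction_amplitude must lie in [0, 0.5): the endocardium "
                "would cross itself at larger amplitudes")
        if self.n_frames < 5:
            raise ValueError("n_frames must be at least 5")


class AnnulusDeformation:
    """Closed-form deformation of the phantom (maps, inverse, strain).

    ``forward(points, t)`` maps material (frame-0) positions to frame ``t``;
    ``inverse`` is its exact inverse.  Points are (N, 2) arrays in pixel
    coordinates (row, col).
    """

    def __init__(self, center: np.ndarray, r_endo: float, a: float, b: float,
                 alpha_max: float, phi_max: float, n_frames: int):
        self.center = np.asarray(center, dtype=np.float64)
        self.r_endo = r_endo
        self.a = a
        self.b = b
        self.alpha_max = alpha_max
        self.phi_max = phi_max
        self.n_frames = n_frames

    # temporal profiles -----------------------------------------------------
    def alpha(self, t: float) -> float:
        return self.alpha_max * 0.5 * (1 - np.cos(2 * np.pi * t / self.n_frames))

    def phi(self, t: float) -> float:
        return self.phi_max * 0.5 * (1 - np.cos(2 * np.pi * t / self.n_frames))

    def delta(self, t: float) -> float:
        """Area deficit 2·alpha − alpha² of the endocardial disk."""
        al = self.alpha(t)
        return self.r_endo**2 * (2 * al - al**2)

    @property
    def es_frame(self) -> int:
        return self.n_frames // 2

    # radial maps -----------------------------------------------------------
    def _radius_forward(self, r: np.ndarray, t: float) -> np.ndarray:
        d = self.delta(t)
        if d == 0:
            return r.copy()
        a, b = self.a, self.b
        lam = np.sqrt(max(self.r_endo**2 - d, 1e-12)) / self.r_endo
        out = r.copy()
        core = r <= self.r_endo
        out[core] = r[core] * lam
        mid = (r > self.r_endo) & (r <= a)
        out[mid] = np.sqrt(r[mid] ** 2 - d)
        taper = (r > a) & (r < b)
        out[taper] = np.sqrt(r[taper] ** 2 - d * (b - r[taper]) / (b - a))
        return out

    def _radius_inverse(self, rp: np.ndarray, t: float) -> np.ndarray:
        d = self.delta(t)
        if d == 0:
            return rp.copy()
        a, b = self.a, self.b
        lam = np.sqrt(max(self.r_endo**2 - d, 1e-12)) / self.r_endo
        out = rp.copy()
        core = rp <= self.r_endo * lam
        out[core] = rp[core] / lam
        r_a = np.sqrt(a**2 - d)
        mid = (rp > self.r_endo * lam) & (rp <= r_a)
        out[mid] = np.sqrt(rp[mid] ** 2 + d)
        taper = (rp > r_a) & (rp < b)
        # r^2 + (d/(b-a)) r - (rp^2 + d b/(b-a)) = 0
        q = d / (b - a)
        out[taper] = -0.5 * q + np.sqrt(0.25 * q**2 + rp[taper] ** 2 + q * b)
        return out

    def _rot_weight(self, r: np.ndarray) -> np.ndarray:
        w = np.clip((self.b - r) / (self.b - self.a), 0.0, 1.0)
        w[r <= self.a] = 1.0
        return w

    def _is_identity(self, t: float) -> bool:
        return self.delta(t) == 0 and self.phi(t) == 0

    # point maps ------------------------------------------------------------
    def forward(self, points: np.ndarray, t: float) -> np.ndarray:
        if self._is_identity(t):
            return np.asarray(points, dtype=np.float64).copy()
        rel = np.asarray(points, dtype=np.float64) - self.center
        r = np.hypot(rel[..., 0], rel[..., 1])
        th = np.arctan2(rel[..., 0], rel[..., 1])
        rp = self._radius_forward(r.ravel(), t).reshape(r.shape)
        thp = th + self.phi(t) * self._rot_weight(r.ravel()).reshape(r.shape)
        out = np.empty_like(rel)
        out[..., 0] = rp * np.sin(thp)
        out[..., 1] = rp * np.cos(thp)
        return out + self.center

    def inverse(self, points: np.ndarray, t: float) -> np.ndarray:
        if self._is_identity(t):
            return np.asarray(points, dtype=np.float64).copy()
        rel = np.asarray(points, dtype=np.float64) - self.center
        rp = np.hypot(rel[..., 0], rel[..., 1])
        thp = np.arctan2(rel[..., 0], rel[..., 1])
        r = self._radius_inverse(rp.ravel(), t).reshape(rp.shape)
        th = thp - self.phi(t) * self._rot_weight(r.ravel()).reshape(rp.shape)
        out = np.empty_like(rel)
        out[..., 0] = r * np.sin(th)
        out[..., 1] = r * np.cos(th)
        return out + self.center

    # analytic strain -------------------------------------------------------
    def strain_rr_cc(self, r: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Closed-form Green–Lagrange Err/Ecc at material radius ``r``
        (valid in the incompressible band ``r_endo < r <= a``)."""
        d = self.delta(t)
        err = d / (2.0 * (r**2 - d))
        ecc = -d / (2.0 * r**2)
        return err, ecc


@dataclass
class PhantomGroundTruth:
    images: CineSequence
    labels: np.ndarray                  # (T, H, W) int
    deformation: AnnulusDeformation
    true_volumes: VolumeCurve
    config: PhantomConfig
    noise_free: np.ndarray = None       # (T, H, W) noise-free images

    def true_flow(self, i: int, j: int) -> np.ndarray:
        """flow(i, j): warping frame j backward by it reproduces frame i."""
        H, W = self.images.shape
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        pts = np.stack([rr, cc], axis=-1).astype(np.float64)
        material = self.deformation.inverse(pts, i)
        target = self.deformation.forward(material, j)
        return (target - pts).astype(np.float32)

    def flow_to_reference(self, reference: int = 0) -> np.ndarray:
        """(T, H, W, 2) table of flow(t, reference) for every frame t."""
        T = self.images.n_frames
        return np.stack([self.true_flow(t, reference) for t in range(T)])

    @property
    def es_frame(self) -> int:
        return self.deformation.es_frame

    def analytic_ef(self) -> float:
        """Closed-form LV ejection fraction of the imposed contraction, %."""
        al = self.deformation.alpha(self.deformation.es_frame)
        return 100.0 * (1.0 - (1.0 - al) ** 2)

    def analytic_strain_fields(self, t: int | None = None):
        """Per-pixel analytic (Err, Ecc) over the ED myocardium at frame t."""
        t = self.deformation.es_frame if t is None else t
        H, W = self.images.shape
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        rel = np.stack([rr, cc], -1) - self.deformation.center
        r = np.hypot(rel[..., 0], rel[..., 1])
        myo = self.labels[0] == LABEL_MYOCARDIUM
        err = np.full((H, W), np.nan)
        ecc = np.full((H, W), np.nan)
        e_r, e_c = self.deformation.strain_rr_cc(np.maximum(r, 1e-6), t)
        err[myo] = e_r[myo]
        ecc[myo] = e_c[myo]
        return err, ecc


def _smoothstep(x: np.ndarray, edge: float = 0.75) -> np.ndarray:
    """0→1 transition of width ~2*edge px around x=0 (anti-aliased boundary)."""
    t = np.clip(0.5 + x / (2 * edge), 0.0, 1.0)
    return t * t * (3 - 2 * t)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  n_modes: int = 6, scale: float = 1.0) -> np.ndarray:
    """Smooth random field from a few low-frequency Fourier modes, in [-1, 1]."""
    H, W = shape
    yy, xx = np.meshgrid(np.linspace(0, 1, H), np.linspace(0, 1, W),
                         indexing="ij")
    out = np.zeros(shape)
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.5, 2.5, 2) * scale
        ph = rng.uniform(0, 2 * np.pi, 2)
        out += rng.normal() * np.cos(2 * np.pi * fy * yy + ph[0]) \
            * np.cos(2 * np.pi * fx * xx + ph[1])
    m = np.abs(out).max()
    return out / m if m > 0 else out


def _geometry(cfg: PhantomConfig, slice_scale: float = 1.0):
    H, W = cfg.grid_size
    S = min(H, W)
    center = np.array([H / 2.0 - 0.5, W / 2.0 + 0.06 * S - 0.5])
    r_endo = 0.17 * S * slice_scale
    r_epi = 0.29 * S * slice_scale
    a = 0.36 * S
    b = 0.47 * S
    rv_center = center + np.array([0.0, -(r_epi + 0.10 * S)])
    rv_radius = 0.19 * S * slice_scale
    return center, r_endo, r_epi, a, b, rv_center, rv_radius


def _material_labels(cfg: PhantomConfig, pts: np.ndarray, geom) -> np.ndarray:
    center, r_endo, r_epi, a, b, rv_center, rv_radius = geom
    r_lv = np.hypot(pts[..., 0] - center[0], pts[..., 1] - center[1])
    r_rv = np.hypot(pts[..., 0] - rv_center[0], pts[..., 1] - rv_center[1])
    lab = np.zeros(pts.shape[:-1], dtype=np.int16)
    lab[(r_rv < rv_radius) & (r_lv > r_epi)] = LABEL_RV_POOL
    lab[(r_lv > r_endo) & (r_lv <= r_epi)] = LABEL_MYOCARDIUM
    lab[r_lv <= r_endo] = LABEL_LV_POOL
    return lab


def _material_intensity(cfg: PhantomConfig, pts: np.ndarray, geom,
                        texture: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    center, r_endo, r_epi, a, b, rv_center, rv_radius = geom
    r_lv = np.hypot(pts[..., 0] - center[0], pts[..., 1] - center[1])
    r_rv = np.hypot(pts[..., 0] - rv_center[0], pts[..., 1] - rv_center[1])
    bg, lv, myo, rv = 0.20, 0.90, 0.45, 0.85
    in_lv = _smoothstep(r_endo - r_lv)
    in_epi = _smoothstep(r_epi - r_lv)
    in_rv = _smoothstep(rv_radius - r_rv) * _smoothstep(r_lv - r_epi)
    img = bg * np.ones(pts.shape[:-1])
    img = img * (1 - in_rv) + rv * in_rv
    img = img * (1 - in_epi) + myo * in_epi
    img = img * (1 - in_lv) + lv * in_lv
    # additive material texture: chest wall, trabeculation and papillary
    # structure advect with the tissue and keep motion photometrically
    # observable everywhere in the FOV
    return np.clip(img + cfg.texture_amplitude * texture(pts), 0.02, None)


def generate_cine_phantom(config: PhantomConfig,
                          slice_scale: float = 1.0) -> PhantomGroundTruth:
    """Generate one deforming 2D+t slice with exact ground truth.

    Deterministic for a fixed seed; different seeds change texture, bias and
    noise draws but not the imposed deformation.
    """
    cfg = config
    H, W = cfg.grid_size
    T = cfg.n_frames
    geom = _geometry(cfg, slice_scale)
    center, r_endo, r_epi, a, b, rv_center, rv_radius = geom
    deform = AnnulusDeformation(center, r_endo, a, b,
                                cfg.contraction_amplitude,
                                cfg.rotation_amplitude, T)

    rng = np.random.default_rng(cfg.seed)
    tex_field = _smooth_field(rng, (H, W), n_modes=16, scale=3.5)

    def texture(pts: np.ndarray) -> np.ndarray:
        ry = np.clip(pts[..., 0], 0, H - 1)
        cx = np.clip(pts[..., 1], 0, W - 1)
        r0 = np.floor(ry).astype(int)
        c0 = np.floor(cx).astype(int)
        r1 = np.minimum(r0 + 1, H - 1)
        c1 = np.minimum(c0 + 1, W - 1)
        fy = ry - r0
        fx = cx - c0
        return (tex_field[r0, c0] * (1 - fy) * (1 - fx)
                + tex_field[r0, c1] * (1 - fy) * fx
                + tex_field[r1, c0] * fy * (1 - fx)
                + tex_field[r1, c1] * fy * fx)

    bias = 1.0 + cfg.bias_amplitude * _smooth_field(rng, (H, W), n_modes=4,
                                                    scale=0.6)

    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pts = np.stack([rr, cc], axis=-1).astype(np.float64)

    frames = np.empty((T, H, W), dtype=np.float32)
    labels = np.empty((T, H, W), dtype=np.int16)
    lv_ml = np.empty(T)
    noise = rng.normal(0.0, cfg.noise_sigma, size=(T, H, W)) \
        if cfg.noise_sigma > 0 else np.zeros((T, H, W))
    for t in range(T):
        material = deform.inverse(pts, t)
        frames[t] = (bias * _material_intensity(cfg, material, geom, texture)
                     + noise[t]).astype(np.float32)
        labels[t] = _material_labels(cfg, material, geom)
        al = deform.alpha(t)
        area_px = np.pi * (r_endo * (1 - al)) ** 2
        lv_ml[t] = (area_px * cfg.pixel_spacing[0] * cfg.pixel_spacing[1]
                    * cfg.slice_thickness) / 1000.0

    px_vol = cfg.pixel_spacing[0] * cfg.pixel_spacing[1] * cfg.slice_thickness
    rv_ml = np.array([(labels[t] == LABEL_RV_POOL).sum() * px_vol / 1000.0
                      for t in range(T)])
    volumes = VolumeCurve(lv_ml=lv_ml, rv_ml=rv_ml)
    seq = CineSequence(frames=frames, pixel_spacing=cfg.pixel_spacing,
                       slice_thickness=cfg.slice_thickness, dt=cfg.dt)
    noise_free = (frames - noise).astype(np.float32)
    return PhantomGroundTruth(images=seq, labels=labels, deformation=deform,
                              true_volumes=volumes, config=cfg,
                              noise_free=noise_free)


def generate_slice_stack(config: PhantomConfig) -> list[PhantomGroundTruth]:
    """A short-axis stack from base (full radius) to apex (tapered radius)."""
    n = config.n_slices
    if n == 1:
        return [generate_cine_phantom(config)]
    scales = 1.0 - config.slice_taper * np.arange(n) / max(n - 1, 1)
    return [generate_cine_phantom(config, slice_scale=float(s)) for s in scales]


def generate_coil_maps(n_coils: int, grid: tuple[int, int],
                       seed: int = 0) -> np.ndarray:
    """Smooth complex coil sensitivities; uniform single coil for n_coils=1.

    Gaussian-magnitude lobes centred outside the FOV on a ring, each with a
    smooth linear phase ramp; the root-sum-of-squares is strictly positive.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    H, W = grid
    if n_coils == 1:
        return np.ones((1, H, W), dtype=np.complex128)
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    maps = np.empty((n_coils, H, W), dtype=np.complex128)
    S = min(H, W)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.05)
        cy = H / 2 + 0.75 * S * np.sin(ang)
        cx = W / 2 + 0.75 * S * np.cos(ang)
        sigma = 0.8 * S
        mag = 0.2 + np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2)
                             / (2 * sigma**2)))
        ramp = (np.sin(ang) * yy + np.cos(ang) * xx) / S
        phase = 2 * np.pi * 0.15 * ramp + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    return maps


def generate_kt_mask(shape: tuple[int, int], R: float, acs_lines: int = 4,
                     seed: int = 0) -> np.ndarray:
    """Variable-density incoherent ky-t sampling mask (T, H_ky).

    The central ``acs_lines`` block is sampled in every frame; the remaining
    budget per frame is drawn without replacement from a centre-weighted
    density, re-drawn per frame so the pattern is incoherent along t.
    """
    T, H = shape
    if R < 1:
        raise ValueError("acceleration R must be >= 1")
    if not (0 <= acs_lines < H):
        raise ValueError("acs_lines must be in [0, H_ky)")
    n_keep = int(round(H / R))
    if n_keep < acs_lines:
        raise ValueError(
            f"infeasible: ACS block ({acs_lines} lines) exceeds the per-frame "
            f"budget of {n_keep} lines at R={R}")
    if R == 1:
        return np.ones((T, H), dtype=np.float32)
    rng = np.random.default_rng(seed)
    center = (H - 1) / 2.0
    acs_lo = int(np.floor(center)) - acs_lines // 2 + 1
    acs_idx = np.arange(acs_lo, acs_lo + acs_lines)
    k = np.arange(H)
    density = np.exp(-0.5 * ((k - center) / (0.25 * H)) ** 2)
    mask = np.zeros((T, H), dtype=np.float32)
    for t in range(T):
        mask[t, acs_idx] = 1.0
        remaining = np.setdiff1d(k, acs_idx)
        p = density[remaining]
        p = p / p.sum()
        extra = rng.choice(remaining, size=n_keep - acs_lines, replace=False,
                           p=p)
        mask[t, extra] = 1.0
    return mask


def simulate_kspace(images: CineSequence, coils: np.ndarray,
                    mask: np.ndarray, noise_sigma: float = 0.0,
                    seed: int = 0) -> KSpaceBundle:
    """Per coil and frame: k = mask * F(C * image) (+ complex noise).

    The fully sampled k-space is retained in ``y_full`` for reference metrics.
    """
    frames = images.frames
    T, H, W = frames.shape
    if coils.shape[-2:] != (H, W):
        raise ValueError("coil maps do not match the image grid")
    if mask.shape != (T, H):
        raise ValueError("mask must be (T, H_ky)")
    y_full = fft2c(frames[:, None, :, :] * coils[None])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * np.abs(y_full).max() / np.sqrt(H * W)
        y_full = y_full + scale * (rng.standard_normal(y_full.shape)
                                   + 1j * rng.standard_normal(y_full.shape))
    y = y_full * mask[:, None, :, None]
    R = mask.size / max(mask.sum(), 1)
    return KSpaceBundle(y=y, coils=coils, mask=mask, R=float(R), y_full=y_full,
                        pixel_spacing=images.pixel_spacing,
                        slice_thickness=images.slice_thickness, dt=images.dt)
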