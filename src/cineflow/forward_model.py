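"""The Cartesian MR forward operation A = phi F C, its adjoint and inverses.

The Fourier transform is the centered orthonormal 2D FFT, so ``A`` has operator
norm at most one and iterative solvers can use unit-scale steps.  The sampling
mask selects ky lines (image rows) per frame and is broadcast along kx.
"""

from __future__ import annotations

import numpy as np

from .containers import CineSequence, KSpaceBundle


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def ifft2c(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def _expand_mask(phi: np.ndarray, shape_hw: tuple[int, int]) -> np.ndarray:
    """Accept (H,), (T, H) or full (T, H, W) masks; return broadcastable form."""
    H, W = shape_hw
    phi = np.asarray(phi)
    if phi.ndim >= 2 and phi.shape[-2:] == (H, W):
        return phi
    if phi.shape[-1] != H:
        raise ValueError(f"mask ky dimension {phi.shape[-1]} != image rows {H}")
    return phi[..., None]


def apply_forward(x: np.ndarray, coils: np.ndarray,
                  phi: np.ndarray) -> np.ndarray:
    """A x = phi F (C x).

    x: (..., H, W) image; coils: (coils, H, W); returns (..., coils, H, W).
    """
    x = np.asarray(x)
    H, W = x.shape[-2:]
    if coils.shape[-2:] != (H, W):
        raise ValueError("coil map grid does not match image grid")
    cx = x[..., None, :, :] * coils
    k = fft2c(cx)
    m = _expand_mask(phi, (H, W))
    if m.ndim > 1 and m.shape[0] != 1 and x.ndim > 2:
        m = np.reshape(m, m.shape[:1] + (1,) + m.shape[1:])  # (T,1,H[,W])
    return k * m


def apply_adjoint(y: np.ndarray, coils: np.ndarray,
                  phi: np.ndarray) -> np.ndarray:
    """A^H y = C^H F^{-1} (phi y); y: (..., coils, H, W) -> (..., H, W)."""
    y = np.asarray(y)
    H, W = y.shape[-2:]
    m = _expand_mask(phi, (H, W))
    if m.ndim > 1 and m.shape[0] != 1 and y.ndim > 3:
        m = np.reshape(m, m.shape[:1] + (1,) + m.shape[1:])
    img = ifft2c(y * m)
    return (np.conj(coils) * img).sum(axis=-3)


def coil_combine(images: np.ndarray, coils: np.ndarray | None = None) -> np.ndarray:
    """Combine per-coil images: matched-filter when maps are known, else RSS.

    images: (..., coils, H, W) complex; returns (..., H, W).
    """
    if coils is None:
        return np.sqrt((np.abs(images) ** 2).sum(axis=-3))
    denom = (np.abs(coils) ** 2).sum(axis=0)
    denom = np.maximum(denom, 1e-12)
    return (np.conj(coils) * images).sum(axis=-3) / denom


def zero_filled_recon(bundle: KSpaceBundle) -> CineSequence:
    """Inverse Fourier of the masked k-space, coil-combined, magnitude."""
    img = ifft2c(bundle.y)
    combined = coil_combine(img, bundle.coils)
    return CineSequence(frames=np.abs(combined),
                        pixel_spacing=bundle.pixel_spacing,
                        slice_thickness=bundle.slice_thickness,
                        dt=bundle.dt)
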