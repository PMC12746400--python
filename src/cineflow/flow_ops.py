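"""Dense displacement-field utilities shared across the pipeline.

Component order is ``(row_offset, col_offset)`` — the single most common
integration bug, so it is stated here once and relied on everywhere.  A field
``u`` is used with backward warping: ``warped(p) = source(p + u(p))``, with
edge-clamped out-of-domain samples (the cine background is static, so clamping
avoids spurious photometric error at the frame border).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["warp_image", "compose_flows", "jacobian_determinant",
           "nonpositive_jacobian_fraction", "flow_to_rgb", "save_flow_png"]


def _check_flow(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u)
    if u.ndim != 3 or u.shape[-1] != 2:
        raise ValueError("flow must be (H, W, 2)")
    if not np.isfinite(u).all():
        raise ValueError("flow contains non-finite values")
    return u


def warp_image(source: np.ndarray, u: np.ndarray,
               mode: str = "linear") -> np.ndarray:
    """Backward-warp ``source`` by ``u``: out(p) = source(p + u(p)).

    mode='linear' for intensities, mode='nearest' for label maps.
    """
    u = _check_flow(u)
    source = np.asarray(source)
    H, W = source.shape[-2:]
    if u.shape[:2] != (H, W):
        raise ValueError("flow grid does not match image grid")
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([rr + u[..., 0], cc + u[..., 1]])
    order = {"linear": 1, "nearest": 0}[mode]
    if np.iscomplexobj(source):
        re = ndimage.map_coordinates(source.real, coords, order=order,
                                     mode="nearest")
        im = ndimage.map_coordinates(source.imag, coords, order=order,
                                     mode="nearest")
        return re + 1j * im
    out = ndimage.map_coordinates(source, coords, order=order, mode="nearest")
    return out.astype(source.dtype) if mode == "nearest" else out


def compose_flows(u_ab: np.ndarray, u_bc: np.ndarray) -> np.ndarray:
    """Function-style composition: (u_ab ∘ u_bc)(p) = u_bc(p) + u_ab(p + u_bc(p)).

    With the package convention ``f_ij = flow(i, j)`` (warping frame j by it
    reproduces frame i), chaining i→j→k is ``f_ik = compose_flows(f_jk, f_ij)``:
    the inner field is evaluated at p, the outer field at the displaced point.
    """
    u_ab = _check_flow(u_ab)
    u_bc = _check_flow(u_bc)
    if u_ab.shape != u_bc.shape:
        raise ValueError("flows must share a grid")
    outer = np.stack([warp_image(u_ab[..., 0], u_bc),
                      warp_image(u_ab[..., 1], u_bc)], axis=-1)
    return u_bc + outer


def jacobian_determinant(u: np.ndarray) -> np.ndarray:
    """det(I + ∇u) per pixel; central differences, one-sided at borders."""
    u = _check_flow(u)
    du0_d0, du0_d1 = np.gradient(u[..., 0])
    du1_d0, du1_d1 = np.gradient(u[..., 1])
    return (1.0 + du0_d0) * (1.0 + du1_d1) - du0_d1 * du1_d0


def nonpositive_jacobian_fraction(u: np.ndarray) -> float:
    """Percentage of pixels with det(I + ∇u) <= 0 (folding); 0 is desired."""
    det = jacobian_determinant(u)
    return 100.0 * float((det <= 0).sum()) / det.size


def flow_to_rgb(u: np.ndarray, max_mag: float | None = None) -> np.ndarray:
    """Colour-wheel visualization: hue = direction, saturation = magnitude."""
    import matplotlib.colors as mcolors

    u = _check_flow(u)
    mag = np.hypot(u[..., 0], u[..., 1])
    ang = np.arctan2(u[..., 0], u[..., 1])
    max_mag = float(mag.max()) if max_mag is None else max_mag
    hsv = np.zeros(u.shape[:2] + (3,))
    hsv[..., 0] = (ang + np.pi) / (2 * np.pi)
    hsv[..., 1] = np.clip(mag / max(max_mag, 1e-9), 0, 1)
    hsv[..., 2] = 1.0
    return mcolors.hsv_to_rgb(hsv)


def save_flow_png(u: np.ndarray, path: str,
                  max_mag: float | None = None) -> None:
    """Write the colour-wheel rendering of a flow field to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, flow_to_rgb(u, max_mag=max_mag))
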