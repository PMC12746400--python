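"""Ventricular function analysis: volumes, ejection fraction, Green–Lagrange
strain with radial/circumferential projection, and AHA 17-segment summaries.

Conventions
-----------
* Volumes are Simpson-style slice sums: pool pixel count × pixel area × slice
  thickness, in ml.  ED/ES are the frames of maximal/minimal LV volume.
* The strain tensor is computed from the displacement field ``u`` mapping
  end-diastolic positions to their position at the analysed frame,
  E = 1/2 (∇u + ∇uᵀ + ∇uᵀ∇u), with gradients in physical units.  E vanishes
  for rigid motion.
* Radial unit vectors point from the epicardial centre of mass outward;
  circumferential vectors are their 90° counter-clockwise rotation.  With the
  phantom's thickening contraction, Err > 0 and Ecc < 0 at end-systole.
* The 17-segment model: 6 basal, 6 mid-ventricular, 4 apical segments plus
  the apex, with the angular origin at the anterior RV insertion point
  derived from the RV mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .containers import (LABEL_LV_POOL, LABEL_MYOCARDIUM, LABEL_RV_POOL,
                         SegMask, VolumeCurve)

__all__ = ["ventricular_volumes", "ejection_fraction", "green_lagrange",
           "local_coordinates", "project_strain", "aha17_bullseye",
           "StrainResult", "BullsEye17", "plot_bullseye"]


def _labels_of(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, SegMask) else np.asarray(mask)


def ventricular_volumes(masks_per_slice, pixel_spacing: tuple[float, float],
                        slice_thickness: float) -> VolumeCurve:
    """Simpson-style volumes from per-slice, per-frame label masks.

    masks_per_slice: list over slices of lists over frames of SegMask/arrays;
    a single slice's frame list is also accepted.
    """
    if not isinstance(masks_per_slice[0], (list, tuple)):
        masks_per_slice = [masks_per_slice]
    n_frames = len(masks_per_slice[0])
    px_ml = pixel_spacing[0] * pixel_spacing[1] * slice_thickness / 1000.0
    lv = np.zeros(n_frames)
    rv = np.zeros(n_frames)
    for slc in masks_per_slice:
        for t, m in enumerate(slc):
            lab = _labels_of(m)
            lv[t] += (lab == LABEL_LV_POOL).sum() * px_ml
            rv[t] += (lab == LABEL_RV_POOL).sum() * px_ml
    if lv.max() == 0:
        raise ValueError("LV blood pool empty in every frame")
    return VolumeCurve(lv_ml=lv, rv_ml=rv)


def ejection_fraction(edv: float, esv: float) -> float:
    """100 * (EDV - ESV) / EDV, in percent."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def green_lagrange(u: np.ndarray,
                   pixel_spacing: tuple[float, float] = (1.0, 1.0)
                   ) -> np.ndarray:
    """Green–Lagrange tensor field E (H, W, 2, 2) from displacement ``u``.

    ``u`` maps end-diastolic grid positions to their displaced positions
    (pixel units, (row, col) order); spacing converts to physical gradients.
    Central differences in the interior, one-sided at the borders.
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 3 or u.shape[-1] != 2:
        raise ValueError("u must be (H, W, 2)")
    sp = (pixel_spacing[0], pixel_spacing[1])
    u_mm = u * np.array(sp)
    grad = np.empty(u.shape[:2] + (2, 2))
    for comp in range(2):
        gr, gc = np.gradient(u_mm[..., comp], *sp)
        grad[..., comp, 0] = gr
        grad[..., comp, 1] = gc
    gt = np.swapaxes(grad, -1, -2)
    return 0.5 * (grad + gt + gt @ grad)


def local_coordinates(ed_mask, min_contour_points: int = 8
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial/circumferential unit-vector fields from the ED epicardium.

    The epicardial contour is the outer boundary of (LV pool ∪ myocardium).
    Its centre of mass defines the origin; every pixel's radial vector points
    from the centre through the pixel (the contour definition extended
    inward by angle), and the circumferential vector is its 90° CCW rotation.

    Returns (r_field, c_field, center), each field (H, W, 2).
    """
    lab = _labels_of(ed_mask)
    epi = (lab == LABEL_LV_POOL) | (lab == LABEL_MYOCARDIUM)
    if not epi.any():
        raise ValueError("empty epicardial region")
    contours = measure.find_contours(epi.astype(float), 0.5)
    contour = max(contours, key=len)
    if len(contour) < min_contour_points:
        raise ValueError("degenerate epicardial contour")
    center = contour.mean(axis=0)
    H, W = lab.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    rel = np.stack([rr - center[0], cc - center[1]], axis=-1)
    norm = np.linalg.norm(rel, axis=-1, keepdims=True)
    r_field = np.where(norm > 1e-9, rel / np.maximum(norm, 1e-9), 0.0)
    # 90 deg counter-clockwise in (row, col) with row pointing down:
    # (dr, dc) -> (-dc, dr) is the tangential direction of increasing
    # counter-clockwise angle in image convention
    c_field = np.stack([-r_field[..., 1], r_field[..., 0]], axis=-1)
    return r_field, c_field, center


def project_strain(E: np.ndarray, r_field: np.ndarray, c_field: np.ndarray,
                   myo_mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Err = rᵀEr and Ecc = cᵀEc per pixel (NaN outside the myocardium)."""
    err = np.einsum("...i,...ij,...j->...", r_field, E, r_field)
    ecc = np.einsum("...i,...ij,...j->...", c_field, E, c_field)
    if myo_mask is not None:
        err = np.where(myo_mask, err, np.nan)
        ecc = np.where(myo_mask, ecc, np.nan)
    return err, ecc


@dataclass
class StrainResult:
    E: np.ndarray              # (H, W, 2, 2)
    Err: np.ndarray            # (H, W), NaN outside myocardium
    Ecc: np.ndarray
    mGRS: float                # myocardial mean radial strain at ES
    mGCS: float                # myocardial mean circumferential strain at ES


def compute_strain(u_ed_to_es: np.ndarray, ed_mask,
                   pixel_spacing: tuple[float, float] = (1.0, 1.0)
                   ) -> StrainResult:
    """End-systolic strain from the ED→ES displacement and the ED mask."""
    lab = _labels_of(ed_mask)
    myo = lab == LABEL_MYOCARDIUM
    E = green_lagrange(u_ed_to_es, pixel_spacing)
    r_field, c_field, _ = local_coordinates(lab)
    err, ecc = project_strain(E, r_field, c_field, myo)
    return StrainResult(E=E, Err=err, Ecc=ecc,
                        mGRS=float(np.nanmean(err)),
                        mGCS=float(np.nanmean(ecc)))


@dataclass
class BullsEye17:
    """Per-segment means; NaN marks segments with no myocardial pixels."""

    values: np.ndarray         # (17,)

    SEGMENT_NAMES = (
        "basal anterior", "basal anteroseptal", "basal inferoseptal",
        "basal inferior", "basal inferolateral", "basal anterolateral",
        "mid anterior", "mid anteroseptal", "mid inferoseptal",
        "mid inferior", "mid inferolateral", "mid anterolateral",
        "apical anterior", "apical septal", "apical inferior",
        "apical lateral", "apex")


def _rv_insertion_angle(ed_labels: np.ndarray, center: np.ndarray) -> float:
    """Angle of the anterior RV insertion point (from the RV mask)."""
    rv = ed_labels == LABEL_RV_POOL
    if not rv.any():
        return np.pi / 2.0
    rr, cc = np.nonzero(rv)
    ang = np.arctan2(rr - center[0], cc - center[1])
    # anterior insertion: the most counter-clockwise RV pixel as seen from
    # the LV centre (smallest angle of the RV angular span)
    ang = np.unwrap(np.sort(ang))
    return float(ang[0])


def aha17_bullseye(strain_per_slice: list[np.ndarray],
                   masks_per_slice: list,
                   slice_positions: list[float] | None = None,
                   rv_insertion_angle: float | None = None) -> BullsEye17:
    """Map per-slice myocardial strain fields onto the 17-segment model.

    strain_per_slice: base-to-apex list of (H, W) strain fields (NaN outside
    the myocardium); masks_per_slice: matching ED masks.  Slices are split
    into basal/mid/apical thirds by position (index order if positions are
    not given); 6+6+4 angular sectors plus the apex segment.
    """
    n = len(strain_per_slice)
    if n < 3:
        raise ValueError("need at least 3 slices (basal, mid, apical)")
    if slice_positions is None:
        slice_positions = list(range(n))
    order = np.argsort(slice_positions)
    thirds = np.array_split(np.asarray(order), 3)
    sums = np.zeros(17)
    counts = np.zeros(17)
    for ring, slice_ids in enumerate(thirds):  # 0 basal, 1 mid, 2 apical
        n_sect = 4 if ring == 2 else 6
        base_seg = (0, 6, 12)[ring]
        for si in slice_ids:
            lab = _labels_of(masks_per_slice[si])
            field = strain_per_slice[si]
            myo = (lab == LABEL_MYOCARDIUM) & np.isfinite(field)
            if not myo.any():
                continue
            _, _, center = local_coordinates(lab)
            theta0 = rv_insertion_angle if rv_insertion_angle is not None \
                else _rv_insertion_angle(lab, center)
            rr, cc = np.nonzero(myo)
            ang = np.arctan2(rr - center[0], cc - center[1]) - theta0
            sector = np.floor((ang % (2 * np.pi)) / (2 * np.pi / n_sect))
            sector = sector.astype(int) % n_sect
            vals = field[rr, cc]
            for s in range(n_sect):
                sel = sector == s
                sums[base_seg + s] += vals[sel].sum()
                counts[base_seg + s] += sel.sum()
    # apex (segment 17) from the most apical slice's full myocardium
    apex_id = thirds[2][-1]
    lab = _labels_of(masks_per_slice[apex_id])
    field = strain_per_slice[apex_id]
    myo = (lab == LABEL_MYOCARDIUM) & np.isfinite(field)
    if myo.any():
        sums[16] = field[myo].sum()
        counts[16] = myo.sum()
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BullsEye17(values=values)


def plot_bullseye(be: BullsEye17, path: str, title: str = "",
                  cmap: str = "RdBu_r") -> None:
    """Render the classic polar 17-segment plot to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(5, 5))
    vals = be.values
    vmax = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
    norm = plt.Normalize(-vmax, vmax)
    rings = [(3, 4, 0, 6), (2, 3, 6, 6), (1, 2, 12, 4)]
    for r0, r1, base, nsect in rings:
        for s in range(nsect):
            th0 = 2 * np.pi * s / nsect
            th = np.linspace(th0, th0 + 2 * np.pi / nsect, 24)
            v = vals[base + s]
            color = plt.get_cmap(cmap)(norm(v)) if np.isfinite(v) else "0.8"
            ax.fill_between(th, r0, r1, color=color)
            ax.plot(th, np.full_like(th, r1), "k", lw=0.5)
    v = vals[16]
    color = plt.get_cmap(cmap)(norm(v)) if np.isfinite(v) else "0.8"
    th = np.linspace(0, 2 * np.pi, 60)
    ax.fill_between(th, 0, 1, color=color)
    ax.set_yticks([])
    ax.set_xticks([])
    ax.set_title(title)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=100)
    plt.close(fig)
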