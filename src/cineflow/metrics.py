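"""Evaluation metrics for segmentation, registration and reconstruction.

Conventions: DSC of two empty masks is 1; HDD/MCD are undefined (NaN) for an
empty mask; NRMSE is normalized by the reference intensity range; SSIM uses a
7-pixel window with k1=0.01, k2=0.03 and the reference dynamic range; the
overlap score (OS) warps masks between end-diastole and end-systole in both
directions and averages the two Dice values.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from skimage.metrics import structural_similarity

from . import flow_ops

__all__ = ["dice", "hausdorff", "mean_contour_distance", "overlap_score",
           "nrmse", "ssim", "boundary_points"]


def dice(pred: np.ndarray, ref: np.ndarray,
         label: int | None = None) -> float:
    """2|A∩B| / (|A|+|B|); both-empty -> 1 by convention."""
    a = np.asarray(pred) == label if label is not None else \
        np.asarray(pred).astype(bool)
    b = np.asarray(ref) == label if label is not None else \
        np.asarray(ref).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixel coordinates via 4-connectivity erosion difference."""
    from scipy import ndimage

    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.empty((0, 2))
    er = ndimage.binary_erosion(
        m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return np.argwhere(m & ~er)


def _contour_dists(a: np.ndarray, b: np.ndarray,
                   spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    pa = boundary_points(a) * np.asarray(spacing)
    pb = boundary_points(b) * np.asarray(spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("empty mask: contour distance undefined")
    d = cdist(pa, pb)
    return d.min(axis=1), d.min(axis=0)


def hausdorff(pred: np.ndarray, ref: np.ndarray,
              spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm."""
    dab, dba = _contour_dists(pred, ref, spacing)
    return float(max(dab.max(), dba.max()))


def mean_contour_distance(pred: np.ndarray, ref: np.ndarray,
                          spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Symmetric mean nearest-boundary distance, in mm."""
    dab, dba = _contour_dists(pred, ref, spacing)
    return float(0.5 * (dab.mean() + dba.mean()))


def overlap_score(mask_ed: np.ndarray, mask_es: np.ndarray,
                  flow_ed_to_es: np.ndarray, flow_es_to_ed: np.ndarray,
                  label: int | None = None) -> float:
    """DSC between manual and motion-propagated masks, both directions.

    ``flow_ed_to_es`` is flow(ED, ES): warping the ES mask by it propagates
    it into the ED frame, and vice versa.  The two Dice values are averaged.
    """
    ed = np.asarray(mask_ed)
    es = np.asarray(mask_es)
    prop_to_ed = flow_ops.warp_image(es, flow_ed_to_es, mode="nearest")
    prop_to_es = flow_ops.warp_image(ed, flow_es_to_ed, mode="nearest")
    return 0.5 * (dice(prop_to_ed, ed, label) + dice(prop_to_es, es, label))


def nrmse(test: np.ndarray, ref: np.ndarray) -> float:
    """RMSE normalized by the reference intensity range."""
    test = np.asarray(test, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if test.shape != ref.shape:
        raise ValueError("image shapes differ")
    rng = ref.max() - ref.min()
    if rng == 0:
        raise ValueError("constant reference: NRMSE undefined")
    return float(np.sqrt(np.mean((test - ref) ** 2)) / rng)


def ssim(test: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity, window 7, k1=0.01, k2=0.03, ref dynamic range."""
    test = np.asarray(test, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    dr = ref.max() - ref.min()
    return float(structural_similarity(ref, test, win_size=7, K1=0.01,
                                       K2=0.03, data_range=dr))
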