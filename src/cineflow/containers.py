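"""Lightweight data containers shared across the pipeline.

Conventions used throughout the package
---------------------------------------
* Image arrays are ``(T, H, W)`` (time first); k-space is ``(T, coils, H, W)``.
* Displacement fields ("flows") are ``(H, W, 2)`` in **pixel units** with
  component order ``(row_offset, col_offset)``.  ``flow(i, j)`` denotes the
  field ``u`` satisfying ``frame_i(p) ≈ frame_j(p + u(p))``: backward-warping
  frame ``j`` by ``u`` reproduces frame ``i``, and ``u(p)`` is the displacement
  of the tissue seen at ``p`` in frame ``i`` to its position in frame ``j``.
* Segmentation labels: 0 background, 1 LV blood pool, 2 myocardium,
  3 RV blood pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_BACKGROUND = 0
LABEL_LV_POOL = 1
LABEL_MYOCARDIUM = 2
LABEL_RV_POOL = 3
N_CLASSES = 4


@dataclass
class CineSequence:
    """A 2D+t cine slice: magnitude or complex frames with geometry metadata."""

    frames: np.ndarray               # (T, H, W)
    pixel_spacing: tuple[float, float] = (1.9, 1.9)   # mm
    slice_thickness: float = 8.0     # mm
    dt: float = 40.0                 # temporal resolution, ms

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.frames) if np.iscomplexobj(self.frames) else self.frames


@dataclass
class KSpaceBundle:
    """Multi-coil Cartesian k-space with coil maps and a ky-t sampling mask."""

    y: np.ndarray                    # (T, coils, H, W) masked k-space
    coils: np.ndarray                # (coils, H, W) complex sensitivities
    mask: np.ndarray                 # (T, H) binary over ky lines
    R: float = 1.0                   # nominal acceleration
    y_full: np.ndarray | None = None  # fully sampled reference k-space
    pixel_spacing: tuple[float, float] = (1.9, 1.9)
    slice_thickness: float = 8.0
    dt: float = 40.0

    def __post_init__(self):
        if self.y.ndim != 4:
            raise ValueError("y must be (T, coils, H, W)")
        if self.coils.shape != self.y.shape[1:]:
            raise ValueError("coil maps must match k-space shape")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass
class SegMask:
    """Per-frame 4-class segmentation; probs optional (4, H, W) simplex."""

    labels: np.ndarray               # (H, W) int
    probs: np.ndarray | None = None

    def one_hot(self) -> np.ndarray:
        oh = np.zeros((N_CLASSES,) + self.labels.shape, dtype=np.float32)
        for c in range(N_CLASSES):
            oh[c] = self.labels == c
        return oh


@dataclass
class VolumeCurve:
    """Per-frame ventricular blood-pool volumes in ml with ED/ES landmarks."""

    lv_ml: np.ndarray
    rv_ml: np.ndarray
    ed_frame: int = field(init=False)
    es_frame: int = field(init=False)

    def __post_init__(self):
        self.ed_frame = int(np.argmax(self.lv_ml))
        self.es_frame = int(np.argmin(self.lv_ml))

    @property
    def lv_edv(self) -> float:
        return float(self.lv_ml[self.ed_frame])

    @property
    def lv_esv(self) -> float:
        return float(self.lv_ml[self.es_frame])

    @property
    def rv_edv(self) -> float:
        return float(self.rv_ml[int(np.argmax(self.rv_ml))])

    @property
    def rv_esv(self) -> float:
        return float(self.rv_ml[int(np.argmin(self.rv_ml))])
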