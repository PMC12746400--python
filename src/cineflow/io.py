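"""HDF5 bundle interchange and NIfTI export.

The bundle layout (schema version 1):

    /images      (T, H, W) float or complex
    /kspace      (T, coils, H, W) complex           [optional]
    /kspace_full (T, coils, H, W) complex           [optional]
    /coils       (coils, H, W) complex              [optional]
    /mask        (T, H_ky) binary                   [optional]
    /labels      (T, H, W) int                      [optional]
    /flows       (P, H, W, 2) float                 [optional]
    /flow_pairs  (P, 2) int — (i, j) per stored flow
    attrs: schema, pixel_spacing, slice_thickness, dt, seed, R, config (JSON)
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import CineSequence, KSpaceBundle

SCHEMA_VERSION = 1

__all__ = ["write_bundle", "read_bundle", "write_flow_table",
           "read_flow_table", "export_nifti", "SCHEMA_VERSION"]


def write_bundle(path: str | Path, images: CineSequence | None = None,
                 kspace: KSpaceBundle | None = None,
                 labels: np.ndarray | None = None,
                 flows: dict | None = None, seed: int | None = None,
                 config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        if images is not None:
            f.create_dataset("images", data=images.frames)
            f.attrs["pixel_spacing"] = images.pixel_spacing
            f.attrs["slice_thickness"] = images.slice_thickness
            f.attrs["dt"] = images.dt
        if kspace is not None:
            f.create_dataset("kspace", data=kspace.y)
            f.create_dataset("coils", data=kspace.coils)
            f.create_dataset("mask", data=kspace.mask)
            if kspace.y_full is not None:
                f.create_dataset("kspace_full", data=kspace.y_full)
            f.attrs["R"] = kspace.R
            if images is None:
                f.attrs["pixel_spacing"] = kspace.pixel_spacing
                f.attrs["slice_thickness"] = kspace.slice_thickness
                f.attrs["dt"] = kspace.dt
        if labels is not None:
            f.create_dataset("labels", data=labels.astype(np.int16))
        if flows:
            pairs = sorted(flows.keys())
            f.create_dataset("flows",
                             data=np.stack([flows[p] for p in pairs]))
            f.create_dataset("flow_pairs", data=np.asarray(pairs))
        if seed is not None:
            f.attrs["seed"] = seed
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def read_bundle(path: str | Path) -> dict:
    """Read a bundle back into a dict of containers/arrays."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        schema = int(f.attrs.get("schema", -1))
        if schema != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported bundle schema {schema} "
                f"(this build reads version {SCHEMA_VERSION})")
        spacing = tuple(f.attrs.get("pixel_spacing", (1.9, 1.9)))
        thick = float(f.attrs.get("slice_thickness", 8.0))
        dt = float(f.attrs.get("dt", 40.0))
        if "images" in f:
            out["images"] = CineSequence(frames=f["images"][()],
                                         pixel_spacing=spacing,
                                         slice_thickness=thick, dt=dt)
        if "kspace" in f:
            out["kspace"] = KSpaceBundle(
                y=f["kspace"][()], coils=f["coils"][()], mask=f["mask"][()],
                R=float(f.attrs.get("R", 1.0)),
                y_full=f["kspace_full"][()] if "kspace_full" in f else None,
                pixel_spacing=spacing, slice_thickness=thick, dt=dt)
        if "labels" in f:
            out["labels"] = f["labels"][()]
        if "flows" in f:
            pairs = [tuple(int(v) for v in p) for p in f["flow_pairs"][()]]
            out["flows"] = dict(zip(pairs, f["flows"][()]))
        if "seed" in f.attrs:
            out["seed"] = int(f.attrs["seed"])
        if "config" in f.attrs:
            out["config"] = json.loads(str(f.attrs["config"]))
    return out


def write_flow_table(path: str | Path, table, seed: int | None = None) -> None:
    write_bundle(path, flows=table.flows, seed=seed,
                 config={"n_frames": table.n_frames})


def read_flow_table(path: str | Path):
    from .mopnet import FlowTable

    data = read_bundle(path)
    table = FlowTable(int(data["config"]["n_frames"]))
    table.flows.update(data["flows"])
    return table


def export_nifti(path: str | Path, frames: np.ndarray,
                 pixel_spacing: tuple[float, float] = (1.9, 1.9),
                 slice_thickness: float = 8.0) -> None:
    """Magnitude frames (T, H, W) -> NIfTI (H, W, 1, T) with spacing header."""
    import nibabel as nib

    frames = np.abs(np.asarray(frames))
    vol = np.transpose(frames, (1, 2, 0))[:, :, None, :]
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], slice_thickness, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header.set_zooms((pixel_spacing[0], pixel_spacing[1],
                          slice_thickness, 1.0))
    nib.save(img, str(path))
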