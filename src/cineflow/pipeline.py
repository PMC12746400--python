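"""End-to-end orchestration on synthetic phantoms.

Two entry points:

* :func:`run_phantom_pipeline` — the full chain (phantom → undersampling →
  self-supervised registration → motion-compensated reconstruction →
  weakly supervised segmentation → volumes/EF/strain) with a JSON-able
  report; used by the CLI ``pipeline`` command.
* :func:`joint_ablation_case` — one seeded comparison of joint training
  (reconstruction in the loop + pseudo-label supervision) against a
  segmentation-only baseline trained on zero-filled images with the same
  two labeled frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import metrics
from .containers import LABEL_LV_POOL
from .forward_model import zero_filled_recon
from .function_analysis import compute_strain, ventricular_volumes
from .moco import MocoConfig, ktslr_reconstruct
from .mopnet import (TINY_PROFILE, DEFAULT_PROFILE, Mopnet, MopnetConfig,
                     full_cycle_inference)
from .phantom import (PhantomConfig, generate_cine_phantom,
                      generate_coil_maps, generate_kt_mask, simulate_kspace)
from .training import (LossConfig, TrainConfig, TINY_TRAIN_PROFILE,
                       run_training_stage, _onehot)
from .unet import (TINY_PROFILE as UNET_TINY, UNet, UnetConfig,
                   generate_pseudo_labels, normalize_image, segment)

__all__ = ["prepare_case", "run_phantom_pipeline", "joint_ablation_case"]


def prepare_case(seed: int, grid: int = 32, R: float = 8.0,
                 n_coils: int = 6, acs_lines: int | None = None):
    """Phantom + undersampled k-space + zero-filled images for one case."""
    gt = generate_cine_phantom(PhantomConfig(grid_size=(grid, grid),
                                             seed=seed))
    T, H, W = gt.images.frames.shape
    if acs_lines is None:
        # keep the ACS block well below the per-frame budget so the random
        # complement stays incoherent across frames
        acs_lines = max(2, min(4, int(H / R) // 2))
    coils = generate_coil_maps(n_coils, (H, W), seed=seed)
    mask = generate_kt_mask((T, H), R=R, acs_lines=acs_lines, seed=seed)
    ks = simulate_kspace(gt.images, coils, mask)
    zf = zero_filled_recon(ks)
    return gt, ks, zf


def _train_registration(frames: np.ndarray, steps: int, seed: int,
                        profile: str = "tiny") -> Mopnet:
    prof = TINY_PROFILE if profile == "tiny" else DEFAULT_PROFILE
    model = Mopnet(MopnetConfig(seed=seed, **prof))
    cfg = TrainConfig(steps=steps, seed=seed, **TINY_TRAIN_PROFILE)
    run_training_stage("registration", {"sequences": [frames]}, cfg,
                       models={"mopnet": model})
    return model


def _train_segmentation(images: np.ndarray, labels: np.ndarray, steps: int,
                        seed: int, profile: str = "tiny") -> UNet:
    prof = UNET_TINY if profile == "tiny" else {}
    model = UNet(UnetConfig(seed=seed, **prof))
    cfg = TrainConfig(steps=steps, seed=seed, **TINY_TRAIN_PROFILE)
    run_training_stage("segmentation",
                       {"images": images,
                        "onehot": np.stack([_onehot(l) for l in labels])},
                       cfg, models={"unet": model})
    return model


def run_phantom_pipeline(out_dir: str | Path | None = None, R: float = 8.0,
                         grid: int = 64, profile: str = "tiny",
                         train_steps: int = 300, seg_steps: int = 200,
                         refine: int = 0, seed: int = 0) -> dict:
    """Full phantom chain; returns (and optionally writes) a metrics report."""
    gt, ks, zf = prepare_case(seed, grid=grid, R=R)
    T = gt.images.n_frames
    ed, es = 0, gt.es_frame
    spacing = gt.config.pixel_spacing

    # 1. self-supervised registration on the fully sampled training images
    # (available in the retrospective setting; see docs/methods.md)
    model = _train_registration(gt.images.frames, train_steps, seed, profile)
    table = full_cycle_inference(
        np.stack([normalize_image(f) for f in gt.images.frames]), model)
    flows_ref = table.to_reference(ed)

    # 2. motion-compensated reconstruction (optionally re-registered)
    recon = ktslr_reconstruct(ks, flows_ref, MocoConfig(reference_frame=ed))
    for _ in range(refine):
        table = full_cycle_inference(
            np.stack([normalize_image(f) for f in recon.frames.frames]), model)
        flows_ref = table.to_reference(ed)
        recon = ktslr_reconstruct(ks, flows_ref, MocoConfig(reference_frame=ed))

    # 3. weakly supervised segmentation: manual ED/ES labels + pseudo-labels
    pseudo = generate_pseudo_labels(gt.labels[ed], table, ed,
                                    [t for t in range(T) if t not in (ed, es)])
    imgs = [recon.frames.frames[ed], recon.frames.frames[es]]
    labs = [gt.labels[ed], gt.labels[es]]
    for f, lab in sorted(pseudo.items()):
        imgs.append(recon.frames.frames[f])
        labs.append(lab)
    unet = _train_segmentation(np.stack(imgs), np.stack(labs), seg_steps, seed,
                               profile)
    masks = segment(recon.frames, unet)
    labels_pred = np.stack([m.labels for m in masks])

    # 4. function analysis on the predicted masks and estimated motion
    vols = ventricular_volumes([list(labels_pred)], spacing,
                               gt.config.slice_thickness)
    strain = compute_strain(table.flow(ed, es), labels_pred[vols.ed_frame],
                            spacing)
    zf_nrmse = float(np.mean([metrics.nrmse(zf.frames[t],
                                            gt.noise_free[t])
                              for t in range(T)]))
    mc_nrmse = float(np.mean([metrics.nrmse(recon.frames.frames[t],
                                            gt.noise_free[t])
                              for t in range(T)]))
    report = {
        "seed": seed, "R": float(ks.R), "grid": grid,
        "lvef_percent": float(100 * (vols.lv_edv - vols.lv_esv) / vols.lv_edv),
        "lvef_analytic_percent": float(gt.analytic_ef()),
        "mgrs": strain.mGRS, "mgcs": strain.mGCS,
        "lv_dsc_vs_truth": float(np.mean(
            [metrics.dice(labels_pred[t], gt.labels[t], LABEL_LV_POOL)
             for t in range(T)])),
        "zero_filled_nrmse": zf_nrmse,
        "moco_nrmse": mc_nrmse,
        "final_objective": float(recon.objective[-1]),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_bundle, write_flow_table
        write_bundle(out / "phantom.h5", images=gt.images, kspace=ks,
                     labels=gt.labels, seed=seed)
        write_bundle(out / "recon.h5", images=recon.frames)
        write_bundle(out / "masks.h5", labels=labels_pred)
        write_flow_table(out / "flows.h5", table, seed=seed)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def joint_ablation_case(seed: int, grid: int = 32, R: float = 8.0,
                        reg_steps: int = 200, seg_steps: int = 150,
                        joint_steps: int = 150) -> dict:
    """Joint training vs. segmentation-only on one seeded phantom at R.

    Both variants see manual labels only at ED and ES.  The baseline trains
    the U-Net on the zero-filled images; the joint variant runs registration
    and motion-compensated reconstruction first, then optimizes the joint
    loss with pseudo-label supervision on intermediate frames.  Reported:
    LV blood-pool Dice over all frames against the phantom truth.
    """
    gt, ks, zf = prepare_case(seed, grid=grid, R=R)
    T = gt.images.n_frames
    ed, es = 0, gt.es_frame

    # --- segmentation-only baseline on zero-filled images
    base_unet = _train_segmentation(
        np.stack([zf.frames[ed], zf.frames[es]]),
        np.stack([gt.labels[ed], gt.labels[es]]), seg_steps + joint_steps,
        seed)
    base_masks = segment(zf.frames, base_unet)
    base_dsc = float(np.mean([metrics.dice(base_masks[t].labels,
                                           gt.labels[t], LABEL_LV_POOL)
                              for t in range(T)]))

    # --- joint variant: registration -> reconstruction -> joint stage
    # (registration on the fully sampled training images; see methods note)
    mopnet = _train_registration(gt.images.frames, reg_steps, seed)
    table = full_cycle_inference(
        np.stack([normalize_image(f) for f in gt.images.frames]), mopnet)
    recon = ktslr_reconstruct(ks, table.to_reference(ed),
                              MocoConfig(reference_frame=ed))
    rec_frames = recon.frames.frames
    joint_unet = _train_segmentation(
        np.stack([rec_frames[ed], rec_frames[es]]),
        np.stack([gt.labels[ed], gt.labels[es]]), seg_steps, seed)
    inner = [t for t in range(T) if t not in (ed, es)]
    ps_ed = generate_pseudo_labels(gt.labels[ed], table, ed, inner)
    ps_es = generate_pseudo_labels(gt.labels[es], table, es, inner)
    pseudo = {f: 0.5 * (_onehot(ps_ed[f]) + _onehot(ps_es[f]))
              for f in inner}
    cfg = TrainConfig(steps=joint_steps, seed=seed, **TINY_TRAIN_PROFILE)
    run_training_stage(
        "joint",
        {"recon_images": [rec_frames], "labels": [gt.labels],
         "labeled_frames": [(ed, es)], "sequences": [rec_frames],
         "pseudo_labels": [pseudo]},
        cfg, loss_cfg=LossConfig(K=mopnet.cfg.K),
        models={"mopnet": mopnet, "unet": joint_unet})
    joint_masks = segment(recon.frames, joint_unet)
    joint_dsc = float(np.mean([metrics.dice(joint_masks[t].labels,
                                            gt.labels[t], LABEL_LV_POOL)
                               for t in range(T)]))
    return {"seed": seed, "baseline_lv_dsc": base_dsc,
            "joint_lv_dsc": joint_dsc}
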