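# cineflow

Joint multi-frame registration, motion-compensated reconstruction,
segmentation and ventricular function analysis for accelerated cardiac cine
MRI — with a synthetic deforming cardiac phantom so that every stage is
testable end-to-end without patient data.

## Who this is for

Researchers in cardiac MR image analysis who need a transparent, CPU-runnable
reference implementation of the "registration ↔ reconstruction ↔
segmentation" synergy loop: dense motion estimation feeds a
motion-compensated k-t reconstruction, reconstructed images feed a weakly
supervised segmenter, and motion-propagated pseudo-labels feed back into
training.  Ejection fraction and Green–Lagrange strain come out at the end.

## What is inside

| Stage | Core idea |
|---|---|
| `cineflow.phantom` | 2D+t short-axis phantom: incompressible thickening annulus, closed-form deformation/inverse/strain, labels, coil maps, variable-density incoherent ky–t masks, simulated multi-coil k-space |
| `cineflow.mopnet` | recurrent tri-frame optical flow: shared encoders, dual correlation volumes, warped hidden motion states carried across refinement iterations, ConvGRU residual-flow decoding, cyclic sliding-window full-cycle inference |
| `cineflow.moco` | kt-SLR reconstruction of `y_t = phi_t F C U_t X_t`: nuclear norm of the Casorati matrix + spatiotemporal TV, monotone accelerated proximal gradient |
| `cineflow.unet` | four-class 2D U-Net, soft Dice loss, pseudo-labels by motion-warping manual ED/ES masks |
| `cineflow.training` | photometric + smoothness + Dice losses, the registration → segmentation → joint three-stage schedule |
| `cineflow.function_analysis` | Simpson volumes, EF, Green–Lagrange `E = (∇u + ∇uᵀ + ∇uᵀ∇u)/2`, radial/circumferential projection `Err = rᵀEr`, `Ecc = cᵀEc`, AHA 17-segment bull's eye |
| `cineflow.metrics` | DSC, Hausdorff, mean contour distance, overlap score, NRMSE, SSIM, nonpositive-Jacobian percentage |

The two trainable models are also exposed as scikit-learn-style estimators
(`cineflow.MopnetRegistrar`, `cineflow.UNetSegmenter`) with
`fit`/`predict`/`get_params`.  The networks run on a small self-contained
numpy autodiff engine (`cineflow.nn`) — no GPU framework required.

## Worked example

Generate a phantom, compute volumes, EF and end-systolic strain from the
ground-truth motion, and compare with the imposed contraction:

```python
import numpy as np
from cineflow.phantom import PhantomConfig, generate_cine_phantom
from cineflow.function_analysis import (ventricular_volumes,
                                        ejection_fraction, compute_strain)

gt = generate_cine_phantom(PhantomConfig(grid_size=(64, 64), seed=1))
vols = ventricular_volumes([list(gt.labels)], gt.config.pixel_spacing,
                           gt.config.slice_thickness)
ef = ejection_fraction(vols.lv_edv, vols.lv_esv)
strain = compute_strain(gt.true_flow(0, gt.es_frame), gt.labels[0])
print(f"LVEF {ef:.1f}% (closed form {gt.analytic_ef():.1f}%)")
print(f"mGRS {strain.mGRS:.3f}  mGCS {strain.mGCS:.3f}")
```

```
LVEF 58.0% (closed form 57.6%)
mGRS 0.234  mGCS -0.160
```

The ejection fraction from the discrete label masks lands within half a
percentage point of the analytic value of the imposed contraction.  The
positive global radial strain and negative circumferential strain are the
physiological systolic signatures: the incompressible wall thickens radially
while shortening circumferentially.

Registration and reconstruction, estimator-style:

```python
from cineflow.estimators import MopnetRegistrar
from cineflow.moco import MocoConfig, ktslr_reconstruct

reg = MopnetRegistrar(profile="tiny", steps=300, seed=0)
reg.fit([gt.images.frames])                    # self-supervised: no flow labels
table = reg.predict([gt.images.frames])[0]     # full-cycle frame-pair flows
# motion-compensated reconstruction of undersampled k-space:
# recon = ktslr_reconstruct(kspace_bundle, table.to_reference(0))
```

A full phantom-to-report chain is available from the shell:

```bash
cineflow pipeline --out-dir runs/demo --R 8 --grid 32 --seed 0
```

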