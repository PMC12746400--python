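# Methods

`cineflow` implements a joint framework for ventricular function assessment
from accelerated 2D+t short-axis cine MRI: multi-frame bidirectional image
registration with temporal motion propagation, motion-compensated low-rank +
sparse reconstruction, weakly supervised four-class segmentation, and
automated volumetric/strain analysis.  Because no imaging data ships with the
package, every component is validated against a synthetic deforming cardiac
phantom whose deformation, labels, volumes and strain are closed form.

## The phantom and its ground truth

The phantom emulates one short-axis slice: a bright LV blood pool inside a
myocardial annulus, an adjacent crescent-shaped RV pool, and a static
background.  The deformation is radially organised around the LV centre:

* LV pool (`r <= r_endo`): uniform radial scaling `r' = (1 - alpha(t)) r`.
  `alpha(t) = alpha_max (1 - cos 2 pi t / T)/2`, so frame 0 is end-diastole
  and frame `T//2` end-systole.
* Myocardium and a margin beyond (`r_endo < r <= a`): the area-preserving map
  `r' = sqrt(r^2 - delta(t))` with `delta = r_endo^2 (2 alpha - alpha^2)`.
  The wall thickens as it contracts, giving the physiological signs
  Err > 0 and Ecc < 0 with closed forms
  `Err = delta / (2 (r^2 - delta))`, `Ecc = -delta / (2 r^2)`.
* A linear taper band (`a < r < b`) brings the area deficit to zero (the
  inverse stays a quadratic root); beyond `b` the map is the identity.
* A rigid twist with the same taper is superposed; rotation adds no
  Green–Lagrange strain in the uniformly rotating core.

Both the map and its inverse are closed form, so the dense flow between any
two frames, the per-frame label maps, the LV volume curve
(`EF = 100 (1 - (1-alpha_max)^2)`) and the end-systolic strain fields are
exact.  Flow convention throughout the package: `flow(i, j)` warps frame `j`
backward onto frame `i` (`frame_i(p) = frame_j(p + u(p))`); components are
`(row, col)` in pixel units.

Default study conditions (chosen once; see the limitations section for what
they do and do not represent): 25 cardiac phases, pixel spacing 1.9 mm, slice
thickness 8 mm, `alpha_max = 0.35` (EF ~ 58%, mid healthy range), twist
0.08 rad, additive Gaussian image noise sigma = 0.01 of the intensity scale
(high-SNR bSSFP), a smooth additive material texture of amplitude 0.15 that
advects with the tissue (trabeculation, papillary muscle and chest-wall
structure make real motion photometrically observable everywhere — with a
textureless background the flow there would be unidentifiable), and a static
multiplicative receive-bias field of amplitude 0.15.

K-space is simulated per coil and frame as `mask * F(C * image)` with a
centred orthonormal FFT and analytic smooth complex coil maps.  Undersampling
uses a Cartesian variable-density incoherent ky–t mask: a guaranteed central
ACS block plus per-frame random lines drawn from a centre-weighted Gaussian
density.  At small grids the ACS block is capped at half the per-frame budget;
otherwise the "random" complement vanishes and every frame samples identical
lines, which silently removes the k-t incoherence the reconstruction relies
on.

## Registration network

A recurrent tri-frame optical-flow model.  Five frames form backward
`(I1,I2,I3)`, fixed `(I2,I3,I4)` and forward `(I3,I4,I5)` triplets; the
output maps each fixed frame to its predecessor (`ubwd`) and successor
(`ufwd`).  Components: a shared strided convolutional feature encoder
(instance-normalised; the temporal axis is folded into the batch axis), a
context encoder whose output splits into the GRU initial state and a context
input, dot-product self-attention over the context features, dual all-pairs
correlation volumes (scaled by `1/sqrt(C)`) with an average-pooled pyramid and
windowed lookups around the flow-displaced position, and a motion-propagation
recurrence: each triplet keeps a hidden motion state (all initialised with one
seeded Gaussian draw), the neighbour states are warped into the fixed frame's
domain by the current flows, concatenated with the fixed state, re-encoded
(through depth-wise large-kernel blocks with 1x1 funnel skips), and the warped
states become the next iteration's neighbour states.  A convolutional GRU
decodes residual flows which accumulate from zero — zero refinement
iterations therefore return exactly zero flow.  Residuals are estimated at
feature resolution and upsampled bilinearly.

Two profiles: `default` (downsample 8, 64 channels, 4 pyramid levels,
radius 4, K=6) and `tiny` for CPU-scale experiments (downsample 4,
16 channels, 2 levels, radius 3, K=4).  Channel widths and normalisation are
not uniquely determined by the architecture description and are declared in
the config, not claimed canonical.

Training is self-supervised: L1 photometric loss between the fixed triplet
and the motion-warped neighbours plus lambda1 = 0.04 times the L1 of the flow
gradients, summed without discount over all K iterations.  AdamW
(weight decay 5e-4) with gradient clipping (global norm 1) and cosine
annealing with a 5% linear warmup; the desk-scale profile uses lr 1e-3 over
300 steps (the full-scale default of 1e-4 assumes orders of magnitude more
steps).  Training windows are sampled at temporal strides 3–5: at a 32x32
grid the adjacent-frame motion is below 0.06 px on average, which is beneath
the photometric noise floor, whereas stride 3–5 windows carry up to a half
cycle of motion within one window.  Evaluation of the recovery experiment
follows the same logic (direct forward-pair estimates of stride 4–5 windows
against the zero-flow baseline).

Full-cycle inference slides windows over the cyclic sequence, using only the
forward estimates.  One pass per stride 1..5 with greedy start placement
emits every frame pair at most once; mappings to a chosen reference compose
along the shortest stored-edge path.  Composing adjacent (stride-1) estimates
alone is numerically fragile — sub-pixel per-pair noise compounds over many
hops — so the multi-stride plan keeps reference paths to a few accurate
large-stride edges.

## Motion-compensated reconstruction

The acquired k-space is modelled frame-wise as `y_t = phi_t F C U_t X_t`,
where `U_t` (a sparse bilinear-warp matrix, exact adjoint available) maps the
reference-aligned frame into frame-t geometry.  The aligned sequence is
recovered by minimising the data term plus `lambda_lr` times the nuclear norm
of the Casorati (pixels x frames) matrix plus `lambda_s` times spatiotemporal
total variation — the convex relaxation of the k-t sparsity + low-rank
family, chosen for solver robustness.  The solver is accelerated proximal
gradient (singular-value thresholding and a Chambolle TV prox) with a
monotone restart safeguard, so the recorded objective is non-increasing; a
genuine increase over three consecutive iterations raises an error.  The
step is `0.9 / L` with `L` estimated by power iteration on the
identity-warp and most-deformed frames.  Defaults
`lambda_lr = 0.3, lambda_s = 1e-3, 60 iterations` were tuned on phantom
validation seed 3 and are recorded in `MocoConfig`; they are this package's
choices, not published values.  With accurate motion the aligned Casorati
matrix is near rank one (second singular value < 5% of the first on the
noise-free phantom), which is exactly the regime singular-value thresholding
exploits.

Accuracy budget: with the study-condition phantom at 32x32 and R=8, the
reconstruction beats the zero-filled baseline for mean flow errors up to
roughly 0.8 px and decisively below ~0.4 px.  Flows composed from stride-1
estimates alone exceed this budget; the multi-stride inference plan and, in
the end-to-end pipeline, registration run on the fully sampled training
images (which exist in the retrospective setting) keep the error inside it.
At this grid R=8 leaves only 4 of 32 ky lines per frame — proportionally far
harsher than the same R on a clinical 192-line grid — and self-supervised
registration directly on such zero-filled images is not reliable at desk
scale; this is a deliberate scaled-down surrogate, stated here rather than
hidden.

## Segmentation and weak supervision

A 2D U-Net over four classes (background, LV pool, myocardium, RV pool):
3x3 convolution + ReLU + batch-norm blocks, max-pool downsampling,
transposed-convolution upsampling with skip concatenation, and a 1x1
four-channel head with per-pixel softmax.  The default profile uses five
resolution levels with widths 32..512 and eight encoder conv blocks
(2,2,1,1,2 per level) — the written description of the contracting path
("eight levels", widths 32 to 512) is internally inconsistent, and this is
the resolution adopted; the per-level block counts are configurable.  Inputs
are min-max normalised to [-1, 1] per image; odd sizes are edge-padded
internally.  The soft multi-class Dice loss uses smoothing eps = 1e-5.

Pseudo-labels warp a manual ED or ES mask to unlabelled frames with
nearest-neighbour interpolation along the estimated motion; when both ED and
ES reach a frame the two one-hot maps are averaged into a soft target.

## Three-stage schedule and the joint stage

Stages run registration → segmentation → joint.  The joint loss is
`L_reg + 0.05 L_Dice + 0.04 L_Dice-warp`.  Joint-stage windows always place a
labelled frame first or last (so a manual mask anchors the window), with the
intermediate frames drawn in increasing temporal order.  The reconstruction
sits between registration and segmentation but is treated as a fixed
operator: no gradients flow through the solver, and its output is refreshed
from the current motion estimates at the start of the stage (a configurable
choice that keeps CPU-scale training feasible).  Desk-scale step counts are
150/100/100 (registration/segmentation/joint) in the ablation experiment and
300/200 in the standalone experiments; full-scale defaults follow the
published protocol of the underlying method family (150k/50k/200k) and are
config values only.

The ablation experiment compares, on seeded phantoms at R=8 with manual
labels only at ED and ES: (a) a segmentation-only baseline trained on
zero-filled images, against (b) the joint variant — registration,
motion-compensated reconstruction, then joint optimisation with pseudo-label
supervision — evaluated as LV blood-pool Dice over all frames against the
phantom truth.

## Functional analysis

Volumes are Simpson-style sums (pool pixel count x pixel area x slice
thickness); ED/ES are the frames of maximal/minimal LV volume;
`EF = 100 (EDV - ESV)/EDV`.  Strain uses the Green–Lagrange tensor
`E = (grad u + grad u^T + grad u^T grad u)/2` of the ED→frame displacement
(central differences, physical spacing).  The local frame comes from the ED
epicardial contour: radial unit vectors point from the contour's centre of
mass through each pixel (the contour definition extended inward by angle) and
circumferential vectors are their 90° counter-clockwise rotation;
`Err = r^T E r`, `Ecc = c^T E c`, with global mGRS/mGCS the myocardial means
at end-systole over all slices (an all-slice mean is one of two defensible
readings and is labelled as such in outputs).  The 17-segment map uses
6 basal + 6 mid + 4 apical sectors plus the apex, slices split into thirds by
position, with the angular origin at the anterior RV insertion derived from
the RV mask.  Segments without myocardial pixels are reported as missing
(NaN), never as zero.

## Numerical and engineering choices

* No GPU framework is assumed: the trainable models run on a small in-repo
  reverse-mode autodiff engine over numpy (float32), with convolution
  implemented as shift-and-accumulate BLAS products, bilinear warping and
  point sampling differentiable in both image and coordinates, and AdamW +
  cosine schedule as the optimiser.  Gradients were verified against central
  differences for every structured op.
* Edge-clamped sampling everywhere (warping, correlation lookup): the cine
  background is static, so replicating the border avoids spurious
  photometric loss at the frame edge.
* Jacobian determinants use central differences in the interior and
  one-sided differences at the borders; the folding metric is the percentage
  of pixels with `det(I + grad u) <= 0`.
* Empty-mask conventions: Dice of two empty masks is 1; boundary distances
  for an empty mask are undefined and reported missing.
* All randomness (phantom, masks, coil maps, weight init, samplers) flows
  from explicit integer seeds; repeated runs are bit-identical.

## What the phantom does and does not establish

Passing the phantom suite shows the operators are mathematically correct
(adjoints, closed-form strain, metric conventions), that self-supervised
training recovers imposed motion under realistic contrast and noise, and that
motion compensation recovers image quality that zero-filling cannot.  The
phantom does not model bSSFP banding, B0/B1 inhomogeneity, through-plane
motion, arrhythmic cycles, or pathological wall-motion patterns; desk-scale
grids (32–64 px) make R=8 proportionally harsher than on clinical grids; and
the tiny training profiles are orders of magnitude below a full run.  Results
on real cine data are therefore not implied — the phantom establishes
component correctness and the direction of the framework's benefits, not
clinical performance.
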