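# Methods

This note documents the models, algorithms and numerical choices behind
`dosewarp`, what the synthetic data emulates (and does not), and the
parameters that matter.

## Registration model

Both the fixed image `I_F` (reference, the last brachytherapy session) and
the moving image `I_M` are scalar 3D volumes on a common grid with
anisotropic voxel spacing in mm.  A displacement field `u` (mm, stored on
the fixed grid) acts by backward (pull) warping: the registered image is
`I_M ∘ φ` with `φ(p) = p + u(p)`, sampled trilinearly with
clamp-to-border.

### Mix-transformer network (MTDIR)

1. **Encoders.**  Two separate (non-weight-shared) CNNs, one per image:
   four 3×3×3 convolution stages with LeakyReLU(0.2), strides 2×2×s_z,
   giving ×16 in-plane downsampling and a configurable through-plane factor
   (default 4, chosen because through-plane resolution is typically coarser
   — 2.5–5 mm slices).  Default channel widths (16, 16, 32, 32).  The two
   encoders start from identical initialization (their weights diverge
   freely during training): fixed and moving features then live in a common
   basis, so attention scores and the decoder's skip comparisons are
   meaningful from the first optimizer step — with independent
   initializations the plateau before the similarity loss starts falling is
   markedly longer and seed-dependent.
2. **Tokens.**  The feature maps are flattened row-major over the token
   lattice (e.g. 48×48×32 voxels → 3×3×8 = 72 tokens), linearly projected
   to the embedding dimension d (default 256) and fused with a learned
   positional table by element-wise summation.
3. **Cross-attention.**  The moving image supplies queries, the fixed image
   keys and values: `A = softmax(Q Kᵀ/√d) V` with 1/√d scaling (a single
   head, single layer).  The correlation features passed to the decoder are
   the fused tokens `M = A + Q`: the residual keeps the moving image's own
   spatial embedding available to the decoder.  Without it, the softmax is
   nearly uniform early in training, every token receives the same mean
   value vector, and the decoded field cannot acquire spatial structure —
   in ground-truth probes the cosine similarity between the predicted and
   true field stalls near 0.15, versus ≈0.8 with the residual.
4. **Decoder.**  `M` is un-flattened to the token lattice and upsampled by
   transposed convolutions that mirror the encoder strides, with
   kernel = stride (non-overlapping, checkerboard-free synthesis — each
   output voxel inside an upsampling block is a learned function of its
   parent feature).  After every upsampling stage except the last, the
   fixed and moving encoders' features at the matching resolution are
   concatenated and merged in through a zero-initialized 1×1×1 adapter
   convolution (the conv-encoder / transformer-bottleneck / skip-decoder
   layout standard in transformer registration networks; zero-initialized
   so the skips switch on as training needs them instead of perturbing the
   early field).  The skips are essential at this
   scale: one token per 16×16 in-plane patch carries no millimetre-level
   phase, and without direct access to fine image structure the decoder's
   training loss plateaus at the unregistered pair's value, while the
   skip-connected decoder recovers held-out deformations (endpoint error
   below the zero field on 10/10 test pairs).  A zero-initialized 1×1×1
   head emits 3 channels, scaled by a fixed gain `flow_scale` (default
   20 mm per unit activation), and a fixed Gaussian smoothing stage
   (σ = 2 voxels, zero-padded, hence exactly self-adjoint) produces the
   final field.  Zero initialization makes the initial transform the
   identity, so training starts from the raw pair's similarity.

The output gain and the smoothing stage exist because of the optimization
regime, and both were validated against known truth fields: Adam moves each
weight by at most ≈lr per step, so with a small step budget the field could
otherwise never reach millimetre scale; and without the smoothing stage both
networks reduce the loss with high-frequency, non-physical fields whose
endpoint error exceeds the zero field's.

### CNN baseline

A VoxelMorph-style comparator: the two images are concatenated as channels
and passed through a small U-Net-style encoder–decoder (strided convolutions
down, transposed convolutions up, one additive skip at half resolution),
ending in the same zero-initialized scaled head and smoothing stage.  It
shares the warp and the losses and serves as the "VoA" backend in dose
accumulation.

### Loss

`L = −LNCC(I_F, I_M∘φ) + λ · Lsmooth(u)`.

* **LNCC** — squared local normalized cross-correlation over cubic windows
  of edge n = 9 voxels, computed with box-filter sums (zero-padded window
  sums with the full n³ normalization).  The per-window correlation is
  squared, making the score sign-invariant and bounded in [0, 1]; the
  denominator is stabilized with ε = 1e-5, which also defines the
  correlation of locally constant windows as 0.
* **Lsmooth** — the diffusion regularizer, squared spatial gradients of all
  three field components.  Gradients are central differences with one-sided
  boundary stencils, in mm per voxel step.  The training loss uses the mean
  over voxels and components so that λ = 1 (the default) is independent of
  grid size; the raw sum is also available.

Both terms have analytic gradients (box-filter algebra for LNCC; the exact
adjoint of the difference stencil for the regularizer; trilinear-weight
derivatives for the warp), each verified against central finite differences
in the test suite.

### Training

Adam, batch size one volume pair, all randomness from a single seed.  The
published recipe (learning rate 1e-4, up to 400 epochs, five-fold
cross-validation with selection by highest validation score — mean organ
DSC when masks are available, otherwise lowest validation loss) is the
`TrainConfig` default.  The *desk-scale benchmark* used by the test suite
and the acceptance script trains on 20 synthetic pairs for 100 epochs with
learning rate 1e-3 and a single fold: at ≤2000 optimizer steps the 1e-4
rate cannot move the zero-initialized head far enough to express
millimetre-scale fields (a budget consideration, not a property of the
model; the published default remains 1e-4).  Training shows a
characteristic plateau near the unregistered pair's loss before the
similarity term starts falling; the initialization choices above shorten
it, and the 100-epoch budget leaves room for the descent phase.

## Dose accumulation

* **EQD2.**  Per-fraction physical doses are converted voxelwise with the
  linear-quadratic model, `EQD2(p) = N · d(p) · (d(p) + α/β)/(2 + α/β)`,
  α/β = 3 Gy (late-responding normal tissue), N identical fractions per
  plan with the plan's own anatomy assumed stable across its fractions.
  2 Gy per fraction is a fixed point: EQD2 equals physical dose.
* **Warping.**  EQD2 grids are pull-warped into the last-ICBT frame by
  trilinear interpolation, treated as point quantities — no Jacobian
  (mass/energy) correction.  This is the dominant clinical convention; it
  conserves local dose values, not integral energy, which is a known
  limitation wherever the field compresses or expands tissue.
* **Topology.**  Each moving frame is registered directly to the last ICBT
  session (star topology), not chained through intermediate sessions.
* **DVH.**  DxCC sorts in-mask voxel doses descending and reads the dose at
  which the accumulated voxel volume reaches x cm³, linearly interpolating
  between the straddling sorted voxels (an integer-voxel mode exists; the
  difference matters for sub-voxel volumes like D0.1cc on coarse grids).
  V50 is the percentage of in-mask voxels at or above 50 Gy.
* **Addition strategies.**  DA sums per-plan D-metrics computed on each
  plan's own frame (the worst-case convention: it assumes all hotspots
  coincide).  How a DA V-metric should be defined across frames is not
  established; `direct_addition` therefore reports V50 as undefined, and
  the course-level helper computes it from the unwarped voxel sum, which is
  well-defined here because all synthetic frames share one grid.  MA and
  VoA are deformation-based accumulation with the mix-transformer and the
  CNN baseline respectively.

## Evaluation

DSC is `2|A∩B|/(|A|+|B|)`.  Surfaces are mask voxels with at least one
6-neighbour outside the mask (grid-border voxels count), with coordinates
in mm.  HD is the symmetric Hausdorff distance; HD95 and HDmean are the
95th percentile and mean of the *pooled* two-directional nearest-point
distances, which keeps them symmetric (a directed variant is available by
flag).  Percentiles interpolate linearly between order statistics.
Registration reports are stratified into EBRT-vs-last-ICBT and
other-ICBT-vs-last-ICBT blocks, with before-registration rows included.

Statistics: the Friedman test on the cases × methods matrix (mean ranks for
ties, chi-square approximation with the standard tie correction, agreeing
with reference implementations to 1e-8), followed by paired two-sided
Wilcoxon signed-rank tests per method pair at a Bonferroni-adjusted
threshold α/n (0.05/4 = 0.0125 for four methods; zero differences dropped).
The phrase "paired rank-sum" in the source literature is contradictory
nomenclature; the signed-rank test is what paired data admit.

## Synthetic data

The generator emulates one patient "course": a base pelvic phantom
(ellipsoidal bladder, cylindrical rectum, smoothed-noise texture, arbitrary
intensity units — LNCC is invariant to intensity scale), inter-fraction
anatomy created by pull-warping the base phantom through smooth random
fields (per-axis white noise, Gaussian-smoothed at the requested
`smoothness_sigma`, tapered to zero on the grid boundary, rescaled to the
requested maximum `amplitude`; positive Jacobian determinant for amplitudes
small relative to the smoothness), an EBRT-like per-fraction dose (sigmoid
plateau, 50.4 Gy/28 fractions default) and ICBT-like doses (inverse-square
around a line applicator with the radius clamped at one voxel spacing,
scaled to 6 Gy at a 10 mm prescription distance).

For a registration pair the base phantom is the *moving* image and the
fixed image is the phantom resampled through the stored field, so the truth
is exactly the pull field training should recover.  Course frames are all
independently deformed versions of one base phantom; frame-to-frame truth
fields are then only available approximately (fixed-point composition of
the stored per-frame fields).

What this does *not* emulate: CT artifacts and Hounsfield calibration,
applicator geometry and its deformation, sliding organs and topology
changes, intensity differences between modalities/sessions, and realistic
organ-shape variability.  Passing tests therefore demonstrate that the
algorithms are implemented correctly and can recover known smooth
deformations at the stated noise level — not clinical registration
accuracy.

## Problem sizes and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| Grid / spacing | 48×48×32 at 2×2×4 mm | desk-scale pelvis-like volume, anisotropic like clinical slices |
| Deformation amplitude | 4 mm | bladder-filling/regression scale at desk resolution |
| Smoothness σ | 12 mm | organ-scale smooth anatomical change |
| LNCC window | 9³ voxels | published similarity window |
| λ (smoothness weight) | 1.0 | with the mean-normalized regularizer |
| α/β | 3 Gy | late normal-tissue endpoint |
| d (embedding) | 256 | capacity vs. 72-token lattice |
| flow_scale | 20 mm | field reach within the step budget |
| field smoothing σ | 2 voxels | matches deformation smoothness at desk spacing |
| Benchmark | 20 train / 10 test pairs, 100 epochs, lr 1e-3 | minutes on one CPU core |

Determinism: all generators and training draw from explicit seeds;
single-threaded numpy arithmetic makes reruns bit-identical.

## Known limitations

* No direction cosines or origins in the grid model; world coordinates are
  `index · spacing`.
* Dose warping without Jacobian correction (point-dose convention).
* The inverse-square ICBT kernel is a geometric emulation, not TG-43
  dosimetry.
* Half-resolution effective capacity of the field decoders; very sharp or
  sliding deformations are outside the representable family.
* The attention layer is single-head and single-layer by design; the token
  lattice is coarse (one token per 32×32×16 mm at default settings).
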