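# Methods

This note documents the model, the numerical choices, the calibration of
the architecture against its published complexity budget, and what the
synthetic-data experiments do and do not demonstrate.

## Compute core

All tensor computation runs on a small reverse-mode automatic
differentiation core written on NumPy (`mgraunet.tensor`).  Convolutions
are stride-1, zero-padded "same" cross-correlations evaluated by
im2col + BLAS matmul, with a vectorised depthwise path; downsampling is
2×2 max pooling, upsampling is bilinear interpolation with half-pixel
centres expressed as two cached 1-D interpolation matrices (so its
adjoint is exact).  Backward passes are verified against central finite
differences in float64 (`tests/test_autograd.py`).  Production arrays
are float32.

## Network

Six encoder stages at widths {8, 16, 32, 64, 88, 128}; stage *s* runs at
1/2^(s−1) of the input resolution (inputs must be divisible by 32).
Stage blocks are Conv3×3–BN–ReLU; stages 5–6 carry a second conv.  The
decoder mirrors the encoder with bilinear 2× upsampling, a 1×1 channel
projection, additive skip fusion and a depthwise-separable conv block
per stage (dense and concatenation variants are config flags).  A 1×1
head produces single-channel logits; sigmoid/thresholding at 0.5 happen
in the loss/metrics, not in the network.

### Module placement and the complexity budget

The published budget for this family is ~7.18 M parameters and ~0.97 G
FLOPs at 256×256 for the default model, 26.50 M / 3.66 G for the
{16, 32, 64, 128, 160, 256} channel variant, 9.50 M for the
{13, 19, 25} strip-kernel variant, and ~31.04 M for the classical
U-Net baseline.  Three printed numbers jointly over-determine the strip
wiring: the parameter difference between the {9,15,21} and {13,19,25}
strip sets (~0.193 M per unit of summed kernel size) would alone imply
8.7 M of strip parameters in a 7.18 M network, so no wiring reproduces
all printed values exactly; the stated tolerances (5 % on parameters,
15 % on FLOPs) are attainable and are what the package calibrates to.

The calibrated default, fixed by a closed-form search over the placement
and wiring flags that the config exposes:

- MGHF instances at the two coarsest scales only: encoder stages 5 and
  6, the stage-5 skip path, the bridge entry (before MGRA), and decoder
  stages 5 and 6 (the decoder "stage 6" block sits between the bridge
  attention and the first upsampling).  Placing dense strip convolutions
  at stage 4's resolution would exceed the FLOP budget, which is why the
  spatially cheap stages carry them.
- Strip pairs are dense: K×1 carries the channel mapping (C→C), 1×K is
  depth-preserving (C→C), one order per branch.
- Square convolutions inside in-network MGHF are depthwise.  Dense 3/5/7
  squares at these widths alone cost ~6 M parameters, incompatible with
  the total; the standalone `MGHFConfig` default remains dense and the
  closed-form parameter formula is tested for both modes.
- DGPS at stages 4–6 (encoder) and 4–5 (decoder); MGRA at the bridge.

Measured: default 7.35 M / 1.05 G; large-channel 27.63 M / 3.72 G;
wide-strip 9.08 M; U-Net baseline 31.04 M — all within the stated
tolerances (`scripts/acceptance.py` recomputes them).

FLOP convention: 1 MAC = 1 FLOP; convolution, transposed-convolution and
fully connected layers only; BN, activations, pooling and resampling
excluded.  Counts are taken from a traced forward pass so every layer is
measured at the resolution it actually sees, and the convention string
is embedded in every report.

## Blocks — resolved design points

- **MGHF** follows its defining equation literally: a purely linear
  block (no internal BN/activation; `with_norm_act` adds them), which
  makes homogeneity and the separable-kernel identity exactly testable.
  The residual projection is 1×1.  Branch weights are scaled by
  1/√(#branches) at init so the summed branches do not inflate the
  activation variance of deep stacks.
- **DGPS** partition policy (not specified by the defining equations):
  a one-level variance quadtree — start from a 2×2 grid, subdivide any
  region whose value variance exceeds the mean variance of the current
  regions, minimum region side 2, at most 16 regions; a uniform grid
  policy exists for ablation.  Maps too small to split fall back to a
  single region (logged).  Cosine similarity is taken between
  channel-mean descriptors (region shapes differ, so the raw matrix
  product of regions is ill-posed); mixing across unequal shapes uses
  bilinear resize to the receiver's shape (identity when shapes agree).
  "Concat" of refined regions is spatial reassembly into the original
  layout — the only reading consistent with the residual sum with the
  block input.  The residual uses the block input, and the fusion is
  ReLU(BN(Conv1×1(·)) + X).  Zero-norm descriptors get similarity 0 to
  all others and 1 to themselves rather than a division failure.
- **MGRA**: RCA and RSA run in parallel on the same bridge feature.
  The bound-mixing scalars α₁, β₁, α₂, β₂ are learnable, initialised to
  0.5 (no values are published; a symmetric learnable scalar subsumes
  any fixed choice).  RSA follows its printed equations, which contain
  ReLU but no sigmoid (`rsa_sigmoid` adds one); its 7×7 convolution is
  stride-1 so the upsampling step is the identity (a stride-2 +
  bilinear-2× variant is a flag).  The channel-descriptor naming
  inconsistency between the pooling and MLP equations is treated as a
  notation slip (same quantities).  The fusion head is
  2C → max(2C/16, 4) → 2 with inner ReLU and softmax output, mirroring
  the r = 16 channel reduction.

## Objective and metrics

BceDice = α·BCE + β·Dice with α = β = 1.  Predictions are clipped to
[10⁻⁷, 1−10⁻⁷] before the logarithm; the Dice ratio carries ε = 10⁻⁶ in
numerator and denominator so empty-mask batches stay finite (effect
< 10⁻⁵ on non-empty masks).  Metrics are the five standard ratios of the
pixel confusion table.  Zero-denominator conventions: a ratio is 1 when
both masks are empty, 0 when exactly one is; every degenerate case is
logged.  Dataset results are computed per image and averaged (the
common convention for these benchmarks; pooling pixels instead would
change the third decimal).

## Data pipeline

Images are resized bilinearly and masks by nearest neighbour with
re-binarisation at 0.5 (deterministic across interpolation backends).
Splits: validation and test take ⌈n·ratio⌉ samples each, training the
remainder, assignment by a seeded permutation (so 37 samples at
80/10/10 give 29/4/4); identifiers partition exactly across splits.
Augmentation applies one rotation uniform in ±90° and horizontal/
vertical flips with p = 0.5 each, identically to image and mask, with
mask re-binarisation after interpolation; rotation ranges and flip
probabilities are config fields since no canonical values exist.
Validation and test data are never augmented.

## Synthetic generator

Each image is a mucosa-toned background (per-image colour jitter plus
Gaussian-smoothed low-frequency texture, σ = 6 px, intensity std 10)
with 1–2 lesions: rotated ellipses with aspect ratio in [0.6, 1.6],
boundary deformed by radial harmonics of order 2–4 (amplitude ≤ 0.07),
area drawn from a 2–25 % fraction of the frame, and a configurable mean
intensity offset (default 25/255 — visible but well inside the
background dynamic range) feathered on the image side while the mask
remains the exact pixel support.  Generation is bitwise deterministic
per seed.

The generator emulates the statistical difficulties of polyp data — low
contrast, morphological variety, ambiguous boundaries — not endoscopic
optics (no specular highlights, vignetting, instruments, depth or
motion blur).  Passing the training smoke check therefore shows the
pipeline optimises and generalises on this family of images; it says
nothing quantitative about real-dataset scores, which additionally need
the public benchmarks and GPU-scale training.

## Training

AdamW (lr 10⁻³, weight decay 10⁻², batch 8) with cosine annealing to
the epoch horizon (no restarts), BceDice loss, best checkpoint by
validation DSC, no early stopping by default.  A non-finite loss aborts
with the last good checkpoint restored.  Runs are fully seeded and
reproducible to the float32 ulp.

Problem sizes: the shipped smoke experiment trains the full default
network on 200 synthetic 64×64 images (160/20/20 split) for up to 30
epochs, stopping early once validation DSC reaches 0.92, without
augmentation — the regression bound is about optimisation of the
network itself, not augmentation robustness.  These sizes keep the
experiment a desk-scale CPU run while still exercising every module.

## Known limitations

- The quadtree partition makes DGPS's structure data-dependent, so the
  loss surface has (rare) discontinuities when a region's variance
  crosses the split threshold; training is empirically unaffected.
- BN layers use per-batch statistics in training and running statistics
  in inference; tests pin them to fixed statistics for determinism.
- Single-accelerator, binary segmentation only; no pretrained backbones.
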