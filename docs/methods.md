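# Methods

This note records the models implemented by `glandseg`, the parameters that
matter, the numerical choices made where the design was open, and what the
synthetic benchmark does and does not demonstrate.

## Stain model

Transmitted light through an H&E section follows the Beer–Lambert law, so
stains are additive in optical density. We use

    OD = −log10((v + ε) / (bg + ε)),  bg = 255, ε = 1,

so a pixel at the background intensity maps to OD 0 exactly and v = 0 stays
finite. The inverse transform rounds back to 8-bit; round trips are exact to
±1 intensity level.

The two-stain decomposition `OD ≈ C·M` is fitted on tissue pixels only
(OD norm ≥ 0.15 — near-white pixels carry no stain signal), subsampled to at
most 5000 pixels so fitting cost is independent of tile size. The basis `M`
comes from seeded sparse dictionary learning with two atoms constrained
non-negative (sparsity weight 0.1 by default; coordinate-descent fitting).
Factorization is unique only up to row permutation; we fix the order by the
hematoxylin convention: the row with the larger blue-channel OD component is
hematoxylin (hematoxylin absorbs blue light more strongly than eosin, cf.
the classical absorption directions H ≈ (0.65, 0.70, 0.29),
E ≈ (0.07, 0.99, 0.11)).

Densities are the exact per-pixel non-negative least squares against `M`.
For two stains NNLS has a closed form — take the unconstrained normal-
equation solution and, where a coordinate is negative, the better of the two
clamped single-stain projections — which vectorizes over all pixels and
reproduces exact compositions to 1e-4.

Normalization rescales each density channel so its 99th percentile matches
the target's (a robust scale statistic; the maximum is noise-dominated) and
re-renders with the target basis. Self-normalization of a synthetic tile
perturbs it by ≈1.6 mean intensity levels; the residual is the rank-2
approximation error plus 8-bit rounding.

## Ground-truth derivation

Conventions, fixed once and used everywhere: rasters are row-major and
0-based; *boundaries* use 4-connectivity with outside-the-frame counting as
background; *connected components* use 8-connectivity; a contour of
thickness t is the boundary pixels dilated t−1 times with a 3×3 cross.
Default contour thickness is 2 px at the 480×480 working resolution — thick
enough that two dilations reliably split touching instances, thin enough to
cost little boundary detail. Contour pixels of adjacent instances are both
marked, so subtracting the contour from the object mask separates them.

The three-way partition is: white = gray luma (ITU-R 601) above 220;
gland = annotated instances (precedence over white, so lumina inside
annotated glands count as gland); stroma = everything else. The partition is
exact by construction and the synthetic generator reproduces it through the
derivation path with >99 % per-class pixel agreement.

## Network

The encoder follows the DenseNet layout: stem (7×7 stride-2 convolution,
batch norm, ReLU, 3×3 stride-2 max pool — total /4), four dense blocks with
bottleneck layers (BN→ReLU→1×1 conv to 4g channels→BN→ReLU→3×3 conv to g
channels, output concatenated to the block state), and transitions (1×1
conv halving channels + 2×2 stride-2 average pooling). With the default
[6, 12, 32, 32] blocks and growth rate g = 32 the channel sequence is
64 → 256/128 → 512/256 → 1280/640 → 1664, i.e. the Dense-169 arithmetic.

Because the stem downsamples by 4, each decoder has five stages — one more
than there are dense blocks. A stage is a reverse transition (1×1 conv to
the stage width, bilinear ×2 upsampling) followed by a 3×3 convolution over
the concatenation with the equal-resolution encoder output (block 3, block
2, block 1, the stem activation, then no skip at full resolution). Decoder
widths default to (256, 128, 64, 32, 16); the tiny benchmark model uses
(32, 16, 16, 8, 8). The two decoders share no weights. All convolutions use
He-normal initialization; an optional hook can load pre-trained encoder
weights from an `.npz` file, but nothing in the package depends on it.

The engine underneath (`glandseg.nn`) is a small reverse-mode autodiff on
float32 NumPy arrays. Convolutions are computed as sums over kernel offsets
of strided-slice × weight-matrix BLAS products — no im2col buffers — and
bilinear resizing uses separable dense 1-D operators, so the backward pass
is the exact transpose. Gradients are verified against central differences
in the test suite.

## Training

Loss: `α·BCE(object) + (1−α)·BCE(contour) + λ‖w‖²` with α = 0.5 and
λ = 1e-4. BCE is computed from logits in training (numerically stable) and
from clamped probabilities (ε = 1e-7) in the public scalar API; the L2 term
covers convolution kernels only, not batch-norm parameters. Optimizer: Adam,
lr 1e-3, β = (0.90, 0.99). An epoch is 200 mini-batches of 4 sampled *with
replacement* (epochs are step-based, not dataset passes). The plateau rule
halves the learning rate after exactly 5 consecutive epochs without
validation improvement; the checkpoint with minimum validation loss is
returned. The 80/20 train/validation split is seeded and stratified on the
generator's benign/malignant morphology tag, mirroring a class-balanced
split.

Augmentation draws one spatial transform per sample — horizontal/vertical
flips (p 0.5 each), rotation up to ±45° (p 0.5), perspective jitter of the
tile corners up to 5 % (p 0.25), elastic displacement (Gaussian-smoothed
field, σ 8 px, amplitude 10 px, p 0.25) — applied identically to the image
(bilinear) and both masks (nearest, so masks stay binary), plus image-only
Gaussian noise (σ 5, p 0.25). The random stream is consumed in a fixed
order regardless of which transforms fire, so per-seed outputs are stable.
Images are resized bilinearly and masks by nearest neighbour; per-channel
mean/sd standardization uses population statistics over all training pixels.

## Post-processing

Thresholds default to 0.5 for both maps (they are free parameters; nothing
in the method fixes them). "Two concurrent dilations" of the binary contour
is implemented as 2 iterations with the 3×3 cross. After multiplying the
dilated contour into the object mask and labelling, the boundary band that
the contour removed is returned to the objects by nearest-seed assignment
(taxicab distance, capped at 3·(iters+1)): this recovers exactly the
removed object pixels, never grows beyond the thresholded object mask, and
resolves ties between adjacent glands by proximity. With an empty contour
map the result therefore equals the connected components of the thresholded
object map.

The stroma path inverts the thresholded stroma map and removes white pixels
(gray > 220 on the tile) before labelling — white lumina removed along with
the background are restored by hole filling. Small-component removal
(default min_area 200 px at 480×480, scaled to 50 px for 128×128 tiles)
acts on connected components of the *binary* mask, so a gland ring carrying
several instance labels is kept or dropped whole; hole filling then works
on the union with filled pixels assigned to the nearest label, so a lumen
enclosed by fragments of one ring still fills. Both operations together are
idempotent.

The CRF runs last, on the cleaned binary mask encoded as foreground
probability 0.9/0.1 (saturated unaries would freeze the labeling; this
level lets the pairwise terms correct thin errors while preserving
confident regions). Mean-field updates use a Potts model with two Gaussian
kernels: appearance (spatial σ 20 px, color σ 13 levels, weight 10) and
smoothness (spatial σ 3 px, weight 3), 5 iterations. The appearance kernel
is evaluated with a splat–blur–slice bilateral grid (nearest-cell splat,
σ = 1 cell blur) — an approximation that is accurate at the kernel widths
used and costs O(pixels). The refined map is binarized at 0.5 and instance
labels are carried over by nearest-seed assignment.

## Metrics

Dice is computed on whole-tile binary masks; when both masks are empty it
is reported as 1.0 with an `empty` flag. Hausdorff distance is computed
between boundary pixels (4-connectivity, frame counts as background) via an
exact Euclidean distance transform; `symmetric` (max of both directed
distances) is the default and the mode is recorded in every report, as is
the resolution, since pixel distances are resolution-bound. Equivalence
with the exhaustive all-pairs definition is asserted in the tests (exact
for Dice, 1e-9 for Hausdorff).

## Synthetic tissue and the desk-scale benchmark

The generator emulates the geometry that the method exploits: glands are
ellipses perturbed by 2 radial harmonics (3–5 cycles; amplitude 0.05 for
benign-like, 0.16 for malignant-like morphology) with a concentric lumen of
35 % gland area; the epithelium carries hematoxylin density 1.0 (±15 %
pixel noise) and light eosin; the stroma carries eosin density 0.55
modulated by anisotropic band-pass texture (clipped to 0.6–1.4×) and light
hematoxylin; one white background blob is always present. Rendering is
OD = C·M with the classical H&E basis plus Gaussian intensity noise (σ 3).
Glands are placed by rejection sampling with a 4-px stroma margin, so the
ground truth is exact and every tile contains all three tissue classes.

The benchmark trains the reduced network ([2, 2, 2, 2], growth 8, 128×128)
on 200 tiles of 4 glands (radius 10–20 px) for 5 epochs × 10 steps and
evaluates on 20 tiles from a disjoint seed range. Both approaches reach
Dice 1.0 / Hausdorff 0 after post-processing. That ceiling is a property of
the task, not evidence about real tissue: synthetic classes are separable
almost purely by stain color, glands never touch, stroma texture is
stationary, and there are no nuclei, scanner artifacts, mucin pools, or
annotation noise. What the benchmark *does* establish is that the whole
chain — stain model, target derivation, dense encoder/dual decoder
learning, contour fusion, stroma inversion, cleaning, CRF, metrics — is
wired correctly end to end, that both approaches converge from He
initialization on a CPU in minutes, and that their outputs agree (mutual
Dice 1.0 here). Performance on real colon or breast tissue requires
training the full-size model on real annotated data.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; full-size 480×480
  training is possible but impractical — the package targets desk-scale
  experiments and full-size inference (a 480×480 forward pass takes tens of
  seconds).
* The bilateral-grid CRF approximation uses nearest-cell splatting;
  kernel-width ratios below ~3 px of spatial σ lose accuracy.
* The stain model assumes exactly two stains; tiles dominated by a single
  stain raise an error rather than returning a degenerate basis.
* Stroma masks derived by thresholding inherit any white-threshold
  misclassification (e.g. very pale stroma); 220 is a reasonable default
  for well-stained H&E but is exposed in the config.
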