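# Methods

`hahnfusion` fuses co-registered multi-modal brain images (a grayscale
structural modality such as MRI/CT and a pseudo-colored functional modality
such as SPECT/PET) by letting the sources compete block-by-block inside the
feature space of a small convolutional autoencoder. This note records the
model, the numerical choices, and what the synthetic test world does and
does not establish.

## Pipeline overview

1. **Feature extraction.** Each input (grayscale replicated to 3 channels)
   passes through three stride-1 convolutions — 64 kernels of 7×7 (pad 3),
   5×5 (pad 2), 3×3 (pad 1) — each followed by ReLU. Stride 1 with "same"
   padding means no spatial information is discarded at any depth.
2. **Block competition.** The 64-channel stacks are collapsed to an
   activity image (mean absolute activation over channels), tiled into D×D
   blocks (zero fill bottom/right, stripped after fusion), and each block
   is transformed into 2-D Hahn moments. The block's *potential energy*
   `PE = Σ_{u,v} |H_uv − H_00| / √(u² + v²)` (0-based orders, the singular
   leading term defined as 0) measures how much moment energy sits away
   from the leading moment — flat blocks score ≈ 0, textured blocks score
   high. PE maps are jointly min–max normalized across sources and fed as
   stimuli to one pulse-coupled neural network (PCNN) per source, one
   neuron per block, with per-block link strengths from a saliency map.
   The source whose neuron fires most over the run wins the block and its
   features are copied across all channels; exact ties take the
   element-wise maximum of the tied blocks, which keeps the rule symmetric
   in its inputs and idempotent (`fuse(A, A) = A` exactly).
3. **Reconstruction.** A 3×3 convolution (64 kernels) plus a 1×1
   convolution down to 3 channels, ending in a sigmoid, maps the fused
   features back to an image in (0, 1).

Three or more modalities are handled identically: features are extracted
per source in parallel and the per-block argmax simply runs over k sources,
so there is no cascade of pairwise fusions and no order dependence.

## Hahn basis: numerics

The regularized Hahn functions h̄_n(x) (support 0..N−1, parameters
α, β > −1) form an orthonormal basis, so the 2-D moment transform conserves
energy (Parseval) and inverts exactly at full order.

Two construction paths exist:

- **Reference (oracle):** the literal Rodrigues-type closed form evaluated
  with log-gamma arithmetic. Each surviving term of the n-th backward
  difference has all-positive gamma arguments, so signs are exactly
  (−1)^k; alternating cancellation limits this to N ≲ 20. We verified
  numerically that the printed normalization d_n² is the exact squared
  norm: the closed-form table is orthonormal to machine precision.
- **Production:** Golub–Welsch. The weighted orthonormal values
  φ_n(x) = p_n(x)√ρ(x) satisfy a symmetric three-term recurrence whose
  Jacobi matrix has eigenvalues exactly 0..N−1 and unit eigenvectors equal
  to the basis columns. `scipy.linalg.eigh_tridiagonal` therefore yields a
  table orthonormal by construction for N = 256 and beyond; the per-column
  sign ambiguity is resolved by h̄_0(x) > 0 (the square-root weight is
  positive). A naive forward recurrence in n was tried first and loses
  orthogonality catastrophically (Gram deviation ~24 at N = 64 with skewed
  weights), which is why production diagonalizes instead. The two paths
  agree to ~1e−12 for N ≤ 16, including sign.

Defaults: α = β = 0 (symmetric weight). The fusion literature rarely
states its (α, β); the symmetric choice is least informative and is
exposed in `HahnParams`/`FusionJob` for anyone wanting end-weighted bases.

## Simplified PCNN

Per iteration n (fully synchronous; Y(0) = 0, θ(0) = θ0):

    L = W * Y(n−1)          (3×3 zero-center kernel, zero-padded borders)
    U = S · (1 + β L)
    θ(n) = e^{−α_T} θ(n−1) + V_T · Y(n−1)
    Y(n) = [U ≥ θ(n)]

Defaults: α_T = 0.2, V_T = 20, θ0 = 1, n_iter = 200, W = inverse-Euclidean
8-neighbour kernel. Large V_T enforces a long refractory gap (one pulse per
threshold reset); 200 iterations give stimuli in [0, 1] room for several
firing cycles so counts order stimuli totally. The "firing times" record is
the cumulative count (first-fire iteration is also returned); counts give
the total ordering the selection rule needs. With zero stimulus the
threshold decays but never reaches zero, so such neurons never fire.

The link strength β comes from a complexity-weighted saliency proxy:
min–max normalized product of local intensity entropy (7×7 window, 32 gray
bins) and Gaussian-smoothed (σ = 2 px) Sobel gradient magnitude, averaged
per block. The original complexity-weighted saliency model is not fully
specified in the fusion literature we follow; this proxy keeps its intent —
textured, high-contrast regions couple more strongly — and is pinned here
as the package's definition. A constant image gets uniform zero saliency.

## Losses and training

`L_total = L_ce + (1 − MS-SSIM) + L_tv`, unweighted by default
(weights configurable):

- Cross-entropy, pixel-wise, inputs clamped to [1e−7, 1−1e−7],
  mean-reduced (a raw-sum mode retains the literal formula). Its minimum
  over the output is at O = I and equals the binary entropy of I — not
  zero — so tests assert the minimum property rather than a zero value.
- MS-SSIM with the standard 5-scale exponents (0.0448, 0.2856, 0.3001,
  0.2363, 0.1333), 11×11 Gaussian window σ = 1.5, K1 = 0.01, K2 = 0.03,
  dynamic range 1. Images too small for 5 scales use as many halvings as
  keep the coarsest scale ≥ 16 px, with renormalized exponents (logged).
  Luminance is applied at the coarsest scale only; per-scale terms are
  clamped to [1e−6, 1] before the fractional power so the loss stays
  differentiable.
- Total variation: mean of squared horizontal plus vertical forward
  differences (raw-sum mode available).

Training is plain input-reconstruction (no fusion in the loop): fusion has
no ground-truth image to regress against, and the block rule is
non-differentiable by design, so the extractor/reconstructor pair is
pre-trained as an autoencoder and fusion is inserted at inference. Adam
(lr 1e−3, batch 8, 50 epochs by default), seeded He-normal float32 init;
identical seeds give bit-identical runs because every op is deterministic
numpy. Loading pretrained first-layer weights from a local checkpoint is
supported (`load_weights`), but the default builds with no downloads.

The network stack runs on a purpose-built reverse-mode autodiff engine
(`hahnfusion.autodiff`): NHWC tensors, im2col GEMM convolution with a
col2im backward, and a keyed workspace pool that recycles the large patch
buffers across training steps (fresh ~100 MB allocations cost ~100 ms of
page faults per step otherwise). One desk-scale epoch (64 images of
64×64, batch 8) takes ~10–15 s on one CPU core.

## Metrics

Six standard fusion-quality scores, all computed on ITU-R 601 luminance:

- **Q_AB/F** (edge-information transfer): Sobel strength/orientation
  preservation through the published sigmoids (Γ_g = 0.9994, κ_g = −15,
  σ_g = 0.5; Γ_α = 0.9879, κ_α = −22, σ_α = 0.8), weighted by source edge
  strength.
- **SSIM** via scikit-image (11×11 Gaussian window σ = 1.5, standard
  constants).
- **VIF**, pixel-domain variant: 4 scales, Gaussian-scale-mixture model,
  σ_n² = 2 on the 0–255 intensity scale (inputs are rescaled by 255 so the
  constant means what it does in the canonical implementation).
- **FMI**: normalized mutual information (2I/(H₁+H₂), 256-bin joint
  histograms) between gradient-magnitude features of each source and the
  fused image, averaged over sources. Histogram variants of FMI differ
  across the literature; this gradient-feature NMI variant is the
  package's pinned definition.
- **SF**: RMS of first differences, √(RF² + CF²), normalized by pixel
  count.
- **CE**: mean over the two sources of the KL divergence (bits, ε-smoothed
  256-bin histograms) between source and fused gray-level distributions;
  lower is better.

Pairwise metrics (SSIM, VIF) are averaged over the two sources in
`score_all`.

## Synthetic phantoms: what green tests mean

The generator emulates the *format* of registered clinical pairs — 256×256
8-bit PNG (float in memory, quantized only at I/O), grayscale anatomy with
skull ring/cortical band-pass texture/ventricles/optional lesion, smooth
hot-iron-colored activity blobs confined to the identical brain mask, plus
a CT/MRI/PET-like triple for tri-modal runs. Everything is deterministic
under (seed, size).

It does **not** model acquisition physics, noise statistics,
partial-volume effects, or registration error. A green suite therefore
certifies the pipeline's mechanics (transform exactness, firing dynamics,
selection correctness, training convergence, metric sanity and the
directional advantage over a pixel-average baseline on these phantoms) —
not clinical image quality on hospital data.

## Degenerate inputs and tie-breaks

- PE of an all-equal moment matrix is 0; the (0,0) term of the PE sum is
  defined as 0 (the only finite, continuous completion of 0/0).
- Joint min–max normalization of identical PE maps would divide by zero;
  all-equal maps normalize to all-zero stimuli, which still tie correctly.
- Fusion ties take the element-wise max, so permuting the input list never
  changes the result.
- Blocks are compared after zero fill; the fill is stripped before output,
  so padding never leaks into fused images.
- Convolution stride 0 in the reconstructor's published table is read as
  stride 1 (stride 0 is undefined; a 1×1 kernel at stride 1 preserves
  size).

## Known limitations

- Desk-scale training (64 small phantoms) yields a faithful but imperfect
  autoencoder; fused outputs inherit its reconstruction error.
- **The block energy is brightness-dominated in a ReLU feature space.**
  Every PE term inherits the leading moment when higher orders are empty,
  so PE tracks block mean activity almost perfectly (correlation ≈ 0.9996
  measured on desk-trained features). With features that preserve
  brightness — which an autoencoder must — the brighter modality out-fires
  the textured one and block selection favours smooth bright regions. The
  directional fused-vs-pixel-average advantage on SF/Q_AB/F therefore does
  not materialize at desk scale (the corresponding acceptance test fails,
  deliberately unchanged). Edge-sensitive pretrained first-layer features
  (loadable via `load_weights`, not bundled) are the intended regime in
  which the energy contrast reflects texture.
- The saliency proxy and the FMI/CE variants are pinned package
  definitions, not reproductions of any specific third-party binary.
- The PCNN arbitrates with integer firing counts; very similar stimuli can
  tie, which the max rule resolves smoothly but coarsely.
- No GPU path; the numpy engine is tuned for one CPU core at image sizes
  ≤ 256².
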