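# Methods

## The model

The package solves linear inverse problems of the form
min_x ½‖A x − y‖² + g(x) for grayscale images x ∈ [0,1]^{H×W}. Two sensing
operators A are implemented:

- **Gaussian block CS.** An m×n matrix with i.i.d. standard-normal entries
  whose rows are orthonormalized (QR of the transpose, with the sign of the
  R diagonal fixed so regeneration from a seed is bit-identical). Orthonormal
  rows give A Aᴴ = I, so the Lipschitz constant of ∇f is 1 and unit step
  sizes are admissible. m = round(ratio·n); the achieved ratio is m/n.
- **Masked Fourier (CS-MRI).** Φ = P F with an orthonormally scaled 2-D DFT
  (1/√n in both directions, so the full-mask operator is an isometry) and a
  binary radial mask P on the centered spectrum. Images are treated as
  real-valued magnitudes; measurements are complex; the fidelity gradient
  takes the real part of the adjoint. The DC coefficient is always sampled.

The radial mask is a union of straight spokes through the k-space center
(nearest-neighbor rasterization, angles evenly spaced over [0, π)). The
spoke count is found by bisection on the sampled fraction, followed by a
local scan of ±8 counts because rasterized spokes overlap and the fraction
is only approximately monotone in the count. If no count lands within ±2%
of the requested ratio (possible on very small grids, where one spoke can
change the fraction by several percent), a tolerance error reporting the
closest achievable fraction is raised rather than silently mis-sampling.

The fidelity is defined as ½‖Ax − y‖², so ∇f = Aᴴ(Ax − y). A convention
with ‖Ax − y‖² differs only by a factor of 2 that the learned (or
user-chosen) step sizes absorb.

## Classical solver

One iteration of the accelerated extra proximal-gradient algorithm performs
momentum extrapolation, a fidelity gradient step and a proximal step, then
repeats the three from the just-computed half iterate (predictor–corrector).
Defaults and numerical choices:

- x₀ = Aᴴy and x_{−1/2} = x₀ (the adjoint / zero-filled reconstruction);
- constant step schedules by default, per-iteration arrays accepted; α and
  β are kept independent even though tying them is a common simplification,
  because the unrolled network learns them separately;
- a divergence guard aborts when an iterate becomes non-finite or its norm
  exceeds 10⁶× the initial norm, naming the offending sub-step;
- the objective trace records f + g at the full iterates x_k only.

`l1_transform_prox` provides the closed-form prox of g = λ‖Wx‖₁ for
orthonormal W (soft shrinkage in transform coordinates); a non-orthonormal
W triggers a warning since the formula is then only approximate. ISTA and
FISTA implementations are included purely as high-precision testing oracles.

## The unrolled network

Each of K phases executes the same six sub-steps, with the two proximal
steps replaced by the learned residual update b + G̃(S(G(b))). Parameters
are phase-indexed (no sharing across phases); the two stages within a phase
share one parameter set. Structural choices that are forced by the
parameter budget or adopted as conventions:

- all convolutions are 3×3, stride 1, zero same-padding, **bias-free**
  (any bias would break the 37,475-per-phase budget);
- σ is ReLU exactly;
- shrinkage thresholds θ_{k,j} are stored unconstrained. They are
  initialized at 0.01; a negative learned threshold keeps the formula
  well-defined (it then acts as a magnitude *boost*), which deviates from a
  strict proximal interpretation — a deliberate trade of interpretability
  for capacity;
- γ_k starts at 0 (phases begin as plain proximal-gradient; momentum is
  learned), α_k = β_k = 1 at initialization but learned independently;
- x₀ = Aᴴy, matching the classical solver.

The nonlocal operator computes embedded-Gaussian attention in an N_f/2
bottleneck: W_α, W_β, W_φ project N_f → N_f/2 with 1×1 convolutions, the
(HW)² attention matrix is a row softmax (computed with row-max subtraction),
and an expansion 1×1 convolution maps the aggregate back to N_f channels
before the fusion layer ReLU(C_k[z, M(z)]) projects the 2N_f concatenation
to N_f. The alternative factorization without a separate expansion has the
same parameter count; the bottleneck-plus-expansion reading is chosen
because its purpose is to cut the attention cost. C_k outputs N_f channels
(one scalar weight vector per output channel per pixel) — a single-channel
output would be incompatible with the decoder's N_f-channel input and the
4,096-parameter budget of the block. Attention runs over all pixels of the
input (no windowing); for large MRI frames this is the dominant cost and
the reason the nonlocal variant is slower.

Parameter budgets at N_f = 32, per phase: encoder 288 + 9216 + 9216,
decoder 9216 + 9216 + 288, γ 1, steps 2, θ 32 → 37,475; nonlocal block
512·3 + 512 + 2048 = 4,096 → 41,571. Totals: 9 × 37,475 = 337,275 and
7 × 41,571 = 290,997.

## Differentiation and training

The network runs on numpy with a small in-package reverse-mode autodiff
engine (`epgn/_autodiff.py`): a tape of tensors with per-op backward
closures, covering convolutions (via sliding-window views and einsum),
ReLU, channel shrinkage, momentum interpolation, attention, concatenation,
the fidelity gradient step, and the MSE loss. The fidelity step is a single
custom op: its input Jacobian is I − α·Re(AᴴA), which is self-adjoint, so
the backward pass reuses the operator's normal product; the step-size
gradient is −⟨ḡ, ∇f⟩. Every op's gradient is checked against central finite
differences in the unit tests (relative error ≲ 1e−5 at ε = 1e−6).

Training minimizes L(Θ) = (1/N) Σᵢ ‖x_K(yᵢ; Θ) − xᵢ‖² with Adam
(lr 1e−4, moments 0.9/0.999, no weight decay, no schedule, no clipping —
all config-exposed). Glorot-uniform initialization is used for all kernels.
Measurements are simulated on the fly per batch (y = A x), so only
ground-truth images are stored. Shuffling derives from the config seed;
training is bit-reproducible on one device. A non-finite loss aborts with
the last good checkpoint written.

Defaults the reference configuration leaves open and this package fixes:
batch size 64, no train/validation split rule (validation PSNR is computed
per epoch when a held-out set is supplied), no early stopping.

## Synthetic data

The phantom generator stands in for natural-image and MR corpora: random
ellipses, rectangles and bars at uniform intensities on a constant
background with a low-frequency cosine texture (amplitude 0.05, ≤1.5 cycles
per image side) and optional Gaussian noise, clipped to [0,1]. This
reproduces the property the learned regularizer exploits — sparse gradients
/ transform-sparsity (≥60% of pixels have |∇x| < 0.01 at the default
spec) — but not the rich textures, edges statistics or scanner noise of
real data, so passing tests demonstrate the machinery works end-to-end, not
that real-data reconstruction quality is matched. Block-CS training uses
random 33×33 crops; the MRI mode trains on whole frames (190×190 mirrors a
common crop size; tests use smaller frames). All generators are
deterministic from seeds, and saved sets carry a JSON manifest with counts,
seeds and a content hash.

## Evaluation

PSNR is 10·log₁₀(peak²/MSE) with peak 1.0 on normalized images; identical
images report a capped 99 dB with a flag. SSIM uses the standard 11×11
Gaussian window (σ 1.5) with population (not sample) covariances. Block-CS
test images are edge-padded to a multiple of 33, reconstructed per
non-overlapping block, and cropped back — tiling is exactly lossless on the
ground truth. Reported aggregates are per-image means ± standard deviation.

## Problem sizes

The bundled experiments are deliberately desk-scale: the learning-sanity
run trains a 3-phase, 8-channel network on 200 patches for 30 epochs
(minutes on one CPU) rather than the reference 88,912-patch, 200-epoch GPU
training, and the classical-solver cross-checks use 8×16 LASSO toys with a
10⁵-iteration FISTA oracle. These sizes establish correctness of the
mechanism, not headline reconstruction accuracy.

## Known limitations

- No coil-sensitivity / parallel-imaging model and no non-Cartesian
  gridding; the MRI path assumes single-coil magnitude images.
- Attention memory grows as (HW)²; whole-image nonlocal phases beyond
  roughly 96×96 are slow on CPU.
- The autodiff engine implements exactly the ops the network needs; it is
  not a general-purpose framework.
- Trained quality on real photographs or clinical MR data is out of scope
  here and would require the original corpora and training budgets.
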