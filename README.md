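# epgn — extra proximal-gradient networks for compressive-sensing image reconstruction

`epgn` reconstructs grayscale images from undersampled linear measurements
by unrolling an accelerated **extra proximal-gradient** algorithm into a
fixed-depth neural network with a learned regularizer. It targets two
measurement models:

- **block compressive sensing** — 33×33 luminance patches measured by a
  row-orthonormalized random Gaussian matrix Ψ at sampling ratios such as
  10% or 25% of the pixel count;
- **CS-MRI** — whole images measured by Φ = P F, a binary radial-trajectory
  selection P of orthonormal 2-D discrete-Fourier coefficients F.

Both are instances of the inverse problem

```
min_x  f(x; y) + g(x),      f(x; y) = ½‖A x − y‖²,
```

where the regularizer g is *learned*. The classical iteration (one phase of
the network) interleaves Nesterov momentum, gradient descent on f, and a
proximal step — twice per iteration, in a predictor–corrector ("extra
gradient") pattern:

```
x̃_k   = x_k + γ_k (x_k − x_{k−1/2})
b      = x̃_k − α_k ∇f(x̃_k; y)
x_k+½  = prox_{α_k g}(b)
x̂_k   = x_{k+½} + γ_k (x_{k+½} − x_k)
b′     = x̂_k − β_k ∇f(x̂_k; y)
x_{k+1} = prox_{β_k g}(b′)
```

The network (EPGN) replaces the two proximal steps of phase k with a learned
residual update `x = b + G̃_k(S_k(G_k(b)))`: an encoder
`G_k = B_k ∘ ReLU ∘ A_k ∘ D_k` of three bias-free 3×3 convolutions
(receptive field 7×7, N_f = 32 feature channels), channel-wise soft
shrinkage `S_k(z) = sign(z)·max(|z| − θ_{k,j}, 0)` with learned thresholds,
and a mirror-image decoder. The step sizes α_k, β_k and momentum γ_k are
learned per phase; the two stages inside a phase share one parameter set,
distinct phases do not. The nonlocal variant (NL-EPGN) inserts an
embedded-Gaussian attention operator between shrinkage and decoding that
averages features over all image positions with softmax weights
`w_ij ∝ exp(⟨W_α z_i, W_β z_j⟩)`, computed in an N_f/2 bottleneck and fused
with the local features by a learnable 1×1 projection.

Per phase this gives exactly **37,475** learnable scalars (EPGN, N_f = 32)
and **41,571** (NL-EPGN); the reference 9-phase EPGN and 7-phase NL-EPGN
total **337,275** and **290,997** parameters.

The package also ships the classical solver itself (with ISTA/FISTA
reference implementations), a synthetic phantom generator so everything
trains and tests without external datasets, and PSNR/SSIM evaluation with
block tiling for the block-CS mode.

## Worked example

Train a tiny 3-phase, 8-channel EPGN on 200 synthetic phantom patches at a
25% Gaussian sampling ratio, then compare it with the adjoint baseline
A^H y on held-out phantoms:

```python
import numpy as np
from epgn import (NetworkConfig, PhantomSpec, TrainConfig,
                  adjoint_reconstructor, evaluate, extract_patches,
                  init_parameters, make_gaussian_operator, make_phantoms,
                  network_reconstructor, train)

phantoms = make_phantoms(PhantomSpec(size=(64, 64), seed=1), 30)
patches  = extract_patches(phantoms, patch=33, count=200, seed=1).patches
op  = make_gaussian_operator(33 * 33, ratio=0.25, seed=1, image_shape=(33, 33))
net = init_parameters(NetworkConfig(K=3, Nf=8), seed=1)
net, hist = train(net, patches, op,
                  TrainConfig(learning_rate=1e-4, epochs=30, batch_size=25, seed=1))
print(f"loss epoch 1: {hist.train_loss[0]:.2f} -> epoch 30: {hist.train_loss[-1]:.2f}")

test = make_phantoms(PhantomSpec(size=(66, 66), seed=101), 6)
print("EPGN   :", evaluate(network_reconstructor(net), test, op, mode="cs").summary())
print("adjoint:", evaluate(adjoint_reconstructor, test, op, mode="cs").summary())
```

Output from this exact script:

```
loss epoch 1: 75.87 -> epoch 30: 13.43
EPGN   : PSNR 20.36 ± 1.24 dB, SSIM 0.3861 (n=6)
adjoint: PSNR 9.17 ± 0.85 dB, SSIM 0.0412 (n=6)
```

The training loss (mean squared reconstruction error per patch) drops by
more than 5× in 30 epochs, and the learned network recovers phantoms about
11 dB more accurately than the adjoint baseline — the learned residual
regularizer is doing real work even at this desk scale.

The same surface is available from the shell:

```sh
epgn audit --model nlepgn --phases 7      # parameter budget table
epgn train --mode cs --ratio 0.25 --phases 3 --nf 8 --epochs 30 --out run/
epgn evaluate --checkpoint run/final.npz --ratio 0.25
epgn solve --mode csmri --ratio 0.3 --iters 200   # classical solver
epgn make-fixtures --count 16 --out fixtures/
```

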