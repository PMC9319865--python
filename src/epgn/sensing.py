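"""Measurement models for block compressive sensing and CS-MRI.

Two operator kinds are provided:

* a row-orthonormalized random Gaussian matrix measuring vectorized image
  patches (block CS), and
* a masked, orthonormally scaled 2-D discrete Fourier transform with a
  radial k-space sampling trajectory (CS-MRI).

Both expose the same surface: ``forward`` / ``adjoint`` on single images,
batched variants used by the unrolled network, and the data-fidelity
gradient of f(x; y) = 1/2 ||A x - y||^2, namely ``A^H (A x - y)`` (real
part for the complex Fourier kind — the factor-of-two difference against a
plain squared norm is absorbed into the step sizes).
"""

from __future__ import annotations

import dataclasses
import numpy as np

__all__ = [
    "SensingOperator",
    "GaussianOperator",
    "FourierOperator",
    "RadialMask",
    "make_gaussian_operator",
    "make_radial_mask",
    "make_fourier_operator",
    "fidelity_gradient",
    "save_operator",
    "load_operator",
    "ToleranceError",
]


class ToleranceError(ValueError):
    """Raised when a radial mask cannot reach the requested sampling ratio."""


@dataclasses.dataclass(frozen=True)
class RadialMask:
    """Binary k-space sampling pattern of straight spokes through the DC bin.

    The mask lives on a centered grid: the DC coefficient sits at
    ``(H // 2, W // 2)`` and is always sampled.
    """

    mask: np.ndarray
    ratio: float
    n_spokes: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def achieved_ratio(self) -> float:
        return float(self.mask.mean())


class SensingOperator:
    """Common surface of the measurement models."""

    kind: str
    ratio: float
    image_shape: tuple[int, int]

    @property
    def n(self) -> int:
        return int(np.prod(self.image_shape))

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # --- batched hooks used by the unrolled network (N, 1, H, W) ---

    def batch_forward(self, x: np.ndarray) -> np.ndarray:
        return np.stack([self.forward(xi[0]) for xi in x])

    def batch_adjoint(self, y: np.ndarray) -> np.ndarray:
        return np.stack([np.real(self.adjoint(yi))[None] for yi in y])

    def batch_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Real part of A^H (A x - y), batched over the leading axis."""
        res = self.batch_forward(x) - y
        return np.stack([np.real(self.adjoint(ri))[None] for ri in res])

    def batch_gram(self, x: np.ndarray) -> np.ndarray:
        """Real part of A^H A x (the normal operator), batched."""
        return self.batch_gradient(x, np.zeros((x.shape[0], self.m),
                                               dtype=complex if self.kind == "fourier_masked" else float))

    @property
    def m(self) -> int:
        raise NotImplementedError


class GaussianOperator(SensingOperator):
    """Random Gaussian measurement matrix with orthonormalized rows."""

    kind = "gaussian"

    def __init__(self, matrix: np.ndarray, image_shape: tuple[int, int],
                 ratio: float, seed: int):
        self.matrix = matrix
        self.image_shape = tuple(image_shape)
        self.ratio = float(ratio)
        self.seed = int(seed)

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != self.image_shape:
            raise ValueError(f"image shape {x.shape} != {self.image_shape}")
        return self.matrix @ x.ravel()

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.m,):
            raise ValueError(f"measurement shape {y.shape} != ({self.m},)")
        return (self.matrix.T @ y).reshape(self.image_shape)

    # dense-matrix fast paths
    def batch_forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        return x.reshape(n, -1) @ self.matrix.T

    def batch_adjoint(self, y: np.ndarray) -> np.ndarray:
        n = y.shape[0]
        return (y @ self.matrix).reshape(n, 1, *self.image_shape)

    def batch_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        res = self.batch_forward(x) - y
        return self.batch_adjoint(res)

    def batch_gram(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        return ((x.reshape(n, -1) @ self.matrix.T) @ self.matrix).reshape(x.shape)


class FourierOperator(SensingOperator):
    """Mask-selected orthonormal 2-D DFT coefficients (Phi = P F).

    Images are real-valued; measurements are the complex Fourier
    coefficients selected by the radial mask on the centered spectrum.
    The adjoint zero-fills the unsampled coefficients and inverse
    transforms, yielding the standard zero-filled reconstruction.
    """

    kind = "fourier_masked"

    def __init__(self, radial_mask: RadialMask):
        self.radial_mask = radial_mask
        self.mask = radial_mask.mask.astype(bool)
        self.image_shape = radial_mask.shape
        self.ratio = radial_mask.achieved_ratio
        self._idx = np.flatnonzero(self.mask.ravel())

    @property
    def m(self) -> int:
        return self._idx.size

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.shape != self.image_shape:
            raise ValueError(f"image shape {x.shape} != {self.image_shape}")
        spec = np.fft.fftshift(np.fft.fft2(x, norm="ortho"))
        return spec.ravel()[self._idx]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=complex)
        if y.shape != (self.m,):
            raise ValueError(f"measurement shape {y.shape} != ({self.m},)")
        spec = np.zeros(self.n, dtype=complex)
        spec[self._idx] = y
        spec = spec.reshape(self.image_shape)
        return np.fft.ifft2(np.fft.ifftshift(spec), norm="ortho")

    def batch_forward(self, x: np.ndarray) -> np.ndarray:
        spec = np.fft.fftshift(np.fft.fft2(x[:, 0], norm="ortho"), axes=(-2, -1))
        return spec.reshape(x.shape[0], -1)[:, self._idx]

    def batch_adjoint(self, y: np.ndarray) -> np.ndarray:
        n = y.shape[0]
        spec = np.zeros((n, self.n), dtype=complex)
        spec[:, self._idx] = y
        spec = spec.reshape(n, *self.image_shape)
        img = np.fft.ifft2(np.fft.ifftshift(spec, axes=(-2, -1)), norm="ortho")
        return np.real(img)[:, None]

    def batch_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.batch_adjoint(self.batch_forward(x) - y)

    def batch_gram(self, x: np.ndarray) -> np.ndarray:
        return self.batch_adjoint(self.batch_forward(x))


def make_gaussian_operator(n: int, ratio: float, seed: int,
                           image_shape: tuple[int, int] | None = None) -> GaussianOperator:
    """Row-orthonormalized m x n Gaussian sensing matrix, m = round(ratio * n).

    Deterministic given ``seed``.  If ``image_shape`` is omitted a square
    (or near-square via exact factoring) patch shape is inferred; for the
    standard 33 x 33 block-CS patches ``n = 1089``.
    """
    if not (0 < ratio <= 1):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if n < 1:
        raise ValueError("n must be >= 1")
    m = max(1, int(round(ratio * n)))
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((m, n))
    # QR of the transpose gives orthonormal columns -> orthonormal rows of A
    q, r = np.linalg.qr(g.T)
    # fix signs so the factorization (and hence the operator) is unique
    q = q * np.sign(np.diag(r))
    a = q.T
    if image_shape is None:
        side = int(round(np.sqrt(n)))
        if side * side == n:
            image_shape = (side, side)
        else:
            image_shape = (1, n)
    return GaussianOperator(a, image_shape, ratio, seed)


def _spoke_mask(h: int, w: int, n_spokes: int) -> np.ndarray:
    """Union of ``n_spokes`` evenly rotated straight lines through the center."""
    mask = np.zeros((h, w), dtype=np.uint8)
    cy, cx = h // 2, w // 2
    half = float(np.hypot(h, w)) / 2.0 + 1.0
    t = np.linspace(-half, half, int(4 * half) + 1)
    for s in range(n_spokes):
        ang = np.pi * s / n_spokes
        rows = np.rint(cy + t * np.sin(ang)).astype(int)
        cols = np.rint(cx + t * np.cos(ang)).astype(int)
        keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        mask[rows[keep], cols[keep]] = 1
    mask[cy, cx] = 1  # DC always sampled
    return mask


def make_radial_mask(h: int, w: int, ratio: float,
                     n_spokes: int | None = None, tol: float = 0.02) -> RadialMask:
    """Radial sampling mask whose ones-fraction is within ``tol`` of ``ratio``.

    The spoke count is found by bisection (the sampled fraction is
    nondecreasing in the number of spokes).  Entirely deterministic.
    Passing ``n_spokes`` explicitly skips the search.
    """
    if n_spokes is not None:
        mask = _spoke_mask(h, w, int(n_spokes))
        return RadialMask(mask=mask, ratio=float(mask.mean()), n_spokes=int(n_spokes))
    if not (0 < ratio < 1):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    lo, hi = 1, 4 * (h + w)
    best, best_err = None, np.inf
    while lo <= hi:
        mid = (lo + hi) // 2
        mask = _spoke_mask(h, w, mid)
        frac = mask.mean()
        err = abs(frac - ratio)
        if err < best_err:
            best, best_err, best_spokes = mask, err, mid
        if frac < ratio:
            lo = mid + 1
        else:
            hi = mid - 1
    # the sampled fraction is only approximately monotone in the spoke count
    # (rasterized spokes overlap); refine with a local scan around the
    # bisection crossing
    for s in range(max(1, best_spokes - 8), best_spokes + 9):
        mask = _spoke_mask(h, w, s)
        err = abs(mask.mean() - ratio)
        if err < best_err:
            best, best_err, best_spokes = mask, err, s
    if best_err > tol:
        raise ToleranceError(
            f"cannot reach ratio {ratio:.3f} at {h}x{w}: closest achieved "
            f"fraction is {float(best.mean()):.3f} with {best_spokes} spokes")
    return RadialMask(mask=best, ratio=float(ratio), n_spokes=best_spokes)


def make_fourier_operator(mask: RadialMask) -> FourierOperator:
    """Masked orthonormal-DFT sensing operator Phi = P F from a radial mask."""
    return FourierOperator(mask)


def fidelity_gradient(op: SensingOperator, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of the data-fidelity 1/2 ||A x - y||^2: Re[A^H (A x - y)]."""
    return np.real(op.adjoint(op.forward(x) - y))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_operator(path, op: SensingOperator) -> None:
    """Serialize an operator to an NPZ container with {kind, ratio, seed, data}."""
    if isinstance(op, GaussianOperator):
        np.savez(path, kind="gaussian", ratio=op.ratio, seed=op.seed,
                 data=op.matrix, image_shape=np.array(op.image_shape))
    elif isinstance(op, FourierOperator):
        np.savez(path, kind="fourier_masked", ratio=op.radial_mask.ratio,
                 seed=-1, data=op.radial_mask.mask,
                 n_spokes=op.radial_mask.n_spokes)
    else:  # pragma: no cover
        raise TypeError(f"unknown operator type {type(op)}")


def load_operator(path) -> SensingOperator:
    with np.load(path, allow_pickle=False) as f:
        kind = str(f["kind"])
        if kind == "gaussian":
            return GaussianOperator(f["data"], tuple(f["image_shape"]),
                                    float(f["ratio"]), int(f["seed"]))
        if kind == "fourier_masked":
            rm = RadialMask(mask=f["data"].astype(np.uint8),
                            ratio=float(f["ratio"]), n_spokes=int(f["n_spokes"]))
            return FourierOperator(rm)
    raise ValueError(f"unknown operator kind {kind!r}")
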