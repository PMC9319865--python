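"""Reconstruction quality metrics and experiment orchestration.

PSNR is 10 log10(peak^2 / MSE) with peak 1.0 on normalized images; SSIM is
the standard structural-similarity index with an 11x11 Gaussian window
(sigma 1.5) and default stabilizing constants.  Block-CS evaluation tiles a
test image into non-overlapping 33x33 blocks (edge-padded to a multiple of
the block size), reconstructs each block from its own measurement vector,
and reassembles; CS-MRI evaluation reconstructs the whole image at once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.metrics import structural_similarity

from .sensing import SensingOperator

__all__ = [
    "MetricReport",
    "psnr",
    "ssim",
    "tile_image",
    "untile_image",
    "reconstruct_blockwise",
    "evaluate",
    "PSNR_CAP_DB",
]

PSNR_CAP_DB = 99.0


@dataclasses.dataclass
class MetricReport:
    """Per-image PSNR/SSIM plus their mean and standard deviation."""
    psnr_values: list[float]
    ssim_values: list[float]
    psnr_capped: list[bool]

    @property
    def psnr_mean(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def psnr_std(self) -> float:
        return float(np.std(self.psnr_values))

    @property
    def ssim_mean(self) -> float:
        return float(np.mean(self.ssim_values))

    def summary(self) -> str:
        return (f"PSNR {self.psnr_mean:.2f} ± {self.psnr_std:.2f} dB, "
                f"SSIM {self.ssim_mean:.4f} (n={len(self.psnr_values)})")


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE) in dB.

    Identical images have infinite PSNR; the value is capped at 99 dB
    (callers needing the flag use ``psnr_flagged``).
    """
    return psnr_flagged(x, ref, peak)[0]


def psnr_flagged(x: np.ndarray, ref: np.ndarray,
                 peak: float = 1.0) -> tuple[float, bool]:
    x, ref = np.asarray(x, dtype=float), np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB, True
    val = 10.0 * np.log10(peak * peak / mse)
    return min(val, PSNR_CAP_DB), val >= PSNR_CAP_DB


def ssim(x: np.ndarray, ref: np.ndarray) -> float:
    """Mean structural similarity, 11x11 Gaussian window, data range 1."""
    x, ref = np.asarray(x, dtype=float), np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    return float(structural_similarity(ref, x, data_range=1.0,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False))


# ---------------------------------------------------------------------------
# block tiling for block-CS evaluation
# ---------------------------------------------------------------------------

def tile_image(img: np.ndarray, block: int = 33) -> tuple[np.ndarray, tuple[int, int]]:
    """Edge-pad to a multiple of ``block`` and split into non-overlapping tiles.

    Returns the (N, block, block) tile stack and the original shape for
    ``untile_image``; tiling then untiling is lossless.
    """
    h, w = img.shape
    ph = (-h) % block
    pw = (-w) % block
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    hh, ww = padded.shape
    tiles = (padded.reshape(hh // block, block, ww // block, block)
             .transpose(0, 2, 1, 3).reshape(-1, block, block))
    return tiles, (h, w)


def untile_image(tiles: np.ndarray, shape: tuple[int, int],
                 block: int = 33) -> np.ndarray:
    h, w = shape
    hh = h + (-h) % block
    ww = w + (-w) % block
    grid = tiles.reshape(hh // block, ww // block, block, block)
    padded = grid.transpose(0, 2, 1, 3).reshape(hh, ww)
    return padded[:h, :w]


def reconstruct_blockwise(reconstructor, op: SensingOperator,
                          img: np.ndarray, block: int = 33) -> np.ndarray:
    """Measure and reconstruct each tile independently, then reassemble.

    ``reconstructor(op, y_batch) -> (N, block, block)`` maps a batch of
    measurement vectors to image blocks.
    """
    tiles, shape = tile_image(img, block)
    y = op.batch_forward(tiles[:, None])
    rec = reconstructor(op, y)
    return untile_image(np.asarray(rec), shape, block)


def network_reconstructor(network):
    """Adapter turning a trained network into a batch reconstructor."""
    def _rec(op, y):
        return network.forward(op, y).data[:, 0]
    return _rec


def adjoint_reconstructor(op, y):
    """The A^H y baseline (zero-filled reconstruction for the Fourier kind)."""
    return op.batch_adjoint(y)[:, 0]


def evaluate(reconstructor, test_images: list[np.ndarray],
             op: SensingOperator, mode: str = "cs",
             block: int = 33) -> MetricReport:
    """Reconstruct every test image and aggregate PSNR/SSIM.

    mode 'cs': per-block measurement and reconstruction (block CS);
    mode 'csmri': the whole image is measured and reconstructed at once.
    """
    if not test_images:
        raise ValueError("empty test set")
    psnrs, ssims, caps = [], [], []
    for img in test_images:
        if mode == "cs":
            rec = reconstruct_blockwise(reconstructor, op, img, block)
        elif mode == "csmri":
            y = op.batch_forward(img[None, None])
            rec = np.asarray(reconstructor(op, y))[0]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        p, capped = psnr_flagged(rec, img)
        psnrs.append(p)
        caps.append(capped)
        ssims.append(ssim(rec, img))
    return MetricReport(psnr_values=psnrs, ssim_values=ssims, psnr_capped=caps)
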