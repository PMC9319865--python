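"""Synthetic phantoms, patch extraction, and standard image ingestion.

Desk-scale stand-in for natural-image / MR training corpora: piecewise-
constant phantoms (random ellipses, rectangles and bars on a smooth
low-frequency background, optional additive Gaussian noise) reproduce the
sparse-gradient structure that transform-sparsity regularizers exploit,
without requiring any external dataset.  Block-CS training patches are
random 33x33 luminance crops, mirroring the standard preparation pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings

import numpy as np

__all__ = [
    "PhantomSpec",
    "PatchSet",
    "make_phantoms",
    "extract_patches",
    "to_luminance",
    "load_image",
    "save_patchset",
    "load_patchset",
]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    size: (H, W) pixels; n_shapes: random shapes per image;
    texture_amplitude: peak amplitude of the smooth cosine background;
    noise_sigma: additive Gaussian noise level before clipping to [0, 1].
    """
    size: tuple[int, int] = (64, 64)
    n_shapes: int = 6
    texture_amplitude: float = 0.05
    noise_sigma: float = 0.0
    seed: int = 0


@dataclasses.dataclass
class PatchSet:
    """A stack of square luminance patches plus provenance metadata."""
    patches: np.ndarray  # (N, p, p) in [0, 1]
    offsets: np.ndarray  # (N, 3): source image index, row, col
    patch: int
    seed: int


def make_phantoms(spec: PhantomSpec, count: int) -> list[np.ndarray]:
    """Generate ``count`` phantoms in [0, 1]; deterministic given the spec seed."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    images = []
    for _ in range(count):
        img = np.full((h, w), 0.3)
        if spec.texture_amplitude > 0:
            fy, fx = rng.uniform(0.5, 1.5, size=2)
            py, px = rng.uniform(0, 2 * np.pi, size=2)
            img += spec.texture_amplitude * np.cos(
                2 * np.pi * (fy * yy / h + py)) * np.cos(
                2 * np.pi * (fx * xx / w + px))
        for _ in range(spec.n_shapes):
            kind = rng.integers(0, 3)
            level = rng.uniform(0.1, 0.9)
            cy, cx = rng.uniform(0.15, 0.85) * h, rng.uniform(0.15, 0.85) * w
            if kind == 0:  # ellipse
                ry, rx = rng.uniform(0.05, 0.25) * h, rng.uniform(0.05, 0.25) * w
                ang = rng.uniform(0, np.pi)
                dy, dx = yy - cy, xx - cx
                u = dy * np.cos(ang) + dx * np.sin(ang)
                v = -dy * np.sin(ang) + dx * np.cos(ang)
                inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1
            elif kind == 1:  # rectangle
                ry, rx = rng.uniform(0.05, 0.25) * h, rng.uniform(0.05, 0.25) * w
                inside = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= rx)
            else:  # bar / line segment
                ang = rng.uniform(0, np.pi)
                thick = rng.uniform(1.0, 3.0)
                length = rng.uniform(0.2, 0.6) * min(h, w)
                dy, dx = yy - cy, xx - cx
                along = dy * np.sin(ang) + dx * np.cos(ang)
                across = dy * np.cos(ang) - dx * np.sin(ang)
                inside = (np.abs(across) <= thick) & (np.abs(along) <= length / 2)
            img[inside] = level
        if spec.noise_sigma > 0:
            img += rng.normal(0, spec.noise_sigma, size=img.shape)
        images.append(np.clip(img, 0.0, 1.0))
    return images


def extract_patches(images: list[np.ndarray], patch: int = 33,
                    count: int = 100, seed: int = 0) -> PatchSet:
    """Uniform random square crops from a list of images.

    Images smaller than the patch size are skipped with a warning; crop
    positions are deterministic given the seed and recorded in the result.
    """
    rng = np.random.default_rng(seed)
    usable = []
    for i, img in enumerate(images):
        if img.shape[0] >= patch and img.shape[1] >= patch:
            usable.append(i)
        else:
            warnings.warn(f"image {i} smaller than patch size {patch}; skipped",
                          stacklevel=2)
    if not usable:
        raise ValueError("no image large enough for the requested patch size")
    patches = np.empty((count, patch, patch))
    offsets = np.empty((count, 3), dtype=int)
    for j in range(count):
        i = usable[rng.integers(len(usable))]
        img = images[i]
        r = rng.integers(img.shape[0] - patch + 1)
        c = rng.integers(img.shape[1] - patch + 1)
        patches[j] = img[r:r + patch, c:c + patch]
        offsets[j] = (i, r, c)
    return PatchSet(patches=patches, offsets=offsets, patch=patch, seed=seed)


def to_luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance 0.299 R + 0.587 G + 0.114 B of an (H, W, 3) image in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3), got {rgb.shape}")
    return rgb @ np.array([0.299, 0.587, 0.114])


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/PGM image as a [0, 1] grayscale array.

    RGB(A) input is reduced to BT.601 luminance; integer data is scaled by
    its dtype maximum.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = to_luminance(arr[:, :, :3])
    return np.clip(arr, 0.0, 1.0)


def save_patchset(path, ps: PatchSet) -> None:
    """NPZ container plus a JSON manifest (counts, seed, content hash)."""
    path = pathlib.Path(path)
    np.savez(path, patches=ps.patches, offsets=ps.offsets,
             patch=ps.patch, seed=ps.seed)
    digest = hashlib.sha256(ps.patches.tobytes()).hexdigest()
    manifest = {"count": int(ps.patches.shape[0]), "patch": int(ps.patch),
                "seed": int(ps.seed), "sha256": digest}
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def load_patchset(path) -> PatchSet:
    with np.load(path, allow_pickle=False) as f:
        return PatchSet(patches=f["patches"], offsets=f["offsets"],
                        patch=int(f["patch"]), seed=int(f["seed"]))
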