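"""Seeded co-registered brain-like phantoms for end-to-end testing.

The generator mimics the salient properties of registered clinical pairs —
a 256×256 grayscale structural slice (MRI/CT-like: bright skull ring,
textured cortex, dark ventricles, optional lesion) and a co-registered
pseudo-colored functional slice (SPECT/PET-like: smooth activity blobs
rendered through a hot-iron colormap, confined to the same brain mask).
Everything is deterministic under (seed, size): images are float in [0, 1]
in memory and quantize to 8-bit only at PNG I/O.

These phantoms share geometry and value ranges with real data but none of
its physics: no acquisition noise model, no partial-volume effects, no
registration error.  Green tests built on them certify the pipeline's
mechanics, not clinical image quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomPair",
    "make_pair",
    "make_structural",
    "make_functional",
    "make_dataset",
    "make_tri_modal",
    "brain_mask",
    "hot_iron",
]

_MIN_SIZE = 64


def _check_size(size: int) -> None:
    if size < _MIN_SIZE:
        raise ValueError(f"size must be >= {_MIN_SIZE}, got {size}")


@dataclass(frozen=True)
class PhantomPair:
    """A co-registered structural/functional pair plus its generator meta."""

    structural: np.ndarray = field(repr=False)  # (H, W) in [0, 1]
    functional: np.ndarray = field(repr=False)  # (H, W, 3) in [0, 1]
    seed: int
    size: int
    lesion: tuple[float, float, float] | None = None  # (cy, cx, radius), px


def _grid(size: int):
    y, x = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2
    return (y - cy) / (size / 2), (x - cx) / (size / 2)


def brain_mask(size: int) -> np.ndarray:
    """Elliptical interior region shared by all modalities of one subject."""
    v, u = _grid(size)
    return (v / 0.82)**2 + (u / 0.68)**2 <= 1.0


def _skull_ring(size: int) -> np.ndarray:
    v, u = _grid(size)
    r = np.sqrt((v / 0.90)**2 + (u / 0.76)**2)
    return np.exp(-((r - 1.0) / 0.045)**2)


def _ventricles(size: int) -> np.ndarray:
    """Two dark comma-shaped lobes flanking the midline."""
    v, u = _grid(size)
    lobes = np.zeros((size, size))
    for su in (-1, 1):
        lobes += np.exp(-(((u - su * 0.16) / 0.10)**2
                          + ((v + 0.05) / 0.28)**2))
    return np.clip(lobes, 0, 1)


def _bandpass_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    tex = gaussian_filter(noise, size / 128) - gaussian_filter(noise, size / 32)
    return (tex - tex.min()) / (tex.max() - tex.min())


def make_structural(size: int = 256, seed: int = 0,
                    lesion: tuple[float, float, float] | None = None
                    ) -> np.ndarray:
    """Grayscale anatomy phantom: skull ring, cortical texture, ventricles.

    `lesion`, if given, is a bright disc at (cy, cx) with the stated radius
    (pixels), softened at its rim.
    """
    _check_size(size)
    rng = np.random.default_rng(seed)
    mask = brain_mask(size)
    img = 0.9 * _skull_ring(size)
    interior = 0.25 + 0.5 * _bandpass_texture(size, rng)
    img = np.where(mask, interior, img)
    img *= 1.0 - 0.85 * _ventricles(size)
    if lesion is not None:
        cy, cx, rad = lesion
        y, x = np.mgrid[0:size, 0:size].astype(float)
        d = np.sqrt((y - cy)**2 + (x - cx)**2)
        img = np.maximum(img, np.where(mask, 0.95 / (1 + np.exp(d - rad)), 0))
    return np.clip(img, 0.0, 1.0)


def hot_iron(values: np.ndarray) -> np.ndarray:
    """Map scalars in [0, 1] through a black-red-yellow-white ramp."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    r = np.clip(3.0 * v, 0, 1)
    g = np.clip(3.0 * v - 1.0, 0, 1)
    b = np.clip(3.0 * v - 2.0, 0, 1)
    return np.stack([r, g, b], axis=-1)


def make_functional(size: int = 256, seed: int = 0,
                    lesion: tuple[float, float, float] | None = None
                    ) -> np.ndarray:
    """Pseudo-colored metabolic phantom, co-registered with the structural one.

    2–4 smooth Gaussian activity blobs inside the shared brain mask (one
    centred on the lesion when present), hot-iron colored.
    """
    _check_size(size)
    rng = np.random.default_rng(seed)
    mask = brain_mask(size)
    n_blobs = int(rng.integers(2, 5))
    activity = np.zeros((size, size))
    y, x = np.mgrid[0:size, 0:size].astype(float)
    centers = []
    if lesion is not None:
        centers.append((lesion[0], lesion[1], max(lesion[2] * 1.5, size / 16)))
        n_blobs -= 1
    for _ in range(max(n_blobs, 1)):
        cy = size / 2 + rng.uniform(-0.45, 0.45) * size / 2
        cx = size / 2 + rng.uniform(-0.38, 0.38) * size / 2
        centers.append((cy, cx, rng.uniform(size / 16, size / 7)))
    for cy, cx, s in centers:
        activity += rng.uniform(0.5, 1.0) * np.exp(
            -((y - cy)**2 + (x - cx)**2) / (2 * s**2))
    activity = np.clip(activity / max(activity.max(), 1e-12), 0, 1)
    return hot_iron(activity) * mask[..., None]


def make_pair(size: int = 256, seed: int = 0,
              lesion: tuple[float, float, float] | None = "auto"
              ) -> PhantomPair:
    """One co-registered structural/functional pair under a single seed."""
    _check_size(size)
    if lesion == "auto":
        rng = np.random.default_rng(seed + 1)
        if rng.random() < 0.5:
            cy = size / 2 + rng.uniform(-0.3, 0.3) * size / 2
            cx = size / 2 + rng.uniform(-0.3, 0.3) * size / 2
            lesion = (cy, cx, rng.uniform(size / 24, size / 12))
        else:
            lesion = None
    return PhantomPair(
        structural=make_structural(size, seed, lesion),
        functional=make_functional(size, seed, lesion),
        seed=seed, size=size, lesion=lesion)


def make_dataset(n: int, size: int = 256, seed: int = 0) -> list[PhantomPair]:
    """n reproducible pairs with independent sub-seeds derived from `seed`."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    _check_size(size)
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=n)
    return [make_pair(size, int(s)) for s in sub_seeds]


def make_tri_modal(size: int = 256, seed: int = 0):
    """Co-registered (CT-like, MRI-like, PET-like) triple.

    CT: bright skull, flat interior.  MRI: dim skull, textured interior.
    PET: colored metabolic blobs.  All share one brain mask.
    """
    _check_size(size)
    rng = np.random.default_rng(seed)
    mask = brain_mask(size)
    skull = _skull_ring(size)
    ct = np.clip(1.0 * skull + np.where(mask, 0.18, 0.0), 0, 1)
    mri = np.where(mask, 0.25 + 0.5 * _bandpass_texture(size, rng),
                   0.35 * skull)
    mri = np.clip(mri * (1.0 - 0.85 * _ventricles(size)), 0, 1)
    pet = make_functional(size, seed + 2)
    return ct, mri, pet
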