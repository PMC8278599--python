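"""PNG image I/O, channel handling, and color-space conversion.

Internal convention: row-major float arrays in [0, 1], origin top-left,
0-based indices; grayscale images are (H, W), color images (H, W, 3).
8-bit quantization happens only when a file is written.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

__all__ = [
    "load_image",
    "save_image",
    "to_network_input",
    "to_luminance",
    "convert_colorspace",
]


def load_image(path) -> np.ndarray:
    """Read a raster image as float in [0, 1], preserving channel count."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_image(image: np.ndarray, path) -> None:
    """Write a float [0, 1] image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def to_network_input(image: np.ndarray) -> np.ndarray:
    """Replicate grayscale to 3 channels; pass 3-channel images through."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return np.repeat(arr[..., None], 3, axis=-1)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return arr
    raise ValueError(
        f"expected (H, W) or (H, W, 3), got shape {arr.shape}")


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Collapse a color image to ITU-R 601 luma; grayscale passes through."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return arr @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"expected (H, W) or (H, W, 3), got shape {arr.shape}")


_TO = {
    "RGB": lambda a: a,
    "HSV": _skcolor.rgb2hsv,
    "YUV": _skcolor.rgb2yuv,
}
_FROM = {
    "RGB": lambda a: a,
    "HSV": _skcolor.hsv2rgb,
    "YUV": _skcolor.yuv2rgb,
}


def convert_colorspace(image: np.ndarray, target: str,
                       source: str = "RGB") -> np.ndarray:
    """Convert a 3-channel image between RGB, HSV and YUV."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {arr.shape}")
    for name in (source, target):
        if name not in _TO:
            raise ValueError(f"unknown color space {name!r}; "
                             f"choose from {sorted(_TO)}")
    return _TO[target](_FROM[source](arr))
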