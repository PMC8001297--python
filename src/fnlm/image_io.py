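"""Raster I/O and RGB channel plumbing.

Images are handled as numpy arrays of float64 intensities on [0, 1]:
a single channel ("raster") is a 2-D ``(H, W)`` array, a color image is an
``(H, W, 3)`` array in R, G, B order. Normalization happens on read by
dividing by the dtype maximum (255 or 65535), so the smoothing factors of
the denoisers are meaningful regardless of the source bit depth.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import DimensionError, FormatError

logger = logging.getLogger(__name__)

_DTYPE_MAX = {8: 255, 16: 65535}


def _validate_raster(arr: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise DimensionError(f"{name} must be a 2-D array, got shape {arr.shape}")
    return arr


def _validate_color(arr: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(
            f"{name} must be an (H, W, 3) array, got shape {arr.shape}"
        )
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF file into a normalized ``(H, W, 3)`` float array.

    8-bit input is divided by 255, 16-bit by 65535. Grayscale input is
    replicated into three identical channels; an alpha channel is dropped
    (with a warning) because the denoising pipeline is strictly RGB.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    raw = iio.imread(path)
    if raw.dtype == np.uint8:
        maxv = 255.0
    elif raw.dtype == np.uint16:
        maxv = 65535.0
    else:
        raise FormatError(
            f"unsupported sample format {raw.dtype} in {path}; "
            "expected 8- or 16-bit unsigned integers"
        )
    if raw.ndim == 2:
        chan = raw.astype(np.float64) / maxv
        return np.stack([chan, chan, chan], axis=-1)
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            logger.warning("dropping alpha channel of %s", path)
            raw = raw[:, :, :3]
        if raw.shape[2] == 3:
            return raw.astype(np.float64) / maxv
        if raw.shape[2] == 1:
            chan = raw[:, :, 0].astype(np.float64) / maxv
            return np.stack([chan, chan, chan], axis=-1)
    raise FormatError(f"unsupported channel layout {raw.shape} in {path}")


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a normalized color (or single-channel) image to PNG/TIFF.

    Intensities are scaled by the dtype maximum and rounded half-up, which
    pins the quantization behaviour across platforms.
    """
    if bit_depth not in _DTYPE_MAX:
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None].repeat(3, axis=2)
    arr = _validate_color(arr)
    maxv = _DTYPE_MAX[bit_depth]
    # round-half-up, not banker's rounding
    quant = np.floor(np.clip(arr, 0.0, 1.0) * maxv + 0.5)
    out = quant.astype(np.uint8 if bit_depth == 8 else np.uint16)
    try:
        iio.imwrite(path, out)
    except OSError as exc:  # unwritable path, bad extension, ...
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def split_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the R, G, B planes of a color image as independent arrays."""
    arr = _validate_color(image)
    return arr[:, :, 0].copy(), arr[:, :, 1].copy(), arr[:, :, 2].copy()


def merge_channels(
    r: np.ndarray, g: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Stack three equally sized rasters into an ``(H, W, 3)`` color image."""
    r = _validate_raster(r, "red")
    g = _validate_raster(g, "green")
    b = _validate_raster(b, "blue")
    if not (r.shape == g.shape == b.shape):
        raise DimensionError(
            f"channel shapes differ: {r.shape}, {g.shape}, {b.shape}"
        )
    return np.stack([r, g, b], axis=-1)
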