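"""Brute-force non-local means: the literal, slow reference implementation.

Each output pixel is a convex combination of the pixels inside its search
window; the weight of a neighbour decays exponentially with the (optionally
Gaussian-tapered) squared Euclidean distance between the two patches:

    NL[f](m) = sum_n w(m, n) f(n),
    w(m, n)  = exp(-||v(k_m) - v(k_n)||^2 / d^2) / Z(m),

with Z(m) normalizing the weights to 1 over the search window. This module
makes no attempt to be fast -- per-pixel cost is
O(search_size^2 * kernel_size^2) -- and exists as the correctness oracle for
the integral-image reformulation in :mod:`fnlm.fast`.

Boundary handling is mirror (symmetric) padding by
``search_half + kernel_half`` pixels, cropped after filtering; the fast
module uses the identical scheme so the two agree to floating-point noise.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError
from .image_io import _validate_color, _validate_raster, merge_channels, split_channels
from .params import DenoiseParams

__all__ = [
    "patch_weights",
    "patch_distance",
    "weight_map",
    "nlm_denoise_channel",
    "nlm_denoise_color",
]


def mirror_pad(image: np.ndarray, pad: int) -> np.ndarray:
    """Symmetric (edge-repeating mirror) padding shared by both denoisers."""
    return np.pad(image, pad, mode="symmetric")


def patch_weights(params: DenoiseParams) -> np.ndarray:
    """Unit-sum per-offset weights G(lambda) over the kernel window."""
    k = params.kernel_size
    if params.patch_weighting == "uniform":
        return np.full((k, k), 1.0 / (k * k))
    half = params.kernel_half
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * params.gaussian_std_a**2))
    g = np.outer(g1, g1)
    return g / g.sum()


def patch_distance(
    image: np.ndarray,
    m: tuple[int, int],
    n: tuple[int, int],
    params: DenoiseParams,
) -> float:
    """Weighted squared Euclidean distance between the patches at m and n.

    Returns sum_lambda G(lambda) (f(m+lambda) - f(n+lambda))^2, where G is
    the unit-sum uniform or Gaussian patch taper. Patches reaching past the
    border read from the mirror-padded image.
    """
    image = _validate_raster(image)
    half = params.kernel_half
    fp = mirror_pad(image, half)
    g = patch_weights(params)
    mi, mj = m[0] + half, m[1] + half
    ni, nj = n[0] + half, n[1] + half
    pm = fp[mi - half : mi + half + 1, mj - half : mj + half + 1]
    pn = fp[ni - half : ni + half + 1, nj - half : nj + half + 1]
    return float(np.sum(g * (pm - pn) ** 2))


def weight_map(
    image: np.ndarray, m: tuple[int, int], params: DenoiseParams
) -> np.ndarray:
    """Normalized weights w(m, n) over m's search window, brute force.

    Returned as a ``(search_size, search_size)`` grid indexed by the offset
    n - m; entries sum to 1 and each lies in [0, 1].
    """
    image = _validate_raster(image)
    pad = params.pad
    khalf, shalf = params.kernel_half, params.search_half
    fp = mirror_pad(image, pad)
    g = patch_weights(params)
    mi, mj = m[0] + pad, m[1] + pad
    pm = fp[mi - khalf : mi + khalf + 1, mj - khalf : mj + khalf + 1]
    raw = np.empty((params.search_size, params.search_size))
    for a, di in enumerate(range(-shalf, shalf + 1)):
        for b, dj in enumerate(range(-shalf, shalf + 1)):
            ni, nj = mi + di, mj + dj
            pn = fp[ni - khalf : ni + khalf + 1, nj - khalf : nj + khalf + 1]
            dist = np.sum(g * (pm - pn) ** 2)
            raw[a, b] = np.exp(-dist / params.d**2)
    return raw / raw.sum()


def nlm_denoise_channel(image: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Denoise one channel by direct evaluation of the NLM weights.

    The loop runs over search-window offsets and patch offsets; the pixel
    dimension is vectorized, which leaves the per-pixel arithmetic exactly
    the textbook double sum.
    """
    image = _validate_raster(image)
    if not isinstance(params, DenoiseParams):
        raise ParameterError("params must be a DenoiseParams instance")
    H, W = image.shape
    pad = params.pad
    khalf, shalf = params.kernel_half, params.search_half
    fp = mirror_pad(image, pad)
    g = patch_weights(params)
    inv_d2 = 1.0 / params.d**2

    num = np.zeros((H, W))
    Z = np.zeros((H, W))
    for di in range(-shalf, shalf + 1):
        for dj in range(-shalf, shalf + 1):
            dist = np.zeros((H, W))
            for li in range(-khalf, khalf + 1):
                for lj in range(-khalf, khalf + 1):
                    a = fp[pad + li : pad + li + H, pad + lj : pad + lj + W]
                    b = fp[
                        pad + di + li : pad + di + li + H,
                        pad + dj + lj : pad + dj + lj + W,
                    ]
                    dist += g[li + khalf, lj + khalf] * (a - b) ** 2
            w = np.exp(-dist * inv_d2)
            num += w * fp[pad + di : pad + di + H, pad + dj : pad + dj + W]
            Z += w
    return num / Z


def nlm_denoise_color(image: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Apply :func:`nlm_denoise_channel` to R, G, B with identical params."""
    image = _validate_color(image)
    r, g, b = split_channels(image)
    return merge_channels(
        nlm_denoise_channel(r, params),
        nlm_denoise_channel(g, params),
        nlm_denoise_channel(b, params),
    )
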