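"""Shared parameter containers for the denoisers.

Intensities throughout the package live on a normalized [0, 1] scale, so the
smoothing factor ``d`` is directly comparable to the 0.01-0.05 range that is
meaningful for stained light-microscopy material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import DimensionError, ParameterError

PATCH_WEIGHTINGS = ("uniform", "gaussian")


@dataclass(frozen=True)
class DenoiseParams:
    """Control parameters of the (F)NLM filters.

    Parameters
    ----------
    d:
        Smoothing factor: the exponential decay scale of the similarity
        weight, on normalized intensity units. Larger values smooth more.
    kernel_size:
        Odd side length of the square patch ("kernel") used for the
        similarity comparison.
    search_size:
        Odd side length of the square search window around each pixel.
    patch_weighting:
        ``"uniform"`` weights every in-patch squared difference equally
        (1/kernel_size^2); ``"gaussian"`` applies a unit-sum Gaussian taper
        of standard deviation ``gaussian_std_a``.
    gaussian_std_a:
        Standard deviation (pixels) of the Gaussian patch taper. Only used
        when ``patch_weighting="gaussian"``; defaults to ``kernel_size / 4``.
    """

    d: float = 0.0125
    kernel_size: int = 7
    search_size: int = 21
    patch_weighting: str = "uniform"
    gaussian_std_a: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ParameterError(f"smoothing factor d must be > 0, got {self.d}")
        for name in ("kernel_size", "search_size"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1 or v % 2 == 0:
                raise ParameterError(f"{name} must be an odd integer >= 1, got {v!r}")
        if self.search_size < self.kernel_size:
            raise ParameterError(
                f"search_size ({self.search_size}) must be >= kernel_size "
                f"({self.kernel_size})"
            )
        if self.patch_weighting not in PATCH_WEIGHTINGS:
            raise ParameterError(
                f"patch_weighting must be one of {PATCH_WEIGHTINGS}, "
                f"got {self.patch_weighting!r}"
            )
        if self.gaussian_std_a is None:
            object.__setattr__(self, "gaussian_std_a", self.kernel_size / 4.0)
        elif self.gaussian_std_a <= 0:
            raise ParameterError("gaussian_std_a must be > 0")

    @property
    def kernel_half(self) -> int:
        return (self.kernel_size - 1) // 2

    @property
    def search_half(self) -> int:
        return (self.search_size - 1) // 2

    @property
    def pad(self) -> int:
        """Mirror-padding margin that keeps every patch lookup in range."""
        return self.search_half + self.kernel_half


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest, 0-based with half-open extents."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DimensionError("ROI extents must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise DimensionError("ROI origin must be non-negative")

    def validate_within(self, height: int, width: int) -> None:
        if self.row0 + self.n_rows > height or self.col0 + self.n_cols > width:
            raise DimensionError(
                f"ROI {self} does not fit inside a {height}x{width} image"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.n_rows),
            slice(self.col0, self.col0 + self.n_cols),
        )
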