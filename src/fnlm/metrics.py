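"""No-reference image quality metrics: COV, BRISQUE features, NIQE.

Three evaluators cover the denoising trade-off:

* **COV** (coefficient of variation): std/mean over a flat region of
  interest; drops as noise is removed, insensitive to blur.
* **BRISQUE features**: mean-subtracted contrast-normalized (MSCN)
  luminance coefficients and their four directional paired products,
  summarised by generalized-Gaussian fits; 18 features per scale at two
  scales (36 total). The trained support-vector regressor that maps
  features to an opinion score is a pluggable, out-of-scope component --
  this module delivers the feature stage.
* **NIQE**: a Mahalanobis-type distance between a multivariate Gaussian
  fitted to the features of sharp patches of a pristine corpus and the same
  fit on the test image; grows with both residual noise and over-smoothing.

MSCN coefficients are computed on a 0-255 luminance scale (the normalized
[0, 1] intensities are multiplied by 255) so that the stabilizing constant
C = 1 has its conventional magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate
from scipy.special import gamma as gamma_fn

from .exceptions import (
    DegenerateInputError,
    DimensionError,
    InsufficientDataError,
    UndefinedMetricError,
)
from .image_io import _validate_color, _validate_raster
from .params import ROISpec

__all__ = [
    "ROIStats",
    "MSCNField",
    "AGGDParams",
    "BRISQUEFeatures",
    "NIQEModel",
    "cov_metric",
    "color_luminance",
    "compute_mscn",
    "paired_products",
    "fit_ggd",
    "fit_aggd",
    "brisque_features",
    "fit_niqe_model",
    "niqe_score",
    "mvg_distance",
]

N_FEATURES_PER_SCALE = 18
N_SCALES = 2


# --------------------------------------------------------------------------
# COV
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIStats:
    mean: float
    std: float
    cov: float


def cov_metric(image: np.ndarray, roi: ROISpec) -> ROIStats:
    """Coefficient of variation (population std / mean) over an ROI."""
    image = _validate_raster(image)
    roi.validate_within(*image.shape)
    vals = image[roi.slices()]
    mean = float(vals.mean())
    if mean <= 0:
        raise UndefinedMetricError(
            f"COV undefined for non-positive ROI mean ({mean})"
        )
    std = float(vals.std())  # population (divide-by-N) convention
    return ROIStats(mean=mean, std=std, cov=std / mean)


# --------------------------------------------------------------------------
# MSCN
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MSCNField:
    """MSCN coefficients with the local mean and local deviation fields."""

    coefficients: np.ndarray
    local_mean: np.ndarray
    local_var_field: np.ndarray  # sigma-hat: weighted local std deviation
    C: float


def _gaussian_window(size: int, std: float) -> np.ndarray:
    half = (size - 1) // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * std**2))
    g = np.outer(g1, g1)
    return g / g.sum()


def color_luminance(image: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luminance of a normalized color image, still on [0, 1]."""
    image = _validate_color(image)
    return 0.299 * image[:, :, 0] + 0.587 * image[:, :, 1] + 0.114 * image[:, :, 2]


def compute_mscn(
    image: np.ndarray,
    window_size: int = 7,
    window_std: float = 7.0 / 6.0,
    C: float = 1.0,
) -> MSCNField:
    """Mean-subtracted contrast-normalized coefficients of one channel.

    The local mean is a Gaussian-window weighted average; the deviation
    field is the square root of the weighted variance around that mean.
    Input intensities on [0, 1] are rescaled to 0-255 before normalization
    so the stabilizer ``C`` (default 1) acts on the conventional scale.
    """
    image = _validate_raster(image)
    if C <= 0:
        raise ValueError("C must be > 0")
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be odd")
    lum = image * 255.0
    w = _gaussian_window(window_size, window_std)
    mu = correlate(lum, w, mode="reflect")
    var = correlate(lum * lum, w, mode="reflect") - mu * mu
    sigma = np.sqrt(np.maximum(var, 0.0))
    coeff = (lum - mu) / (sigma + C)
    return MSCNField(coefficients=coeff, local_mean=mu, local_var_field=sigma, C=C)


def paired_products(
    field: MSCNField,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Directional neighbour products of the MSCN coefficients.

    Returns (H, V, D1, D2): horizontal, vertical, main-diagonal and
    anti-diagonal products, each over the valid (clipped) index range.
    """
    f = field.coefficients
    if f.shape[0] < 2 or f.shape[1] < 2:
        raise DimensionError("need at least a 2x2 coefficient field")
    h = f[:, :-1] * f[:, 1:]
    v = f[:-1, :] * f[1:, :]
    d1 = f[:-1, :-1] * f[1:, 1:]
    d2 = f[:-1, 1:] * f[1:, :-1]
    return h, v, d1, d2


# --------------------------------------------------------------------------
# Generalized-Gaussian fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AGGDParams:
    """Asymmetric generalized Gaussian parameters (moment-matched)."""

    shape_alpha: float
    scale_left: float
    scale_right: float
    mean_eta: float

    @property
    def var_left(self) -> float:
        a = self.shape_alpha
        return self.scale_left**2 * gamma_fn(3.0 / a) / gamma_fn(1.0 / a)

    @property
    def var_right(self) -> float:
        a = self.shape_alpha
        return self.scale_right**2 * gamma_fn(3.0 / a) / gamma_fn(1.0 / a)


@lru_cache(maxsize=1)
def _shape_grid() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense shape grid with the two moment-ratio curves used by the fits."""
    alphas = np.arange(0.2, 10.0 + 1e-9, 0.001)
    g1 = gamma_fn(1.0 / alphas)
    g2 = gamma_fn(2.0 / alphas)
    g3 = gamma_fn(3.0 / alphas)
    rho_aggd = g2**2 / (g1 * g3)          # AGGD: rho(alpha) matched to R-hat
    rho_ggd = g1 * g3 / g2**2             # GGD: E[x^2] / E[|x|]^2
    return alphas, rho_aggd, rho_ggd


def fit_ggd(samples: np.ndarray) -> tuple[float, float]:
    """Symmetric generalized-Gaussian fit; returns (shape alpha, variance)."""
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateInputError("GGD fit needs samples with spread")
    m_abs = np.mean(np.abs(x))
    m_sq = np.mean(x * x)
    if m_abs == 0:
        raise DegenerateInputError("GGD fit needs nonzero samples")
    rho_hat = m_sq / m_abs**2
    alphas, _, rho_ggd = _shape_grid()
    alpha = float(alphas[np.argmin((rho_ggd - rho_hat) ** 2)])
    return alpha, float(m_sq)


def fit_aggd(samples: np.ndarray) -> AGGDParams:
    """Asymmetric generalized-Gaussian fit by moment matching.

    Left/right deviations come from the negative/positive halves of the
    sample, the shape parameter from the generalized moment-ratio relation
    solved over a dense grid (0.2-10, step 0.001), and the mean parameter
    from the standard AGGD mean formula.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateInputError("AGGD fit needs samples with spread")
    left = x[x < 0]
    right = x[x > 0]
    if left.size < 1 or right.size < 1:
        raise DegenerateInputError(
            "AGGD fit needs samples on both sides of zero"
        )
    sigma_l = float(np.sqrt(np.mean(left**2)))
    sigma_r = float(np.sqrt(np.mean(right**2)))
    if sigma_l == 0 or sigma_r == 0:
        raise DegenerateInputError("AGGD fit needs spread on both sides")
    gamma_hat = sigma_l / sigma_r
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x**2)
    R_hat = r_hat * (gamma_hat**3 + 1) * (gamma_hat + 1) / (gamma_hat**2 + 1) ** 2
    alphas, rho_aggd, _ = _shape_grid()
    alpha = float(alphas[np.argmin((rho_aggd - R_hat) ** 2)])
    conv = np.sqrt(gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha))
    beta_l = sigma_l * conv
    beta_r = sigma_r * conv
    eta = (beta_r - beta_l) * gamma_fn(2.0 / alpha) / gamma_fn(1.0 / alpha)
    return AGGDParams(
        shape_alpha=alpha, scale_left=beta_l, scale_right=beta_r, mean_eta=eta
    )


# --------------------------------------------------------------------------
# BRISQUE features
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BRISQUEFeatures:
    values: np.ndarray
    scale_count: int = N_SCALES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.shape != (self.scale_count * N_FEATURES_PER_SCALE,):
            raise DimensionError(
                f"expected {self.scale_count * N_FEATURES_PER_SCALE} "
                f"features, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise DegenerateInputError("non-finite feature values")


def _downsample2(image: np.ndarray) -> np.ndarray:
    """2x2 average pooling (crops odd trailing row/column)."""
    h, w = image.shape
    h2, w2 = h - h % 2, w - w % 2
    a = image[:h2, :w2]
    return 0.25 * (a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2])


def _features_from_mscn(field: MSCNField) -> np.ndarray:
    """18-vector: GGD of the coefficients + AGGD of each paired product."""
    feats = list(fit_ggd(field.coefficients))
    for prod in paired_products(field):
        p = fit_aggd(prod)
        feats.extend([p.shape_alpha, p.mean_eta, p.var_left, p.var_right])
    return np.asarray(feats, dtype=np.float64)


def brisque_features(image: np.ndarray) -> BRISQUEFeatures:
    """36 BRISQUE features of one channel: 18 at full and 18 at half scale."""
    image = _validate_raster(image)
    if image.shape[0] < 32 or image.shape[1] < 32:
        raise DimensionError(
            f"image {image.shape} too small for BRISQUE (needs >= 32x32)"
        )
    f1 = _features_from_mscn(compute_mscn(image))
    f2 = _features_from_mscn(compute_mscn(_downsample2(image)))
    return BRISQUEFeatures(values=np.concatenate([f1, f2]))


# --------------------------------------------------------------------------
# NIQE
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NIQEModel:
    """Multivariate Gaussian of pristine-patch features."""

    mean_vec: np.ndarray
    covariance: np.ndarray
    patch_size: int = 32
    sharpness_fraction: float = 0.75

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "fnlm-niqe-model",
            "version": 1,
            "patch_size": self.patch_size,
            "sharpness_fraction": self.sharpness_fraction,
            "mean_vec": self.mean_vec.tolist(),
            "covariance": self.covariance.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NIQEModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "fnlm-niqe-model":
            raise IOError(f"{path} is not a NIQE model file")
        return cls(
            mean_vec=np.asarray(payload["mean_vec"], dtype=np.float64),
            covariance=np.asarray(payload["covariance"], dtype=np.float64),
            patch_size=int(payload["patch_size"]),
            sharpness_fraction=float(payload["sharpness_fraction"]),
        )


def _patch_feature_rows(
    image: np.ndarray, patch_size: int, sharpness_fraction: float
) -> np.ndarray:
    """Per-patch 36-feature rows from the sharp patches of one channel.

    The MSCN field is computed once per scale on the whole image and then
    tiled into non-overlapping ``patch_size`` blocks (``patch_size/2`` at
    half scale). A block is kept when its mean local deviation reaches
    ``sharpness_fraction`` times the sharpest block of the same image.
    """
    image = _validate_raster(image)
    if patch_size < 8 or patch_size % 2:
        raise DimensionError("patch_size must be an even count >= 8")
    p, p2 = patch_size, patch_size // 2
    ny, nx = image.shape[0] // p, image.shape[1] // p
    if ny < 1 or nx < 1:
        raise InsufficientDataError(
            f"image {image.shape} yields no {p}x{p} patches"
        )
    field1 = compute_mscn(image)
    field2 = compute_mscn(_downsample2(image))
    sharp = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            sharp[i, j] = field1.local_var_field[
                i * p : (i + 1) * p, j * p : (j + 1) * p
            ].mean()
    thresh = sharpness_fraction * sharp.max()
    rows = []
    for i in range(ny):
        for j in range(nx):
            if sharp[i, j] < thresh:
                continue
            sub1 = MSCNField(
                coefficients=field1.coefficients[
                    i * p : (i + 1) * p, j * p : (j + 1) * p
                ],
                local_mean=field1.local_mean[i * p : (i + 1) * p, j * p : (j + 1) * p],
                local_var_field=field1.local_var_field[
                    i * p : (i + 1) * p, j * p : (j + 1) * p
                ],
                C=field1.C,
            )
            sub2 = MSCNField(
                coefficients=field2.coefficients[
                    i * p2 : (i + 1) * p2, j * p2 : (j + 1) * p2
                ],
                local_mean=field2.local_mean[
                    i * p2 : (i + 1) * p2, j * p2 : (j + 1) * p2
                ],
                local_var_field=field2.local_var_field[
                    i * p2 : (i + 1) * p2, j * p2 : (j + 1) * p2
                ],
                C=field2.C,
            )
            try:
                row = np.concatenate(
                    [_features_from_mscn(sub1), _features_from_mscn(sub2)]
                )
            except DegenerateInputError:
                continue  # featureless (flat) block
            rows.append(row)
    if not rows:
        raise InsufficientDataError("no usable sharp patches found")
    return np.vstack(rows)


def fit_niqe_model(
    corpus,
    patch_size: int = 32,
    sharpness_fraction: float = 0.75,
) -> NIQEModel:
    """Fit the pristine multivariate-Gaussian feature model.

    ``corpus`` is an iterable of single-channel images (normalized [0, 1]).
    Requires at least feature-dimension + 1 selected patches overall so the
    sample covariance is meaningful.
    """
    all_rows = []
    for img in corpus:
        try:
            all_rows.append(
                _patch_feature_rows(img, patch_size, sharpness_fraction)
            )
        except InsufficientDataError:
            continue
    if not all_rows:
        raise InsufficientDataError("corpus produced no usable patches")
    rows = np.vstack(all_rows)
    dim = rows.shape[1]
    if rows.shape[0] < dim + 1:
        raise InsufficientDataError(
            f"need at least {dim + 1} patches, got {rows.shape[0]}"
        )
    return NIQEModel(
        mean_vec=rows.mean(axis=0),
        covariance=np.cov(rows, rowvar=False),
        patch_size=patch_size,
        sharpness_fraction=sharpness_fraction,
    )


def mvg_distance(
    v1: np.ndarray,
    v2: np.ndarray,
    S1: np.ndarray,
    S2: np.ndarray,
    *,
    sqrt: bool = False,
    ridge: float = 1e-10,
) -> float:
    """Quadratic-form distance between two feature Gaussians.

    ``(v1 - v2)^T ((S1 + S2)/2)^{-1} (v1 - v2)``, symmetric under swapping
    the two Gaussians, zero iff the means coincide. The pooled covariance is
    ridge-regularized by ``ridge * trace/dim`` on the diagonal. ``sqrt=True``
    returns the rooted (Mahalanobis-style) variant.
    """
    v1 = np.asarray(v1, dtype=np.float64).ravel()
    v2 = np.asarray(v2, dtype=np.float64).ravel()
    S1 = np.asarray(S1, dtype=np.float64)
    S2 = np.asarray(S2, dtype=np.float64)
    if v1.shape != v2.shape or S1.shape != S2.shape or S1.shape != (v1.size, v1.size):
        raise DimensionError("mean/covariance dimensions disagree")
    pooled = 0.5 * (S1 + S2)
    dim = v1.size
    pooled = pooled + (ridge * np.trace(pooled) / dim) * np.eye(dim)
    diff = v1 - v2
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"pooled covariance singular after regularization: {exc}"
        )
    val = float(max(diff @ sol, 0.0))
    return float(np.sqrt(val)) if sqrt else val


def niqe_score(
    image: np.ndarray, model: NIQEModel, *, sqrt: bool = False
) -> float:
    """NIQE-style score of one channel under a pristine-fitted model.

    Extracts the test image's sharp-patch features with the model's own
    patch size and selection rule, fits the test mean/covariance, and
    returns the pooled-covariance quadratic distance to the model. Lower is
    closer to the pristine corpus.
    """
    rows = _patch_feature_rows(image, model.patch_size, model.sharpness_fraction)
    if rows.shape[0] < 2:
        raise InsufficientDataError("need >= 2 patches to score an image")
    test_mean = rows.mean(axis=0)
    test_cov = np.cov(rows, rowvar=False)
    return mvg_distance(
        model.mean_vec, test_mean, model.covariance, test_cov, sqrt=sqrt
    )
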