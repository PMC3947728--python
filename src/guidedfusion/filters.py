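"""Low-level image filters composed by the fusion pipelines.

Every windowed operation uses replicate (edge-clamp) padding so weight maps
do not develop dark halos at image borders.  All filters are deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import EPS, GuidedFilterParams, LmmseParams

__all__ = [
    "average_filter",
    "gaussian_smooth",
    "laplacian_magnitude",
    "guided_filter",
    "lmmse_rician_filter",
    "estimate_noise_sigma",
]

#: 4-neighbor discrete Laplacian.
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def _box(img: np.ndarray, size: int) -> np.ndarray:
    """size x size box mean with replicate padding."""
    return ndimage.uniform_filter(img, size=size, mode="nearest")


def average_filter(img, size: int) -> np.ndarray:
    """Arithmetic mean over a ``size`` x ``size`` neighborhood.

    ``size`` must be odd; the window is clamped at the borders by replicate
    padding so the output has the input's shape.
    """
    arr = _as_image(img)
    if size < 1 or size % 2 == 0:
        raise ValueError(f"average filter size must be odd and positive, got {size}")
    if size > 2 * min(arr.shape) - 1:
        raise ValueError(f"average filter size {size} too large for image {arr.shape}")
    return _box(arr, size)


def gaussian_smooth(img, sigma: float, radius: int) -> np.ndarray:
    """Convolve with a normalized truncated Gaussian of the given radius."""
    arr = _as_image(img)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest", radius=radius)


def laplacian_magnitude(img) -> np.ndarray:
    """Absolute response of the 4-neighbor Laplacian (replicate padding)."""
    arr = _as_image(img)
    return np.abs(ndimage.convolve(arr, LAPLACIAN_KERNEL, mode="nearest"))


def guided_filter(guide, src, params: GuidedFilterParams) -> np.ndarray:
    """Edge-preserving guided filter of ``src`` steered by ``guide``.

    Implements the box-filter form of the local linear model: per window the
    output is ``a * guide + b`` with ``a = cov(guide, src) / (var(guide) + eps)``
    and ``b = mean(src) - a * mean(guide)``, averaged over all windows covering
    each pixel.  Runtime is independent of the radius.
    """
    I = _as_image(guide)
    p = _as_image(src)
    if I.shape != p.shape:
        raise ValueError(f"guide shape {I.shape} != input shape {p.shape}")
    size = 2 * params.radius + 1
    mean_I = _box(I, size)
    mean_p = _box(p, size)
    var_I = np.maximum(_box(I * I, size) - mean_I * mean_I, 0.0)
    cov_Ip = _box(I * p, size) - mean_I * mean_p
    a = cov_Ip / (var_I + params.eps + EPS)
    b = mean_p - a * mean_I
    return _box(a, size) * I + _box(b, size)


def lmmse_rician_filter(img, params: LmmseParams) -> np.ndarray:
    """Local-moments LMMSE estimator for Rician-corrupted magnitude data.

    For an observed magnitude image M with noise level sigma, the underlying
    squared signal is estimated from local second and fourth moments as

        x2 = max(0, <M^2> - 2 sigma^2 + K (M^2 - <M^2>)),
        K  = clip(1 - 4 sigma^2 (<M^2> - sigma^2) / var(M^2), 0, 1),

    and the filter returns sqrt(x2).  With sigma = 0 the estimator reduces to
    the identity.  When ``params.sigma_n`` is ``"estimate"`` the noise level is
    estimated from the image's low-intensity windows.
    """
    M = _as_image(img)
    if np.any(M < 0):
        raise ValueError("LMMSE filter expects non-negative magnitude data")
    if isinstance(params.sigma_n, str):
        sigma = estimate_noise_sigma(M, window=params.window)
    else:
        sigma = float(params.sigma_n)
    if sigma < 0:
        raise ValueError(f"sigma_n must be >= 0, got {sigma}")
    if sigma == 0.0:
        return M.copy()
    s2 = sigma * sigma
    M2 = M * M
    m2 = _box(M2, params.window)
    m4 = _box(M2 * M2, params.window)
    var_m2 = np.maximum(m4 - m2 * m2, EPS)
    gain = np.clip(1.0 - 4.0 * s2 * (m2 - s2) / var_m2, 0.0, 1.0)
    x2 = np.maximum(0.0, m2 - 2.0 * s2 + gain * (M2 - m2))
    return np.sqrt(x2)


def estimate_noise_sigma(img, window: int = 7, bins: int = 50) -> float:
    """Robust Rician noise-level estimate from background-dominated windows.

    In background regions a Rician magnitude image is Rayleigh distributed
    with E[M^2] = 2 sigma^2, so sqrt(<M^2>/2) over a background window
    estimates sigma.  The estimate is the histogram mode of that statistic
    over the 10% of windows with the lowest local mean.
    """
    M = _as_image(img)
    if np.any(M < 0):
        raise ValueError("noise estimation expects non-negative magnitude data")
    if min(M.shape) < window:
        raise ValueError(f"image {M.shape} smaller than the moment window {window}")
    m1 = _box(M, window)
    m2 = _box(M * M, window)
    threshold = np.quantile(m1, 0.10)
    candidates = np.sqrt(np.maximum(m2[m1 <= threshold], 0.0) / 2.0)
    if np.ptp(candidates) < EPS:  # degenerate: all windows agree
        return float(max(candidates.flat[0], 0.0))
    counts, edges = np.histogram(candidates, bins=bins)
    mode_bin = int(np.argmax(counts))
    sigma = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
    return float(max(sigma, 0.0))
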