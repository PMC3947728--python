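"""Parameter containers for the fusion pipelines.

All window sizes are in pixels, all intensities on the [0, 1] scale.  The
defaults reproduce the parameterization of the guided-filter fusion (GFF)
lineage: a large/strongly-regularized guided filter for the base-layer
weights and a small/weakly-regularized one for the detail-layer weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np

#: Numerical guard added to every denominator.
EPS = 1e-12

#: Default multi-level weight table: (saliency-difference threshold, weight),
#: thresholds strictly decreasing, scanned top-down, first match wins.
DEFAULT_WEIGHT_LEVELS: Tuple[Tuple[float, float], ...] = (
    (0.30, 1.0),
    (0.25, 0.8),
    (0.20, 0.7),
    (0.15, 0.6),
)


@dataclass(frozen=True)
class GuidedFilterParams:
    """Guided-filter window half-width ``radius`` and regularization ``eps``."""

    radius: int
    eps: float

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"guided filter radius must be >= 1, got {self.radius}")
        if self.eps < 0:
            raise ValueError(f"guided filter regularization must be >= 0, got {self.eps}")


@dataclass(frozen=True)
class LmmseParams:
    """LMMSE Rician estimator parameters.

    ``window`` is the odd side length of the local-moment neighborhood.
    ``sigma_n`` is the noise standard deviation in intensity units, or the
    string ``"estimate"`` to estimate it from the data.
    """

    window: int = 7
    sigma_n: Union[float, str] = "estimate"

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"LMMSE window must be odd and >= 3, got {self.window}")
        if not isinstance(self.sigma_n, str) and self.sigma_n < 0:
            raise ValueError(f"sigma_n must be >= 0, got {self.sigma_n}")
        if isinstance(self.sigma_n, str) and self.sigma_n != "estimate":
            raise ValueError(f"sigma_n must be a float or 'estimate', got {self.sigma_n!r}")


@dataclass(frozen=True)
class WeightLevelTable:
    """Piecewise-constant map from saliency difference to fusion weight.

    ``levels`` is an ordered tuple of ``(threshold, weight)`` pairs with
    strictly decreasing thresholds and non-increasing weights; a difference
    below every threshold receives ``default``.
    """

    levels: Tuple[Tuple[float, float], ...] = DEFAULT_WEIGHT_LEVELS
    default: float = 0.0

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.levels]
        weights = [w for _, w in self.levels]
        if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("weight-level thresholds must be strictly decreasing")
        if any(b > a for a, b in zip(weights, weights[1:])):
            raise ValueError("weight levels must be non-increasing")
        if any(not (0.0 <= w <= 1.0) for w in weights + [self.default]):
            raise ValueError("weight levels must lie in [0, 1]")

    def lookup(self, delta: np.ndarray) -> np.ndarray:
        """Vectorized first-match table lookup on a non-negative difference."""
        delta = np.asarray(delta, dtype=float)
        out = np.full(delta.shape, float(self.default))
        # scan from the smallest threshold up so larger thresholds overwrite,
        # which reproduces top-down first-match semantics
        for threshold, weight in reversed(self.levels):
            out[delta >= threshold] = weight
        return out


@dataclass(frozen=True)
class FusionConfig:
    """Complete parameterization of one fusion run.

    ``scheme`` selects the baseline guided-filter fusion (``"gff"``, binary
    weight maps and Gaussian-smoothed saliency) or the improved scheme
    (``"improved"``, LMMSE-filtered saliency and multi-level weight maps).
    By convention input A is the (possibly noisy) MR image and input B the CT
    image.
    """

    scheme: str = "improved"
    avg_size: int = 31
    gaussian_sigma: float = 5.0
    gaussian_radius: int = 5
    lmmse: LmmseParams = field(default_factory=LmmseParams)
    guided_base: GuidedFilterParams = field(
        default_factory=lambda: GuidedFilterParams(radius=45, eps=0.3)
    )
    guided_detail: GuidedFilterParams = field(
        default_factory=lambda: GuidedFilterParams(radius=7, eps=1e-6)
    )
    weight_levels: WeightLevelTable = field(default_factory=WeightLevelTable)
    tie_policy: str = "first_image"
    normalize_saliency: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("gff", "improved"):
            raise ValueError(f"scheme must be 'gff' or 'improved', got {self.scheme!r}")
        if self.avg_size < 1 or self.avg_size % 2 == 0:
            raise ValueError(f"avg_size must be odd and >= 1, got {self.avg_size}")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.gaussian_radius < 1:
            raise ValueError("gaussian_radius must be >= 1")
        if self.tie_policy != "first_image":
            raise ValueError(f"unsupported tie_policy {self.tie_policy!r}")
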