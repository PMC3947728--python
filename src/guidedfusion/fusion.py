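"""Two fusion pipelines for co-registered grayscale image pairs.

The baseline guided-filter fusion (GFF) decomposes each source into a base
layer (box mean) and a detail layer (residual), compares Laplacian-Gaussian
saliency maps pixelwise to build binary weight maps, refines the maps with a
guided filter steered by the source images, and reconstructs the fused image
as the weighted sum of the four layers.

The improved scheme replaces the Gaussian saliency smoothing with an LMMSE
Rician-noise estimator (so noise in the MR channel does not masquerade as
detail) and replaces the binary weight maps with a multi-level table that
assigns graded weights by the size of the saliency difference, so nearly-tied
pixels are blended instead of winner-takes-all.

By convention input A is the (possibly noisy) MR image and input B the CT
image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EPS, FusionConfig, WeightLevelTable
from .filters import (
    _as_image,
    average_filter,
    gaussian_smooth,
    guided_filter,
    laplacian_magnitude,
    lmmse_rician_filter,
)

__all__ = [
    "TwoScaleDecomposition",
    "WeightMapSet",
    "two_scale_decompose",
    "saliency_gff",
    "saliency_lmmse",
    "normalize_saliency_pair",
    "binary_weight_maps",
    "multilevel_weight_maps",
    "refine_weights",
    "normalize_weight_set",
    "reconstruct",
    "fuse",
]


@dataclass(frozen=True)
class TwoScaleDecomposition:
    """Base (low-frequency) and detail (residual) layers; base + detail
    reproduces the source exactly."""

    base: np.ndarray
    detail: np.ndarray


@dataclass(frozen=True)
class WeightMapSet:
    """Refined per-layer mixing maps for the two sources."""

    base_A: np.ndarray
    base_B: np.ndarray
    detail_A: np.ndarray
    detail_B: np.ndarray


def _check_same_shape(*imgs: np.ndarray) -> None:
    shapes = {img.shape for img in imgs}
    if len(shapes) > 1:
        raise ValueError(f"images must share a shape, got {sorted(shapes)}")


def two_scale_decompose(img, cfg: FusionConfig) -> TwoScaleDecomposition:
    """Split an image into a box-mean base layer and the residual detail."""
    arr = _as_image(img)
    base = average_filter(arr, cfg.avg_size)
    return TwoScaleDecomposition(base=base, detail=arr - base)


def saliency_gff(img, cfg: FusionConfig) -> np.ndarray:
    """Baseline saliency: Gaussian-smoothed Laplacian magnitude."""
    return gaussian_smooth(
        laplacian_magnitude(img), sigma=cfg.gaussian_sigma, radius=cfg.gaussian_radius
    )


def saliency_lmmse(img, cfg: FusionConfig) -> np.ndarray:
    """Improved saliency: LMMSE-filtered Laplacian magnitude.

    The LMMSE estimator shrinks the noise-driven part of the Laplacian
    response toward zero, so the saliency map of a Rician-noisy image stays
    close to that of its clean counterpart.
    """
    return lmmse_rician_filter(laplacian_magnitude(img), cfg.lmmse)


def normalize_saliency_pair(S1, S2) -> tuple[np.ndarray, np.ndarray]:
    """Scale both saliency maps by their joint maximum onto [0, 1].

    The multi-level weight table uses absolute difference thresholds, which
    are only meaningful on a common scale.  If both maps are all-zero they
    are returned unchanged.
    """
    S1 = _as_image(S1)
    S2 = _as_image(S2)
    _check_same_shape(S1, S2)
    peak = max(float(S1.max()), float(S2.max()), EPS)
    return S1 / peak, S2 / peak


def binary_weight_maps(S1, S2, tie_policy: str = "first_image") -> tuple[np.ndarray, np.ndarray]:
    """Winner-takes-all weight maps: P1 = 1 where S1 >= S2, else 0; P2 = 1 - P1.

    Ties are awarded to the first image so that P1 + P2 = 1 everywhere.
    """
    S1 = _as_image(S1)
    S2 = _as_image(S2)
    _check_same_shape(S1, S2)
    if tie_policy != "first_image":
        raise ValueError(f"unsupported tie_policy {tie_policy!r}")
    P1 = (S1 >= S2).astype(float)
    return P1, 1.0 - P1


def multilevel_weight_maps(
    S1, S2, table: WeightLevelTable
) -> tuple[np.ndarray, np.ndarray]:
    """Graded weight maps from the multi-level table.

    Where S1 >= S2 the weight for image A is the table level of the saliency
    difference S1 - S2 (and image B gets 0); where S2 > S1 the roles swap.
    Saliency maps are expected on the normalized [0, 1] scale so the table's
    absolute thresholds apply.
    """
    S1 = _as_image(S1)
    S2 = _as_image(S2)
    _check_same_shape(S1, S2)
    a_wins = S1 >= S2
    levels_a = table.lookup(S1 - S2)
    levels_b = table.lookup(S2 - S1)
    P1 = np.where(a_wins, levels_a, 0.0)
    P2 = np.where(a_wins, 0.0, levels_b)
    return P1, P2


def refine_weights(P1, P2, A, B, cfg: FusionConfig) -> WeightMapSet:
    """Guided-filter refinement of the raw weight maps, then normalization.

    Each source image steers the refinement of its own weight map; the base
    and detail maps differ only in guided-filter parameters (large window and
    strong regularization for the base, small and weak for the detail).
    """
    P1 = _as_image(P1)
    P2 = _as_image(P2)
    A = _as_image(A)
    B = _as_image(B)
    _check_same_shape(P1, P2, A, B)
    raw = WeightMapSet(
        base_A=guided_filter(A, P1, cfg.guided_base),
        base_B=guided_filter(B, P2, cfg.guided_base),
        detail_A=guided_filter(A, P1, cfg.guided_detail),
        detail_B=guided_filter(B, P2, cfg.guided_detail),
    )
    return normalize_weight_set(raw)


def _normalize_pair(wa: np.ndarray, wb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    wa = np.clip(wa, 0.0, 1.0)
    wb = np.clip(wb, 0.0, 1.0)
    total = wa + wb
    dead = total < EPS  # both weights vanished (e.g. tied saliency): split evenly
    safe = np.where(dead, 1.0, total)
    return np.where(dead, 0.5, wa / safe), np.where(dead, 0.5, wb / safe)


def normalize_weight_set(raw: WeightMapSet) -> WeightMapSet:
    """Clamp each map to [0, 1] and normalize each layer pair to sum to 1."""
    base_A, base_B = _normalize_pair(raw.base_A, raw.base_B)
    detail_A, detail_B = _normalize_pair(raw.detail_A, raw.detail_B)
    return WeightMapSet(base_A=base_A, base_B=base_B, detail_A=detail_A, detail_B=detail_B)


def reconstruct(
    W: WeightMapSet, decompA: TwoScaleDecomposition, decompB: TwoScaleDecomposition
) -> np.ndarray:
    """Weighted sum of the four layers, clipped to [0, 1]."""
    _check_same_shape(
        W.base_A, W.base_B, W.detail_A, W.detail_B,
        decompA.base, decompA.detail, decompB.base, decompB.detail,
    )
    fused = (
        W.base_A * decompA.base
        + W.base_B * decompB.base
        + W.detail_A * decompA.detail
        + W.detail_B * decompB.detail
    )
    return np.clip(fused, 0.0, 1.0)


def fuse(A, B, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse two co-registered grayscale images with the configured scheme.

    ``scheme="gff"`` runs the baseline pipeline (Gaussian saliency, binary
    weights); ``scheme="improved"`` runs the noise-aware pipeline (LMMSE
    saliency on both inputs — the estimated noise level of a clean CT image
    is near zero, so the estimator is close to the identity there — jointly
    normalized saliency, multi-level weights).
    """
    cfg = cfg if cfg is not None else FusionConfig()
    A = _as_image(A)
    B = _as_image(B)
    _check_same_shape(A, B)
    if A.min() < -EPS or A.max() > 1 + EPS or B.min() < -EPS or B.max() > 1 + EPS:
        raise ValueError("fusion inputs must lie in [0, 1]")

    decompA = two_scale_decompose(A, cfg)
    decompB = two_scale_decompose(B, cfg)

    if cfg.scheme == "gff":
        S1 = saliency_gff(A, cfg)
        S2 = saliency_gff(B, cfg)
        P1, P2 = binary_weight_maps(S1, S2, cfg.tie_policy)
    else:
        S1 = saliency_lmmse(A, cfg)
        S2 = saliency_lmmse(B, cfg)
        if cfg.normalize_saliency:
            S1, S2 = normalize_saliency_pair(S1, S2)
        P1, P2 = multilevel_weight_maps(S1, S2, cfg.weight_levels)

    W = refine_weights(P1, P2, A, B, cfg)
    return reconstruct(W, decompA, decompB)
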