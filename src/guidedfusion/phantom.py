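"""Synthetic co-registered CT-like / MR-like head phantoms with Rician noise.

The generator emulates the operative property of clinical CT/MR pairs for
fusion work: the two modalities carry complementary structure.  The CT-like
image shows a bright dense "skull" ring with a nearly featureless interior;
the MR-like image shows soft-tissue contrast inside the skull (smooth blobs,
a dark ventricle, low-frequency texture) and almost no signal at the bone.
The MR channel can be corrupted with Rician noise — the noise law of
magnitude MR data, built from Gaussian noise on the real and imaginary
channels, Rayleigh-like at low intensity and positively biased everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomPair", "generate_phantom_pair", "add_rician_noise"]


@dataclass(frozen=True)
class PhantomPair:
    ct: np.ndarray
    mr_clean: np.ndarray
    mr_noisy: np.ndarray
    ideal_composite: np.ndarray
    sigma: float
    seed: int


def add_rician_noise(img, sigma: float, seed, clip: bool = False) -> np.ndarray:
    """Corrupt an image with Rician noise of standard deviation ``sigma``.

    The output is the magnitude sqrt((img + n1)^2 + n2^2) with n1, n2
    independent zero-mean Gaussians of std ``sigma``.  With ``sigma = 0`` the
    input is returned unchanged.  ``clip=True`` clips the result to [0, 1]
    for use as a pipeline input; the raw magnitude (bounded by ~1.5 for unit
    inputs at moderate sigma) is returned otherwise so the noise moments are
    unaltered.
    """
    arr = np.asarray(img, dtype=float)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return arr.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=arr.shape)
    n2 = rng.normal(0.0, sigma, size=arr.shape)
    noisy = np.hypot(arr + n1, n2)
    return np.clip(noisy, 0.0, 1.0) if clip else noisy


def _ellipse_mask(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom_pair(
    size: int = 256,
    seed: int = 0,
    sigma: float = 0.1,
    n_blobs: int = 6,
) -> PhantomPair:
    """Generate a co-registered CT-like / MR-like pair with known truth.

    The pair is deterministic given ``seed``; the Rician corruption of the MR
    channel uses an independent stream derived from the same seed.  The
    ``ideal_composite`` is the pixelwise maximum of the clean images — the
    best achievable union of structure from both modalities.
    """
    if size < 64:
        raise ValueError(f"phantom size must be >= 64, got {size}")
    struct_rng, noise_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    outer_ry, outer_rx = 0.44 * size, 0.38 * size
    inner_ry, inner_rx = 0.38 * size, 0.32 * size

    outer = _ellipse_mask(yy, xx, cy, cx, outer_ry, outer_rx)
    inner = _ellipse_mask(yy, xx, cy, cx, inner_ry, inner_rx)
    ring = outer & ~inner

    # CT: bright skull ring, faint smooth interior gradient, dark background
    ct = np.full((size, size), 0.02)
    ct[inner] = 0.12 + 0.06 * (yy[inner] - cy + size / 2) / size
    ct[ring] = 0.95
    ct = np.clip(ct, 0.0, 1.0)

    # MR: signal-free air background (magnitude MR background is pure noise),
    # no bone signal; soft-tissue blobs, a dark ventricle and smooth texture
    # inside the skull.  The tissue support tapers smoothly well inside the
    # skull so the MR edges live in the interior, complementary to CT.
    tissue = 0.35 * np.ones((size, size))
    for _ in range(n_blobs):
        bcy = cy + struct_rng.uniform(-0.18, 0.18) * size
        bcx = cx + struct_rng.uniform(-0.15, 0.15) * size
        bry = struct_rng.uniform(0.04, 0.10) * size
        brx = struct_rng.uniform(0.04, 0.10) * size
        amp = struct_rng.uniform(0.25, 0.55)
        tissue += amp * np.exp(
            -(((yy - bcy) / bry) ** 2 + ((xx - bcx) / brx) ** 2)
        )
    # dark ventricle
    vry, vrx = 0.10 * size, 0.05 * size
    vent = _ellipse_mask(yy, xx, cy - 0.02 * size, cx, vry, vrx)
    tissue[vent] = 0.08
    # low-frequency texture
    texture = ndimage.gaussian_filter(struct_rng.normal(0.0, 1.0, (size, size)), 4.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    tissue += 0.05 * texture
    support = ndimage.gaussian_filter(
        _ellipse_mask(yy, xx, cy, cx, 0.90 * inner_ry, 0.90 * inner_rx).astype(float),
        0.04 * size,
    )
    mr = np.clip(tissue * support, 0.0, 1.0)

    ideal = np.maximum(ct, mr)
    mr_noisy = add_rician_noise(mr, sigma, noise_rng, clip=True)
    return PhantomPair(
        ct=ct,
        mr_clean=mr,
        mr_noisy=mr_noisy,
        ideal_composite=ideal,
        sigma=float(sigma),
        seed=int(seed),
    )
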