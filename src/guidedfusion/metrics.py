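"""Objective fusion-quality metrics for (A, B, F) triples.

Seven scores are computed, matching the standard comparison suite for
multimodal fusion methods:

* ``zeta_mi`` — normalized mutual information between each source and the
  fused image (0..2, higher is better).
* ``zeta_ssim`` — windowed structural-similarity blend (Yang-style): per
  window a variance-weighted blend of SSIM(A,F) and SSIM(B,F) when the
  sources agree, else the better of the two.
* ``zeta_xp`` — Xydeas-Petrovic gradient-preservation score: how much edge
  strength and orientation is transferred from the sources to F.
* ``zeta_z`` — Zhao-style phase-congruency score: product of correlations of
  the phase-congruency map and its maximum/minimum moment maps.
* ``zeta_p1`` / ``zeta_p2`` — Piella-Heijmans indices: windowed universal
  quality index blends, unweighted and saliency-weighted respectively.
* ``zeta_viff`` — visual-information-fidelity fusion score over four
  band-pass subbands under a Gaussian-scale-mixture noise model.

All metrics are deterministic; identical inputs give bit-identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import EPS
from .filters import _as_image

__all__ = [
    "WindowSpec",
    "MetricReport",
    "mi_measure",
    "ssim_fusion_measure",
    "xydeas_petrovic_measure",
    "zhao_pc_measure",
    "piella_measures",
    "viff_measure",
    "evaluate_all",
]

_C1 = 0.01 ** 2  # SSIM luminance constant, dynamic range L = 1
_C2 = 0.03 ** 2  # SSIM contrast constant


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for the windowed metrics."""

    size: int = 8
    stride: int = 1

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError(f"window size must be >= 2, got {self.size}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


@dataclass(frozen=True)
class MetricReport:
    zeta_mi: float
    zeta_ssim: float
    zeta_xp: float
    zeta_z: float
    zeta_p1: float
    zeta_p2: float
    zeta_viff: float

    def as_dict(self) -> dict[str, float]:
        return {
            "zeta_mi": self.zeta_mi,
            "zeta_ssim": self.zeta_ssim,
            "zeta_xp": self.zeta_xp,
            "zeta_z": self.zeta_z,
            "zeta_p1": self.zeta_p1,
            "zeta_p2": self.zeta_p2,
            "zeta_viff": self.zeta_viff,
        }


# ---------------------------------------------------------------------------
# windowed moments


def _sliding_mean(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Means of all fully-interior size x size windows, subsampled by stride."""
    h, w = x.shape
    if size > h or size > w:
        raise ValueError(f"window size {size} exceeds image shape {x.shape}")
    ii = np.zeros((h + 1, w + 1))
    ii[1:, 1:] = x.cumsum(axis=0).cumsum(axis=1)
    sums = ii[size:, size:] - ii[:-size, size:] - ii[size:, :-size] + ii[:-size, :-size]
    return sums[::stride, ::stride] / (size * size)


def _pair_moments(x: np.ndarray, y: np.ndarray, win: WindowSpec):
    """Per-window means, variances and covariance of two images."""
    mx = _sliding_mean(x, win.size, win.stride)
    my = _sliding_mean(y, win.size, win.stride)
    vx = np.maximum(_sliding_mean(x * x, win.size, win.stride) - mx * mx, 0.0)
    vy = np.maximum(_sliding_mean(y * y, win.size, win.stride) - my * my, 0.0)
    cxy = _sliding_mean(x * y, win.size, win.stride) - mx * my
    return mx, my, vx, vy, cxy


def _ssim_window(mx, my, vx, vy, cxy) -> np.ndarray:
    return ((2 * mx * my + _C1) * (2 * cxy + _C2)) / (
        (mx * mx + my * my + _C1) * (vx + vy + _C2)
    )


def _lambda_weight(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    total = va + vb
    flat = total < EPS
    return np.where(flat, 0.5, va / np.where(flat, 1.0, total))


def _validate_triple(A, B, F):
    A = _as_image(A)
    B = _as_image(B)
    F = _as_image(F)
    if not (A.shape == B.shape == F.shape):
        raise ValueError("A, B and F must share a shape")
    return A, B, F


# ---------------------------------------------------------------------------
# mutual information


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mi_term(X: np.ndarray, F: np.ndarray, bins: int) -> float:
    """MI(X, F) / (H_X + H_F).

    Since MI(X, F) <= min(H_X, H_F), the ratio is bounded by 1/2.  For
    zero-entropy (constant) images the ratio is defined as that supremum 1/2
    when the images are identical and 0 otherwise, which keeps the total
    score in [0, 2] with the maximum attained at F = A = B.
    """
    joint, _, _ = np.histogram2d(
        X.ravel(), F.ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    joint /= joint.sum()
    px = joint.sum(axis=1)
    pf = joint.sum(axis=0)
    hx, hf = _entropy(px), _entropy(pf)
    if hx + hf < EPS:
        return 0.5 if np.array_equal(X, F) else 0.0
    nz = joint > 0
    mi = float(
        (joint[nz] * np.log2(joint[nz] / np.outer(px, pf)[nz])).sum()
    )
    return mi / (hx + hf)


def mi_measure(A, B, F, bins: int = 64) -> float:
    """Normalized mutual-information score, 2 * [MI(A,F)/(H_A+H_F) + MI(B,F)/(H_B+H_F)]."""
    A, B, F = _validate_triple(A, B, F)
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    A = np.clip(A, 0.0, 1.0)
    B = np.clip(B, 0.0, 1.0)
    F = np.clip(F, 0.0, 1.0)
    return 2.0 * (_mi_term(A, F, bins) + _mi_term(B, F, bins))


# ---------------------------------------------------------------------------
# windowed SSIM blend


def ssim_fusion_measure(A, B, F, window: WindowSpec | None = None) -> float:
    """Mean over sliding windows of the source-agreement SSIM blend.

    Where the sources are structurally similar (window SSIM >= 0.75) the
    score blends SSIM(A,F) and SSIM(B,F) with variance weights; elsewhere it
    takes the better of the two, since the fused window can only follow one
    source.
    """
    A, B, F = _validate_triple(A, B, F)
    win = window if window is not None else WindowSpec()
    ma, mb, va, vb, cab = _pair_moments(A, B, win)
    _, mf, _, vf, caf = _pair_moments(A, F, win)
    _, _, _, _, cbf = _pair_moments(B, F, win)
    s_ab = _ssim_window(ma, mb, va, vb, cab)
    s_af = _ssim_window(ma, mf, va, vf, caf)
    s_bf = _ssim_window(mb, mf, vb, vf, cbf)
    lam = _lambda_weight(va, vb)
    blended = np.where(s_ab >= 0.75, lam * s_af + (1 - lam) * s_bf, np.maximum(s_af, s_bf))
    return float(blended.mean())


# ---------------------------------------------------------------------------
# Xydeas-Petrovic gradient preservation

_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8
_TAU_L = 1.5


def _sigmoid(x: np.ndarray, gamma: float, kappa: float, sigma: float) -> np.ndarray:
    return gamma / (1.0 + np.exp(kappa * (x - sigma)))


def _grad(img: np.ndarray):
    sx = ndimage.sobel(img, axis=1, mode="nearest")
    sy = ndimage.sobel(img, axis=0, mode="nearest")
    g = np.hypot(sx, sy)
    alpha = np.arctan2(sy, sx)
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _edge_preservation(gx, ax, gf, af) -> np.ndarray:
    strength_ratio = np.where(gx > gf, gf / (gx + EPS), gx / (gf + EPS))
    orient_pres = 1.0 - np.abs(ax - af) / (np.pi / 2)
    # sigmoids normalized so perfect preservation (ratio 1) scores exactly 1
    q_g = _sigmoid(strength_ratio, _GAMMA_G, _KAPPA_G, _SIGMA_G) / _sigmoid(
        np.array(1.0), _GAMMA_G, _KAPPA_G, _SIGMA_G
    )
    q_a = _sigmoid(orient_pres, _GAMMA_A, _KAPPA_A, _SIGMA_A) / _sigmoid(
        np.array(1.0), _GAMMA_A, _KAPPA_A, _SIGMA_A
    )
    return np.clip(q_g * q_a, 0.0, 1.0)


def xydeas_petrovic_measure(A, B, F) -> float:
    """Gradient-preservation score: how much of each source's edge strength
    and orientation survives in F, weighted by source edge strength."""
    A, B, F = _validate_triple(A, B, F)
    ga, aa = _grad(A)
    gb, ab = _grad(B)
    gf, af = _grad(F)
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab, gf, af)
    tau_a = ga ** _TAU_L
    tau_b = gb ** _TAU_L
    denom = float((tau_a + tau_b).sum())
    if denom < EPS:
        return 1.0  # no edges in either source: nothing to preserve
    return float(np.clip((q_af * tau_a + q_bf * tau_b).sum() / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# phase-congruency score


def _phase_congruency(
    img: np.ndarray,
    nscale: int = 4,
    norient: int = 6,
    min_wavelength: float = 3.0,
    mult: float = 2.1,
    sigma_onf: float = 0.55,
):
    """Phase congruency map plus its maximum/minimum moment maps.

    Log-Gabor quadrature filters over ``nscale`` scales and ``norient``
    orientations; per orientation the congruency is the Kovesi energy
    (projection onto the mean phase minus the deviation) normalized by the
    summed amplitude.  Moments of the per-orientation congruency give the
    orientation-invariant feature maps.
    """
    rows, cols = img.shape
    IM = np.fft.fft2(img)

    fx = np.fft.fftfreq(cols)
    fy = np.fft.fftfreq(rows)
    u, v = np.meshgrid(fx, fy)
    radius = np.hypot(u, v)
    radius[0, 0] = 1.0  # avoid log(0) at DC; the filters are zeroed there
    theta = np.arctan2(-v, u)
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    log_gabors = []
    for s in range(nscale):
        f0 = 1.0 / (min_wavelength * mult ** s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_onf) ** 2)) * lowpass
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = np.pi / norient / 1.3
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    total_energy = np.zeros_like(img)
    total_sum_an = np.zeros_like(img)
    cov_xx = np.zeros_like(img)
    cov_yy = np.zeros_like(img)
    cov_xy = np.zeros_like(img)

    for o in range(norient):
        angle = o * np.pi / norient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta ** 2) / (2 * theta_sigma ** 2))

        eo = [np.fft.ifft2(IM * lg * spread) for lg in log_gabors]
        E = [z.real for z in eo]
        O = [z.imag for z in eo]
        sum_e = np.sum(E, axis=0)
        sum_o = np.sum(O, axis=0)
        sum_an = np.sum([np.hypot(e, od) for e, od in zip(E, O)], axis=0)

        x_energy = np.hypot(sum_e, sum_o) + EPS
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros_like(img)
        for e, od in zip(E, O):
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        energy = np.maximum(energy, 0.0)

        pc_o = energy / (sum_an + EPS)
        cov_x = pc_o * np.cos(angle)
        cov_y = pc_o * np.sin(angle)
        cov_xx += cov_x * cov_x
        cov_yy += cov_y * cov_y
        cov_xy += cov_x * cov_y

        total_energy += energy
        total_sum_an += sum_an

    pc = total_energy / (total_sum_an + EPS)
    spread_term = np.sqrt((2 * cov_xy) ** 2 + (cov_xx - cov_yy) ** 2)
    moment_max = 0.5 * (cov_xx + cov_yy + spread_term)
    moment_min = 0.5 * (cov_xx + cov_yy - spread_term)
    return pc, moment_max, moment_min


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; constant maps correlate 1 only with an equal map."""
    x = x.ravel()
    y = y.ravel()
    if x.std() < EPS or y.std() < EPS:
        return 1.0 if np.allclose(x, y, atol=1e-9) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def zhao_pc_measure(A, B, F) -> float:
    """Product of phase-congruency feature correlations.

    For each of the three feature maps (phase congruency, maximum moment,
    minimum moment) the component score is the best correlation of the fused
    map with the map of A, of B, or of the pixelwise maximum of A and B,
    clamped at 0; the score is the product of the three components.
    """
    A, B, F = _validate_triple(A, B, F)
    feats_a = _phase_congruency(A)
    feats_b = _phase_congruency(B)
    feats_m = _phase_congruency(np.maximum(A, B))
    feats_f = _phase_congruency(F)
    score = 1.0
    for fa, fb, fm, ff in zip(feats_a, feats_b, feats_m, feats_f):
        component = max(_safe_corr(fa, ff), _safe_corr(fb, ff), _safe_corr(fm, ff))
        score *= float(np.clip(component, 0.0, 1.0))
    return score


# ---------------------------------------------------------------------------
# Piella-Heijmans indices


def _uqi_window(mx, my, vx, vy, cxy) -> np.ndarray:
    """Universal quality index per window; 1 for identical degenerate windows."""
    denom = (mx * mx + my * my) * (vx + vy)
    degenerate = denom < EPS
    identical = degenerate & (np.abs(mx - my) <= 1e-9) & (np.abs(vx - vy) <= 1e-12)
    q = 4 * cxy * mx * my / np.where(degenerate, 1.0, denom)
    return np.where(degenerate, np.where(identical, 1.0, 0.0), q)


def piella_measures(A, B, F, window: WindowSpec | None = None) -> tuple[float, float]:
    """Piella-Heijmans fusion indices.

    ``zeta_p1`` is the plain mean over windows of the variance-weighted blend
    of universal quality indices Q_o(A,F) and Q_o(B,F); ``zeta_p2`` weights
    each window by the larger source variance (normalized to sum to 1), so
    structured regions dominate.  Both are clamped to [0, 1].
    """
    A, B, F = _validate_triple(A, B, F)
    win = window if window is not None else WindowSpec()
    ma, mb, va, vb, _ = _pair_moments(A, B, win)
    _, mf, _, vf, caf = _pair_moments(A, F, win)
    _, _, _, _, cbf = _pair_moments(B, F, win)
    q_af = _uqi_window(ma, mf, va, vf, caf)
    q_bf = _uqi_window(mb, mf, vb, vf, cbf)
    lam = _lambda_weight(va, vb)
    blend = lam * q_af + (1 - lam) * q_bf
    p1 = float(blend.mean())
    saliency = np.maximum(va, vb)
    total = float(saliency.sum())
    if total < EPS:
        weights = np.full_like(saliency, 1.0 / saliency.size)
    else:
        weights = saliency / total
    p2 = float((weights * blend).sum())
    return float(np.clip(p1, 0.0, 1.0)), float(np.clip(p2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# VIFF

_VIFF_WEIGHTS = (0.50, 0.25, 0.15, 0.10)
_VIFF_SIGMA_N2 = 0.005
_VIFF_BLOCK = 8


def _viff_subbands(img: np.ndarray) -> list[np.ndarray]:
    """Four band-pass subbands from differences of Gaussian smoothings."""
    levels = [img]
    for sigma in (1.0, 2.0, 4.0, 8.0):
        levels.append(ndimage.gaussian_filter(img, sigma, mode="nearest"))
    return [levels[i] - levels[i + 1] for i in range(4)]


def _viff_information(src_band: np.ndarray, fused_band: np.ndarray):
    """Summed visual information with and without the fusion distortion.

    Per non-overlapping block the fused band is modelled as a gain/additive-
    noise distortion of the source band; information is the Gaussian channel
    capacity under the scale-mixture noise variance ``_VIFF_SIGMA_N2``.
    """
    win = WindowSpec(size=_VIFF_BLOCK, stride=_VIFF_BLOCK)
    _, _, vs, vf, cov = _pair_moments(src_band, fused_band, win)
    gain = np.maximum(cov, 0.0) / (vs + EPS)
    noise_var = np.maximum(vf - gain * cov, 1e-10)
    with_distortion = np.log2(1.0 + gain * gain * vs / (noise_var + _VIFF_SIGMA_N2))
    without_distortion = np.log2(1.0 + vs / _VIFF_SIGMA_N2)
    return float(with_distortion.sum()), float(without_distortion.sum())


def viff_measure(A, B, F) -> float:
    """Visual-information-fidelity fusion score.

    Per subband, each source contributes the ratio of information preserved
    in F to the information the source carries, weighted by how much
    information that source carries; subband scores are combined with fixed
    weights (0.50, 0.25, 0.15, 0.10) from fine to coarse.
    """
    A, B, F = _validate_triple(A, B, F)
    if min(A.shape) < 32:
        raise ValueError("VIFF requires images at least 32x32")
    bands_a = _viff_subbands(A)
    bands_b = _viff_subbands(B)
    bands_f = _viff_subbands(F)
    score = 0.0
    for weight, ba, bb, bf in zip(_VIFF_WEIGHTS, bands_a, bands_b, bands_f):
        vid_a, vind_a = _viff_information(ba, bf)
        vid_b, vind_b = _viff_information(bb, bf)
        if vind_a + vind_b < EPS:
            score += weight  # neither source carries information in this band
            continue
        vif_a = vid_a / (vind_a + EPS)
        vif_b = vid_b / (vind_b + EPS)
        p_a = vind_a / (vind_a + vind_b)
        score += weight * (p_a * vif_a + (1.0 - p_a) * vif_b)
    return float(score)


# ---------------------------------------------------------------------------


def evaluate_all(A, B, F, window: WindowSpec | None = None, bins: int = 64) -> MetricReport:
    """Compute the full seven-score report for one (A, B, F) triple."""
    A, B, F = _validate_triple(A, B, F)
    p1, p2 = piella_measures(A, B, F, window)
    return MetricReport(
        zeta_mi=mi_measure(A, B, F, bins=bins),
        zeta_ssim=ssim_fusion_measure(A, B, F, window),
        zeta_xp=xydeas_petrovic_measure(A, B, F),
        zeta_z=zhao_pc_measure(A, B, F),
        zeta_p1=p1,
        zeta_p2=p2,
        zeta_viff=viff_measure(A, B, F),
    )
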