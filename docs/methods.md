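# Methods

## Pipelines

Both fusion pipelines operate on pairs of co-registered 2-D grayscale images
on the [0, 1] scale, with input A the (possibly noisy) MR image and input B
the CT image.

**Two-scale decomposition.** `base = box_mean(X, avg_size)`,
`detail = X − base`. The decomposition conserves the source exactly by
construction; every windowed operation in the package uses replicate
(edge-clamp) padding so borders do not darken.

**Saliency.** The baseline scheme smooths the 4-neighbor Laplacian magnitude
with a truncated, normalized Gaussian. The improved scheme instead applies a
local-moments LMMSE estimator for Rician magnitude data to the Laplacian
magnitude map: with local box moments `⟨M²⟩`, `⟨M⁴⟩` over an odd window,

    x̂² = max(0, ⟨M²⟩ − 2σ² + K·(M² − ⟨M²⟩)),
    K  = clip(1 − 4σ²(⟨M²⟩ − σ²) / max(⟨M⁴⟩ − ⟨M²⟩², 1e-12), 0, 1),

returning `√x̂²`. The clamps guard degenerate windows (constant
neighborhoods drive the moment variance to zero). With σ = 0 the estimator
is the identity, so the improved saliency degrades gracefully to a plain
Laplacian magnitude on clean inputs; the CT channel, whose estimated noise
level is near zero, is effectively passed through. When σ is not supplied it
is estimated as the histogram mode of `√(⟨M²⟩/2)` over the 10% of windows
with the lowest local mean — in signal-free background the magnitude is
Rayleigh with `E[M²] = 2σ²`. This assumes the image has genuine signal-free
background (true of magnitude MR, where air carries only noise); on images
whose darkest regions carry signal the estimate is biased upward by the
background level.

**Weight maps.** The baseline assigns binary weights by pixelwise saliency
comparison, ties to image A so the pair sums to 1. The improved scheme first
normalizes both saliency maps by their joint maximum — the level table uses
absolute difference thresholds, which are only meaningful on a common
scale — then assigns the tabulated level (1 / 0.8 / 0.7 / 0.6 / 0 at
thresholds 0.30 / 0.25 / 0.20 / 0.15) to the winning image and 0 to the
other.

**Refinement and reconstruction.** Each raw weight map is refined by a
guided filter steered by its own source image: a large, strongly regularized
filter (r=45, ε=0.3) for the base weights and a small, weakly regularized one
(r=7, ε=1e-6) for the detail weights, so base weights follow large-scale
structure while detail weights hug edges. Refined maps are clamped to [0, 1]
and normalized pairwise to sum to 1; pixels where both weights of a pair
vanish (possible when the level table assigns 0 to both sides) fall back to
an even 0.5/0.5 blend, which also makes fusion of two identical images an
exact identity. The fused image is the weighted sum of the four layers,
clipped to [0, 1].

The guided filter itself is the box-filter local-linear-model algorithm:
per window `a = cov(I, p)/(var(I) + ε)`, `b = mean(p) − a·mean(I)`, output
`mean(a)·I + mean(b)`. Every denominator in the package carries a 1e-12
guard, so the ε=0 self-guidance identity holds to ~1e-11 rather than exactly.

## Metrics

Windowed metrics (ζ_SSIM, ζ_P1, ζ_P2) use 8×8 sliding windows with stride 1
— the convention of the metrics they implement — with per-window scalar
statistics from uniform moments; SSIM constants K1=0.01, K2=0.03, L=1.
λ-weights use window variances, with 0.5 at doubly-flat windows; a universal
quality index at a degenerate (zero-denominator) window is 1 when the two
windows are identical and 0 otherwise. ζ_P2's window weights are the larger
source variance normalized to sum to 1.

ζ_MI uses 64-bin histograms on [0, 1] and base-2 logs. Each normalized
ratio MI(X,F)/(H_X+H_F) is bounded by 1/2, so the score lies in [0, 2];
zero-entropy (constant) images take the supremum 1/2 when identical to their
partner, else 0.

ζ_XP uses Sobel gradients, the standard sigmoid constants
(Γ_g=0.9994, κ_g=−15, σ_g=0.5, Γ_α=0.9879, κ_α=−22, σ_α=0.8) and weight
exponent L=1.5, with both sigmoids normalized by their value at perfect
preservation so that exact edge transfer scores 1; this is a strictly
monotone rescaling and does not reorder any two fused images. With no edges
in either source the score is defined as 1.

ζ_Z computes phase congruency per image with log-Gabor quadrature filters
(4 scales × 6 orientations, min wavelength 3, multiplier 2.1, σ_onf 0.55,
no noise-threshold subtraction) and the maximum/minimum moment maps of the
per-orientation congruency. Each of the three feature maps contributes the
best Pearson correlation of the fused map with the feature of A, of B, or of
max(A, B), clamped at 0; the score is the product.

ζ_VIFF decomposes each image into four band-pass subbands (differences of
Gaussian smoothings at σ = 1, 2, 4, 8), partitions each subband into 8×8
blocks, and models the fused block as a gain/additive-noise distortion of
the source block under a scalar Gaussian-scale-mixture channel with noise
variance σ_N² = 0.005. Per subband each source contributes the ratio of
information preserved to information carried, weighted by information
carried; subbands combine with weights 0.50/0.25/0.15/0.10 (fine to coarse).

## Phantom generator

The generator emulates the operative property of clinical CT/MR pairs — the
two modalities carry complementary structure — rather than anatomy or
acquisition physics. The CT-like image is a bright elliptical skull ring
with a faint smooth interior gradient; the MR-like image is zero in air
(magnitude MR background is pure noise), near zero at bone, and carries
smooth soft-tissue blobs, a dark ventricle and low-frequency texture inside
the skull, with the tissue support tapering well inside the ring so MR edges
do not coincide with CT edges. Rician corruption of the MR channel draws two
independent Gaussian fields of std σ and takes the magnitude; the raw
magnitude is returned for distribution-level checks and clipped to [0, 1]
when used as a pipeline input. Defaults are 256×256, σ = 0.1 — a moderate,
clearly visible noise level for unit-range data — and 6 tissue blobs.

What passing tests on these phantoms do not show: robustness to
registration error, intensity non-uniformity (bias fields), anatomy-scale
texture statistics, or spatially varying noise from parallel imaging.

## Problem sizes and numerical choices

The test suite runs phantoms at 64–128 px for identity and oracle checks and
at 256 px (20 seeds) for the improved-vs-baseline comparison, the scale at
which that comparison is defined; the guided-filter brute-force oracle runs
on 16×16 images where the explicit per-window loop is cheap. Histogram and
window parameters above are defaults, overridable per call; all randomness
is generator-seeded and every pipeline stage is deterministic.

## Known limitations

* The multi-level thresholds are absolute on the max-normalized saliency
  scale; images whose saliency is dominated by one extreme outlier compress
  everyone else's differences below 0.15, collapsing the improved scheme
  toward an even blend.
* The noise estimator needs signal-free background; supply σ explicitly when
  there is none.
* Growing the level table monotonically increases transferred information
  (ζ_MI rises along the sweep) but not windowed similarity to a noisy
  source: ζ_P2 measured against the noisy MR input consistently favors
  sparser tables, whose larger fallback regions act like plain averaging.
  The level count is therefore a structure-vs-smoothness trade, not a free
  win on every metric.
* Fusion of more than two sources, color data and 3-D volumes are out of
  scope.
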