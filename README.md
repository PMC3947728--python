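# guidedfusion

Guided-filter fusion of co-registered CT and MR brain images, with a
noise-aware variant for Rician-corrupted MR data, a seven-score objective
fusion-quality suite, and a synthetic CT/MR phantom generator so everything
runs without clinical data.

CT shows dense structure (bone) with little noise; MR shows soft-tissue
contrast but often carries Rician noise — the noise law of magnitude MR data,
Rayleigh-like at low intensity and positively biased everywhere. Fusing the
two into one image that keeps both kinds of structure is a standard step in
neuroradiology pipelines; this package is for people building or evaluating
such fusion steps.

## Method

Both pipelines follow the guided-filter fusion (GFF) recipe. Each source
`X ∈ {A (MR), B (CT)}` is split into a base layer `X * f` (box mean `f`) and
the residual detail layer. Saliency maps steer per-pixel weight maps, which
are refined by a guided filter `G_{r,ε}(P, X)` (output locally a linear
transform of the guiding source image) and the fused image is the weighted
sum of the four layers:

```
F = W_base_A · base_A + W_base_B · base_B + W_det_A · detail_A + W_det_B · detail_B
```

The two schemes differ in two places:

* **Baseline (`gff`)** — saliency `S = |X * h| * g` (Laplacian magnitude,
  Gaussian-smoothed); binary weights `P1 = 1` where `S1 ≥ S2`, else 0.
* **Improved (`improved`)** — the Gaussian `g` is replaced by a local-moments
  LMMSE estimator for Rician magnitude data,
  `x̂² = max(0, ⟨M²⟩ − 2σ² + K(M² − ⟨M²⟩))` with gain
  `K = clip(1 − 4σ²(⟨M²⟩ − σ²)/var(M²), 0, 1)`, which shrinks noise-driven
  saliency toward zero (σ is estimated from background windows when not
  given); and the binary weights become a multi-level table on the jointly
  normalized saliency difference Δ:

  | Δ ≥ 0.30 | ≥ 0.25 | ≥ 0.20 | ≥ 0.15 | otherwise |
  |---------:|-------:|-------:|-------:|----------:|
  | 1        | 0.8    | 0.7    | 0.6    | 0         |

  so nearly-tied pixels are blended instead of winner-takes-all.

Quality is scored with the standard comparison suite: mutual information
(ζ_MI), a windowed SSIM blend (ζ_SSIM), Xydeas–Petrović gradient preservation
(ζ_XP), a phase-congruency score (ζ_Z), the two Piella–Heijmans indices
(ζ_P1, ζ_P2) and visual information fidelity for fusion (ζ_VIFF).

## Worked example

```
guidedfusion demo --size 128 --seed 7 --outdir demo/
```

generates a 128×128 phantom pair (CT ring + soft-tissue MR, Rician noise
σ = 0.1), fuses it with both schemes and prints the metric table:

```
zeta_mi      gff       0.7240        zeta_mi      improved  0.6671
zeta_ssim    gff       0.8975        zeta_ssim    improved  0.9119
zeta_xp      gff       0.6300        zeta_xp      improved  0.8141
zeta_z       gff       0.7645        zeta_z       improved  0.6950
zeta_p1      gff       0.8836        zeta_p1      improved  0.8952
zeta_p2      gff       0.7422        zeta_p2      improved  0.8559
zeta_viff    gff       0.5523        zeta_viff    improved  0.6385
```

The noise-aware scheme wins clearly on ζ_P2 and ζ_VIFF (and here also on
ζ_SSIM, ζ_XP, ζ_P1): its fused image transfers the structured windows of both
sources while passing less MR noise through. Library use:

```python
from guidedfusion import FusionConfig, fuse, evaluate_all, generate_phantom_pair

pair = generate_phantom_pair(size=256, seed=7, sigma=0.1)
fused = fuse(pair.mr_noisy, pair.ct, FusionConfig(scheme="improved"))
report = evaluate_all(pair.mr_noisy, pair.ct, fused)
```

Other CLI subcommands: `fuse --mr MR.png --ct CT.png --scheme improved --out F.png`,
`evaluate --mr ... --ct ... --fused ... --report out.tsv`,
`phantom --size 256 --sigma 0.1 --seed 7 --outdir d/`.

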