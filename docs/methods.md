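# Methods

## Scope and model

`fibro-uq` quantifies collagen in PicroSirius-Red (PSR) stained liver
tiles with a deep-ensemble U-Net and reports, alongside the collagen
proportionate area (CPA), how trustworthy each measurement is. Three
ingredients interact:

1. a **color characterization** stage that summarizes a whole slide by its
   dominant tissue color (for documenting inter-site stain heterogeneity);
2. a **segmentation ensemble** of M independently trained U-Nets whose
   per-pixel mean is the collagen likelihood and whose spread is the model
   uncertainty;
3. a **synthetic-data generator** that emulates the relevant properties of
   multi-site PSR tiles so the full pipeline is exercised and validated
   without clinical material.

## Primary color of a slide

A slide's primary color is computed on a downsampled pyramid level (the
smallest level whose longer side fits 2048 px, configurable): the image is
converted to grayscale (BT.601 luma — one convention has to be fixed),
tissue is separated from background with Otsu's threshold on the 256-bin
histogram (classes {≤ t} / {> t}, smallest maximizing t), background is
replaced by white, and median-cut color quantization with k = 3 is applied.
The representative of the most populous bucket is the primary color,
converted to CIELAB (sRGB, D65, 2° observer) for perceptual comparisons.

Determinism conventions for median cut: the box with the largest
per-channel range is split at the median of that channel (lower half takes
values ≤ median; if the median equals the channel maximum the cut is
strict), ties between boxes go to the lowest index and between channels to
R, G, B order; bucket representatives are rounded means. These conventions
are frozen so that an independent re-implementation reproduces the buckets
exactly, which the test suite checks.

Quantization runs on **tissue pixels only**. Including the whitened
background would let the background bucket win on sparsely covered slides,
and the quantity of interest is the dominant *tissue* color. A flag
restores whole-image quantization for comparison.

Stain deconvolution follows Beer–Lambert: `OD_c = −log10(max(I_c,1)/I0)`
per channel (log base 10, `max(I,1)` to avoid log 0), concentrations are
the inverse stain matrix applied to the OD vector, negatives clamped to 0.
Stain vectors are configuration, not estimation: a Sirius-Red-like default
matrix ships with the package, since per-slide vector estimation is an
external, interactive step.

## Segmentation ensemble

Architecture (depth 3): each encoder level applies two 3×3 conv + ReLU
blocks, with 2×2 max pooling between levels; each decoder step applies
bilinear 2× upsampling, a channel-halving 3×3 convolution, concatenation
with the skip connection, then two 3×3 conv + ReLU blocks; a 1×1
convolution with sigmoid produces the collagen likelihood. There are no
normalization layers; every convolution has a bias. Under this contract
the two reference configurations have exactly 32,665 (filters [8, 16, 32])
and 517,729 ([32, 64, 128]) trainable parameters — these counts are the
architecture's acceptance oracle. The decoder's "upsample → channel-halving
conv → concat" ordering is load-bearing: a plain concat decoder does not
reproduce the counts.

An additive attention-gate variant (1×1 convs: θ on the skip, φ on the
gate, ψ to a scalar, sigmoid rescaling of the skip) is available behind
`attention=True`. With the Mini filter widths it has 522,995 parameters;
the gate widths of a published 612,691-parameter attention variant could
not be reconstructed, so the attention model is best-effort and excluded
from the parameter-count checks.

The engine is pure NumPy (channels-last, float32). Convolutions are
evaluated as nine shifted BLAS matmuls, which profiled ~3× faster than an
im2col lowering on one CPU core at these channel widths; backward passes
are derived analytically and verified against central differences in
float64 (tests tolerate 1e-7 + 1e-3·(|a|+|n|), the residual being
finite-difference noise at gradient magnitudes ≈ 1e-9). Weight
initialization is the standard uniform fan-in scheme,
U(±1/√fan_in), seeded per member.

Training: binary cross-entropy (numerically stable logits form) with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 8, 30 epochs by default.
The learning rate defaults to 1e-3 (a conventional Adam setting;
configurable). Tiles with less than 5% annotated collagen are discarded
from training and validation pools — sub-threshold tiles destabilize early
optimization — but never at inference. Given a seed and a fixed BLAS
thread count, training is bit-reproducible; member seeds derive from a
master seed via `SeedSequence([master, 1000+i])`.

## Uncertainty decomposition

For member likelihoods p_m and ensemble mean p̂:

- aleatoric  = (1/M) Σ p_m (1 − p_m) — image-intrinsic ambiguity,
  concentrated where p_m ≈ 0.5, i.e. on fiber boundaries;
- epistemic  = (1/M) Σ (p_m − p̂)²  — member disagreement, elevated on
  inputs unlike the training data;
- combined   = aleatoric + epistemic = p̂(1 − p̂), an exact algebraic
  identity that the tests verify to 1e-12 on random ensembles.

Both components lie in [0, 0.25]. Tile summaries are spatial means over
**all** pixels; excluding background-only pixels would raise the means on
sparse tiles, and the whole-tile convention keeps them comparable across
tiles (the alternative is a one-line change at the summary step).

A tile is flagged unreliable when its mean epistemic uncertainty exceeds
0.002 — the typical in-distribution value observed for well-trained
ensembles, and the package's scaled-down experiments reproduce that order
of magnitude (clean-tile means ≈ 1e-3). The threshold is data-dependent
and exposed as configuration.

## CPA quantification

Per tile: P = mean of p̂ over all pixels; B = fraction of pixels with
p̂ ≥ 0.5 (boundary inclusive). The ensemble spread of both is the
interquartile range of the per-member values, with quantiles computed by
linear interpolation between order statistics (type 7) — a convention the
outputs record, since IQR definitions differ. B thresholds the ensemble
*mean* map; thresholding members individually and majority-voting differs
for non-binary outputs, and the mean-map formulation is the one with the
algebraic relationship to P. Slide CPA is the tissue-pixel-weighted mean
of tile values so partial-tissue edge tiles do not bias the aggregate.

## Synthetic PSR generator

What it emulates, and why those features:

- **Fiber morphology**: wavy random-walk strands with probabilistic
  branching (a shared step budget keeps the branching process finite),
  dilated to 1–5 px thickness — reproducing the thin, ramified,
  fractal-like geometry that makes collagen segmentation boundary-heavy.
  Fibers are added until the collagen fraction lands in the target range
  (default 6–30%, bracketing reported cohort means of 15–24%), restarting
  with a fresh substream on overshoot.
- **Stain rendering**: per-pixel Beer–Lambert composition
  I = background · 10^(−Σ strengths · OD direction). Collagen strength is
  modulated by a smooth random field (fiber-thickness variation);
  non-collagen tissue receives the counterstain plus 15% of the collagen
  optical density (the "pink parenchyma" of unspecific staining,
  configurable); multiplicative jitter (SD 1%) models sensor/illumination
  noise. Two default training palettes (classic red-on-yellow PSR; PSR
  with a green cytoplasm counterstain) and one held-out
  blue-purple palette for out-of-distribution experiments are > 20 ΔE
  apart in primary color.
- **Artifacts**: air bubbles are rendered at the proportions such
  artifacts typically occupy in afflicted tiles — a disc of radius ≈ one
  third of the tile side, interior blended ~85% toward white, with a
  darker refractive rim of width radius/6 — plus optional JPEG
  recompression noise.
- Reproducibility: every tile derives its RNG streams from
  (master seed, tile index, stream label), so cohorts are bit-identical
  across regenerations and independent of generation order, and masks are
  independent of palette.

What it does **not** model: nuclear/vessel morphology, tissue folds,
scanner optics (MTF, chromatic aberration), stain fading, annotation
noise. Passing tests therefore demonstrate that the pipeline's machinery
is correct and that its uncertainty signals respond to color shift and
occlusion artifacts as intended — not that clinical-cohort Dice or
uncertainty magnitudes are reproduced.

## Scaled-down experiment sizes

The expensive validation experiment uses 200 tiles of 128×128 px from the
two training palettes (80/20 split, 5% filter), an M = 3 U-Net Tiny
ensemble trained 10 epochs, 100 extra held-out in-distribution tiles for
the P–B correlation, and 20 unseen-palette plus 20 air-bubble tiles for
the epistemic comparisons. These sizes keep a full run in the tens of
minutes on a single CPU core while leaving the qualitative structure of
the full-scale protocol (512 px tiles, M = 10, 30 epochs) intact; the
full-scale settings remain the package defaults.

## Numerical choices and degenerate inputs

- Otsu on a constant image raises (no valid threshold); a slide with no
  sub-threshold pixels raises "no tissue detected" rather than returning a
  background color.
- Dice of two empty masks is 1.0 (collagen-free tiles are legitimate at
  inference).
- A single-member "ensemble" predicts but reports no IQRs.
- Bilinear upsampling uses half-pixel-centered sampling
  (align_corners=False); max-pool ties resolve to the first maximum.
- Probability maps are validated to [0, 1]; uncertainty maps to [0, 0.25]
  by construction.

## Known limitations

- The NumPy engine targets the downsized architectures; training
  full-scale U-Nets on 512 px tiles is possible but slow (no GPU path).
- The attention variant's parameter count is not anchored to a published
  figure (see above).
- Epistemic uncertainty from an M = 3 ensemble is a coarser estimate than
  from M = 10; the scaled-down experiments compare ratios, not absolute
  magnitudes, for this reason.
- Synthetic palettes are linear Beer–Lambert idealizations; real scanners
  deviate (glare, white-light assumption violations), which is precisely
  the variability the uncertainty machinery is meant to expose on real
  data.
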