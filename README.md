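# fibro-uq

Uncertainty-aware collagen quantification for PicroSirius Red (PSR) liver
histology.

Collagen proportionate area (CPA) — the fraction of a tissue section
occupied by stained collagen — is a standard image-based fibrosis metric,
but multi-site studies suffer from dramatic differences in PSR staining
protocols (counterstains, stain intensity, scanner color response).
`fibro-uq` provides the building blocks for making CPA measurements
interpretable under that heterogeneity:

- **Slide color characterization** — the *primary color* of a digitized
  slide (Otsu tissue/background separation, background whitening, median-cut
  color quantization over tissue pixels), reported in sRGB and CIELAB so
  cohorts can be compared in a perceptually uniform space; plus Beer–Lambert
  stain deconvolution for profiling stain mixtures.
- **Deep-ensemble segmentation** — downsized U-Nets (U-Net Tiny, 32,665
  trainable parameters; U-Net Mini, 517,729), trained with binary
  cross-entropy and Adam as an ensemble of M independently initialized
  members. The networks and their training run on plain NumPy; no GPU or
  deep-learning framework is required.
- **Uncertainty decomposition** — for member predictions p_m with ensemble
  mean p̂ = (1/M) Σ p_m, the per-pixel predictive variance splits as

      Var = (1/M) Σ p_m (1 − p_m)   +   (1/M) Σ (p_m − p̂)²
             └── aleatoric ──┘            └── epistemic ──┘

  with the algebraic identity aleatoric + epistemic = p̂(1 − p̂). Aleatoric
  uncertainty concentrates on fiber boundaries; epistemic uncertainty rises
  on out-of-distribution inputs (unseen stain colors, air bubbles), and its
  tile mean — typically below 0.002 on in-distribution data — makes a
  practical flag for unreliable predictions.
- **CPA with ensemble spread** — per tile, the mean collagen prediction
  P = (1/WH) Σ p̂ and the segmented area B = (1/WH) Σ 1[p̂ ≥ 0.5], with the
  interquartile range of per-member values as the uncertainty; per slide, a
  tissue-weighted aggregate.
- **Synthetic PSR generator** — wavy, branching collagen-fiber masks
  rendered through Beer–Lambert stain composition under per-site palettes,
  with optional counterstains, air-bubble artifacts and JPEG noise, so the
  whole pipeline is testable without clinical slides.

## Worked example

```python
from fibrouq import UNET_TINY, TrainConfig, binarize, dice_score
from fibrouq.synthetic_histology import DEFAULT_PALETTES, FiberSpec, make_cohort
from fibrouq.ensemble_uncertainty import (
    train_ensemble, ensemble_predict, combined_map, summarize_tile,
)
from fibrouq.cpa_quantification import quantify_tile

tiles, _ = make_cohort(DEFAULT_PALETTES, FiberSpec(), n_tiles=30, seed=5, size=64)
train = [(t.image, t.mask) for t in tiles if t.split == "train"]
ens = train_ensemble(UNET_TINY, TrainConfig(epochs=60), train, M=3, master_seed=42)

tile = next(t for t in tiles if t.split == "val")
pred = ensemble_predict(ens, tile.image)
q = quantify_tile(pred)
s = summarize_tile(combined_map(pred))
print(f"dice={dice_score(binarize(pred.mean_map), tile.mask):.3f}")
print(f"P={q.P:.3f}  B={q.B:.3f}  iqr_P={q.iqr_P:.4f}  iqr_B={q.iqr_B:.4f}")
print(f"aleatoric={s.mean_aleatoric:.4f}  epistemic={s.mean_epistemic:.5f}")
```

prints (a few minutes on one CPU core):

```
dice=0.970
P=0.286  B=0.288  iqr_P=0.0100  iqr_B=0.0116
aleatoric=0.0307  epistemic=0.00180
```

`dice` is the overlap between the thresholded ensemble mean and the ground
truth (whose true collagen fraction here is 0.287); `P` and `B` are the two
tile-level collagen fractions, which agree closely (their correlation across
tiles is ≈ 1); the IQRs are the spread of those fractions across ensemble
members; the tile-mean aleatoric uncertainty reflects fiber-boundary
ambiguity, and the small epistemic value (< 0.002) says the members agree —
the prediction is in-distribution.

A command-line interface mirrors the library:
`fibro-uq synth-generate`, `fibro-uq tile`, `fibro-uq color-characterize`,
`fibro-uq train`, `fibro-uq predict`, `fibro-uq quantify`.

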