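# mpmtex

Texture-based classification of label-free multiphoton microscopy tiles:
colorectal liver metastasis (tumor) versus normal liver tissue.

Label-free multiphoton imaging acquires three co-registered signal
channels per field of view (FoV): CARS (coherent anti-Stokes Raman
scattering, lipid-rich structures; red), TPEF (two-photon excited
fluorescence of endogenous fluorophores; green) and SHG (second harmonic
generation of fibrillar collagen; blue).  Tumor tissue shows gland/nest
epithelial motifs with dense collagenous stroma; normal liver shows
hepatocyte cords with sparse reticulin and occasional lipid droplets.
These differences are textural, which makes tile-level classification
possible without staining: useful, for example, when assessing resection
margins where per-tile tumor probability maps localize suspicious
regions.

`mpmtex` implements that pipeline end to end, for image analysts and
methodologists who want a tested, reproducible reference implementation:

1. **Tile QC** — FoVs with tissue borders, large holes or detector
   saturation are discarded by explicit numeric rules.
2. **Texture features** — per channel, after min–max normalization to
   [0, 1]: five first-order statistics (mean μ, standard deviation σ,
   kurtosis m₄/m₂², skewness m₃/m₂^1.5, Shannon entropy of the 256-bin
   histogram) and, for pixel distances d ∈ {1, 12, 30} (1 µm/pixel), four
   gray-level co-occurrence matrix (GLCM) parameters averaged over the
   orientations 0°/45°/90°/135°:

   contrast = Σᵢⱼ P(i,j)(i−j)², correlation = Σᵢⱼ P(i,j)(i−μᵣ)(j−μ꜀)/(σᵣσ꜀),
   energy = Σᵢⱼ P(i,j)², homogeneity = Σᵢⱼ P(i,j)/(1+|i−j|),

   giving 17 parameters per channel.  The default *selected* feature set
   uses all 17 from CARS and TPEF but only 8 from SHG (first-order plus
   contrast at each distance): 42 features per FoV.
3. **Discriminant classification** — Gaussian class-conditional model
   with pooled (LDA) or per-class (QDA) covariance; posterior
   P(tumor | x) ∝ π_tumor · N(x; μ_tumor, Σ); a tile is called tumor when
   its posterior exceeds 0.5.
4. **Evaluation** — leave-one-sample-out cross-validation (all images of
   one tissue sample classified by a model trained on all others) and a
   patient-level train/test split; correct rate, sensitivity/specificity
   (tumor = positive), per-sample correct fractions, posterior-confidence
   summaries.
5. **Maps** — per-sample tiled posterior maps: light blue (p = 0) → gray
   (p = 0.5) → orange (p = 1), discarded tiles dark gray.

Because raw patient images are rarely shareable, the package includes a
seeded synthetic cohort generator that emulates the two tissue classes'
motifs with a controllable separability knob, so the whole pipeline is
testable without any external data.

## Worked example

```python
import mpmtex as m

cfg = m.SyntheticConfig(n_matched_patients=4, tiles_per_sample=10, seed=42)
cohort = m.generate_cohort(cfg)                  # 8 samples, 80 FoVs
kept = [m.filter_sample(s)[0] for s in cohort]   # tile QC
spec = m.FeatureSpec.reduced_shg()               # 42-feature selected set
table = m.features_table(kept, spec)
report, preds = m.leave_one_sample_out_cv(table, spec, "linear")
print(report.to_text())
```

prints

```
images: 80  correct rate: 1.000
sensitivity (tumor recall): 1.000  specificity (normal recall): 1.000
macro per-sample: tumor 1.000  normal 1.000
true-class posterior >= 0.95: 1.000  >= 0.99: 1.000
```

At full separability the synthetic classes are easy: every one of the 80
tiles is classified correctly out-of-fold, and every tile's true-class
posterior exceeds 0.99.  Lowering `separability` toward 0 degrades the
correct rate toward chance; `m.SyntheticConfig(separability=0.0, ...)`
is the built-in null control.

The same pipeline runs from the shell:

```sh
mpmtex all --seed 1 --out runs/demo        # simulate -> QC -> features ->
                                           # LOSO-CV -> report + maps
mpmtex simulate --out cohort/              # or stage by stage
mpmtex features --in cohort/ --spec reduced_shg --out features.csv
mpmtex crossval --features features.csv --out report.json
```

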