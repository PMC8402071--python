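# berrymorph

Outline morphometrics and multivariate discrimination of fruit
silhouettes, built for berry (table-grape) phenotyping: from binary
two-orientation silhouette images to size/shape traits, elliptic Fourier
shape descriptors, canonical discriminant analysis and variety-level
clustering.

## The problem

Berry size and shape drive both variety identification and the design of
sorting/processing machinery, but visual shape assessment is subjective
and ordinal. Given calibrated silhouettes of each berry in two
orientations (a horizontal L×W view and a vertical W×T cross-section,
with a known mm-per-pixel scale), the pipeline quantifies:

**Size/shape traits** per berry — projected area *PA* (mm²), equivalent
diameter *ED* = √(4·PA/π), perimeter *P*, circularity *C* = 4π·PA/P²,
dimensions *L* ≥ *W*, *T*, and the derived traits

- elongations *Eh* = L/W, *Ev* = W/T,
- geometric mean diameter *Dg* = (L·W·T)^(1/3),
- sphericity *φ* = 100·Dg/L (%),
- ellipsoid volume *V* = (π/6)·L·W·T and surface area *SA* = π·Dg².

**Shape descriptors** — each closed contour is traced into a Freeman
chain code and expanded into elliptic Fourier harmonics
(Kuhl–Giardina): x(t) = A₀ + Σₙ aₙcos(2πnt/T) + bₙsin(2πnt/T), likewise
y(t) with (cₙ, dₙ), 20 harmonics by default. Coefficients are normalized
by the first-harmonic ellipse (size-, rotation-, translation- and
start-point-invariant; a₁ = 1, b₁ = c₁ = 0) and summarized by covariance
PCA, with shape variation visualized as outlines reconstructed at
mean ± 2 SD along each component.

**Group statistics** — one-way ANOVA with Duncan's multiple range
letters; canonical discriminant analysis (eigenvalues λᵢ of W⁻¹B,
canonical correlations √(λᵢ/(1+λᵢ)), structure matrix, resubstitution
classification by Mahalanobis distance); MANOVA via Wilks'
Λ = Π 1/(1+λᵢ) (Rao's F) and Pillai's trace Σ λᵢ/(1+λᵢ); pairwise
Hotelling T² tests with Bonferroni correction and Mahalanobis D²; and
UPGMA clustering of variety centroids.

Because berry image panels are rarely redistributable, the package ships
a first-class synthetic generator: ellipse-, sphere- and drop-like
outline families whose (L, W, T) distributions are parameterized per
variety, so every stage is testable against known ground truth. A
built-in ten-variety panel mimics published dimension statistics of
Anatolian table grapes.

## Worked example

```python
from berrymorph import synth, morpho, mvstats

configs = [
    synth.VarietyConfig("Round", "sphere", 25.0, 1.0, 24.5, 1.0, 24.5, 1.0, n_berries=20),
    synth.VarietyConfig("Long", "ellipse", 33.0, 1.5, 21.0, 1.0, 21.5, 1.0, n_berries=20),
    synth.VarietyConfig("Teardrop", "drop", 30.0, 1.2, 22.0, 1.0, 22.5, 1.0,
                        asym=0.3, n_berries=20),
]
masks, truth = synth.generate_dataset(configs, master_seed=8, scale=0.1)
traits = morpho.measure_dataset(masks)
fit = mvstats.cda_fit(traits[["L", "W", "T", "phi", "Eh", "C_h"]], traits["variety"])
```

Running `python examples/04_discriminant_analysis.py` (this exact
analysis) prints:

```
function  eigenvalue  %variance  canonical r
       1      24.550       90.4        0.980
       2       2.599        9.6        0.850

Wilks' lambda = 0.01088 (F = 74.4, df = 12/104, p = 2.2e-45)
Pillai trace  = 1.683 (F = 46.9, p = 7.9e-37)

pairwise squared Mahalanobis distances:
           Long  Round  Teardrop
Long        0.0  183.1      16.7
Round     183.1    0.0      60.7
Teardrop   16.7   60.7       0.0
...
98.3% of berries correctly classified; small D^2 marks similar varieties.
```

The first discriminant function (90.4% of the between-group separation,
canonical correlation 0.980) contrasts elongated and round berries; the
tiny Wilks' Λ says almost all generalized variance is between varieties;
the D² matrix shows the teardrop variety is far closer in trait space to
the elongated one (16.7) than either is to the round one.

The other examples cover silhouette generation (`01`), trait measurement
with ground-truth recovery (`02`), elliptic Fourier PCA (`03`) and the
full configured pipeline (`05`), which on the built-in ten-variety panel
(800 silhouettes at 0.05 mm/px, ~30 s) reports shape PC1 = 99.6% of
outline variation and 80.2% resubstitution accuracy from the ten
size/shape traits.

A thin CLI mirrors the stages:

```bash
berrymorph generate --seed 1 --out data/
berrymorph measure --in data/masks --scale 0.05 --out traits.csv
berrymorph efd --in data/masks --scale 0.05 --out coeffs.csv
berrymorph discriminate --traits traits.csv --out results/
berrymorph run --seed 1 --out results/
```

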