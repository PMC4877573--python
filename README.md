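# epidermtex

Texture-based identification of plant species from microscopy images of the
leaf epidermis.

Dissociated abaxial epidermis preparations carry rich taxonomic signal: the
pavement-cell mosaic, the density and geometry of stomatal complexes, and
the micro-texture of the cuticle all differ between species. The classical
workflow measures a handful of stomatal traits by hand (stomata density,
guard-cell length, stomatal-complex width) and classifies on those three
numbers. `epidermtex` implements the computational alternative: describe
the whole micrograph with texture descriptors and classify the descriptor
vectors — and provides the evaluation protocols to compare both approaches,
including their robustness to phenotypic plasticity (the same species grown
in different environments).

## Methods at the core

All descriptors operate on 8-bit grayscale images `f(x, y)`, optionally
contrast-enhanced by a saturating linear histogram stretch (1% of pixel
mass clipped at each intensity extreme).

* **Fourier circular** — with `F(u, v)` the centered magnitude spectrum,
  descriptor entry *g* is the sum of `|F|` over all bins within Euclidean
  distance *g* of the zero-frequency bin, for integer radii
  `g = 1 … ⌊min(M, N)/2⌋ − 1`. A native 2080×1540 micrograph yields 769
  values.
* **Fourier circular-angular** — `|F|` summed over 64 ring×wedge sectors:
  8 annuli with outer radii 3, 6, …, 24 bins times 8 equal 45° wedges.
* **CITA (corrosion-inspired texture analysis)** — the image is a metal
  surface evolved as a cellular automaton: per synchronous step each cell
  with state difference `d = s − min(Moore neighbours) > v` corrodes by
  `C = ⌊γ·d⌋` (defaults `v = 2`, `γ = 0.05`); the cumulative corroded mass
  after each of `T = 200` iterations is the descriptor.
* **LBP** — the classic 3×3 local binary pattern: each interior pixel's
  8 neighbours are thresholded against the centre (`s(x ≥ 0) = 1`, bit 0
  east, counterclockwise) and the 256-bin code histogram is the feature.

Classification: per-fold z-scoring and PCA, then 1-nearest-neighbour
(Euclidean, deterministic tie-breaks) or a pooled-covariance Gaussian
linear discriminant, evaluated by stratified 6-fold cross-validation
repeated 10 times (mean ± std accuracy, per-class success rates), plus a
split-environment protocol that trains on one environment and tests on
held-out samples from another.

Because no public epidermis image set accompanies the methodology, the
package includes a seeded synthetic generator (cell mosaic + 1/f^α spectral
noise + elliptical stomata with controllable trait distributions and a
plasticity-shift mode) so every stage is testable end-to-end.

## Worked example

```python
import epidermtex as et
from epidermtex.imaging import enhance_contrast

models = et.well_separated_models(4)
images, labels, traits = et.generate_dataset(models, 6, size=(128, 128), seed=42)
feats = et.FourierDescriptor(mode="circular").transform(
    [enhance_contrast(img) for img in images])
table = et.make_feature_table(feats, labels.species.tolist(),
                              labels.sample_id.tolist(), labels.environment.tolist())
res = et.stratified_cv(table, "knn", k=1, folds=6, repeats=10, seed=0, pca=10)
print(f"mean accuracy {res.mean_accuracy:.2f}% (+/-{res.std_accuracy:.2f}), "
      f"PCA components {res.n_components}")
for sp, rate in res.per_class_rate.items():
    print(f"  {sp}: {rate:.1f}%")
```

prints

```
mean accuracy 97.08% (+/-1.91), PCA components 10
  species_00: 88.3%
  species_01: 100.0%
  species_02: 100.0%
  species_03: 100.0%
```

i.e. 24 synthetic micrographs of four species, described by 63 Fourier
circular values each, are recovered at 97% mean accuracy over ten repeats
of stratified 6-fold cross-validation; the per-class lines are the success
rates per species.

The same pipeline is available from the shell:

```sh
epidermtex synth --config models.yaml --n 9 --size 512x512 --seed 7 --out imgs/
epidermtex extract --images imgs/ --labels imgs/labels.csv --method lbp --out lbp.csv
epidermtex classify --features lbp.csv --classifier knn --k 1 --folds 6 --repeats 10 --pca auto --seed 42
epidermtex evaluate-split --train gallery.csv --test marsh.csv
epidermtex report cv1.json cv2.json
```

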