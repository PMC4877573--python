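# Methods

This note documents the models, conventions and design choices behind
`epidermtex`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic validation does and
does not establish.

## Contrast enhancement

The stretch maps `p ↦ (p − lo)·255/(hi − lo)`, clipped to [0, 255] and
rounded, where `lo`/`hi` are the `q` and `1 − q` quantiles of the pixel
multiset (`q` = 0.01 by default: 1% of pixel mass saturates at each
extreme). Quantiles use a nearest-rank convention: with `n` pixels and
`k = ⌊q·n⌋`, `lo` and `hi` are the k-th and (n−1−k)-th order statistics
(0-indexed). Consequences worth knowing: the map is monotone; it is
idempotent up to ±1 level of rounding; the output support touches 0 and
255 whenever `hi > lo`; and a near-constant image (`hi == lo`) passes
through unchanged with a warning rather than raising, so degenerate
synthetic inputs flow through the pipeline. Clipping happens on the real
line before rounding. RGB inputs are converted with the BT.601 luma
weights (0.299, 0.587, 0.114); no formula is canonical here, so the choice
is recorded in one constant.

## Fourier descriptors

The spectrum is the unnormalised forward 2-D DFT, shifted so zero
frequency sits at bin `(⌊M/2⌋, ⌊N/2⌋)`; magnitudes are raw `|F|` (no log,
no windowing). Distances are measured in bin units from that centre bin,
with no half-bin correction for even dimensions.

*Circular*: entry `g` sums `|F|` over bins with distance ≤ g, `g = 1…G`
with `G = ⌊min(M, N)/2⌋ − 1` — the only simple radius bound consistent
with 769 descriptors at 2080×1540. The centre (DC) bin is included
(cumulative "from the origin"), making the sequence non-decreasing.

*Circular-angular*: annuli are half-open `(r_lo, r_hi]` with outer radii
3, 6, …, 24, so every bin is counted exactly once and the 64 sector sums
recompose the `0 < r ≤ 24` annulus total exactly. The DC bin is excluded —
its angle is undefined. Wedges are `[kπ/4, (k+1)π/4)` counterclockwise
from the positive horizontal-frequency axis; ordering is ring-major. Any
fixed wedge origin yields an equivalent descriptor up to permutation; this
one is pinned so brute-force oracle tests are bitwise meaningful.

## Corrosion automaton (CITA)

The update rule is reconstructed from its prose description and kept in a
single function (`corrosion_amounts`) so an alternative form can be swapped
in: per synchronous step, `d` is the central state minus the minimum state
over the Moore 8-neighbourhood (centre excluded; border cells use in-grid
neighbours only), and a cell with `d > v` loses `C = ⌊γ·d⌋`. Defaults
`v = 2`, `γ = 0.05`, `T = 200`. The descriptor is the running cumulative
corroded mass, which equals the total state loss from the initial grid at
every step (mass conservation), is non-decreasing, and freezes permanently
once an iteration corrodes nothing — the automaton has reached its fixed
point, and the implementation short-circuits there.

Two conventions the prose leaves open are fixed as follows: corrosion
lowers states toward the pit (the descriptor is invariant to the opposite
reading under intensity inversion), and mass counts `Σ C`, not the number
of corroding cells. The vectorised kernel uses a full 3×3 minimum filter
with edge replication, which is provably identical to the centre-excluded
truncated rule for `v ≥ 0`: the extra values entering the minimum are
copies of in-window cells or the centre itself, and a centre-dominated
minimum yields `d = 0`, below any non-negative threshold. The naive
double-loop reference implementation ships in the package and is compared
bitwise in the tests.

## Local binary patterns

Classic 3×3 LBP: `P = 8` integer-offset neighbours at `R = 1` (forced by
the 256-bin histogram), bit `p` set when neighbour `g_p ≥ g_c`, bit 0 at
the east neighbour proceeding counterclockwise. No circular interpolation
— at integer offsets it would only blur real pixel values. Border pixels
are skipped, so the histogram total is exactly `(M − 2R)(N − 2R)`. Raw
counts are the default; frequency normalisation is a transformer switch
recorded in the run configuration. Codes are invariant to any strictly
increasing intensity remapping, including the global shifts the
enhancement step can introduce.

## Classification pipeline

Feature tables are DataFrames (`sample_id`, `species`, `environment`,
`f0…fn`). Standardisation (z-score) and PCA are fitted on training folds
only; the texture and trait features have incommensurate scales, so
standardisation defaults on. PCA components are either a fixed count or
`auto` — an inner 3-fold CV over a small grid (2, 5, 10, 20, 40, 80,
capped by the training-fold size), selected per outer fold, since no
single component count is optimal for every descriptor/classifier pair.

k-NN uses Euclidean distance with pinned tie rules (equidistant training
rows: lowest index; tied votes: smallest class label). The linear
discriminant pools within-class covariance with empirical priors and adds
a ridge of `1e-6 × trace(S)/d` to the diagonal, because post-PCA pooled
covariances can remain ill-conditioned. Both are written in-package so the
tie/regularisation behaviour is explicit; they are cross-checked against
scikit-learn's implementations on tie-free, well-conditioned data in the
test suite.

Cross-validation is stratified 6-fold repeated 10 times (defaults).
Accuracy is pooled over the folds of a repeat (every sample classified
exactly once per repeat), and the std is taken across repeats. Rows are
sorted by `sample_id` before splitting, making results invariant to input
order; per-repeat shuffle seeds derive deterministically from one master
seed. Per-class rates, weighted by class size, recompose the overall
accuracy to machine precision. The split-environment protocol fits the
full pipeline on one table and reports overall/per-class success on a
held-out table, the direct measure of plasticity robustness. Trait fusion
appends the three manual measurements after the texture vector (+3
features, matching the bookkeeping of the texture+quantitative runs).

## Synthetic generator

Each species is a parameter vector: expected stoma count per image
(Poisson), truncated-normal axis lengths (truncation at zero keeps the
moment checks elementary), a von Mises orientation concentration,
pavement-cell spacing, background power-law exponent α (noise amplitude
spectrum `f^{−α/2}`), and intensity base/contrast. Scenes render at 2×
resolution and box-downsample, so descriptor tests are not dominated by
aliasing. The generator returns the realized traits (count, mean axis
lengths) as the ground-truth "manual measurements".

The default 8-species panel pairs geometrically spaced mosaic scales
(6 → 44 px) with alternating spectral exponents (1.0–3.4) and noise
amplitudes, so each species occupies a distinctive radial energy profile;
trait parameters step monotonically so the trait-only baseline is also
informative. This family was chosen as the minimal one exercising all four
descriptor types — wedges see orientation concentration, rings see the
mosaic scale and spectral slope, CITA sees cell-wall contrast steps, LBP
sees the micro-pattern statistics — and not as a biological claim. What
the synthetic studies do *not* establish: performance on real stained
preparations, where illumination gradients, staining variability,
trichomes and focus artefacts add nuisance structure absent here.

## Study sizes and evaluation conditions

The synthetic identification study uses 8 species × 12 images at 256×256
(descriptor length 127 for Fourier circular) with PCA to 20 components —
comfortably separable by design, and a fraction of the native-resolution
geometry, which is exercised separately by generating one 2080×1540 image
to confirm the length constants (769/64/833/200/256). The plasticity
scenario shifts one species' trait parameters by factors (0.5, 1.5, 1.3)
for nine held-out second-environment samples, mirroring a
nine-sample/one-species hold-out design: trait-only identification of the
shifted samples collapses while Fourier features are unaffected, because
the shift moves the trait distribution across class boundaries but leaves
the micro-texture untouched. Only the direction of that contrast is a
stable claim; its magnitude depends on the shift factors and panel
spacing.

## Known limitations

* The CITA rule is a faithful reconstruction of a prose description; if a
  variant definition is required (e.g. a different corrosion increment),
  replace `corrosion_amounts`.
* `auto` PCA selection is greedy over a fixed grid, not a full nested
  optimisation.
* The generator's stomata may overlap at high densities; realized density
  is the drawn count, not a post-overlap count.
* Mixed image sizes are rejected for size-dependent descriptors rather
  than resampled; resize explicitly if needed.
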