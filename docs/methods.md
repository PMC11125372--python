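# Methods

## Problem

Archaeobotanical and palaeobotanical identification of grape (*Vitis*) seeds
rests on seed shape: wild and cultivated grapevines, and the various wild
*Vitis* species of Eurasia and North America, differ in the silhouette of the
pip (body elongation, taper, and the apical beak). Given scanned dorsal
silhouettes of modern reference seeds grouped by species and a set of
"unknown" specimens (e.g. fossil pips), the pipeline asks: which reference
group do the unknowns resemble, and how confidently can individual specimens
be assigned?

## Pipeline

1. **Imaging.** Grayscale scans (dark seed, light background, known dpi) are
   thresholded (Otsu by default, or a fixed value), cleaned (largest
   connected component kept, interior holes filled — a seed silhouette is
   simply connected, so inner loops are scanner artifacts), traced at the
   0.5 iso-contour (sub-pixel, which keeps high-harmonic noise down relative
   to pixel-edge tracing), converted to millimetres (mm = px · 25.4 / dpi),
   and resampled to 360 equidistant points along the curvilinear abscissa.
   Outlines are stored counter-clockwise: elliptic Fourier coefficient signs
   depend on traversal direction, so one convention keeps all specimens
   comparable.

2. **Elliptic Fourier descriptors.** The closed outline's coordinate
   functions are expanded as truncated Fourier series; coefficients come
   from the classical closed-form per-segment accumulation for a
   chord-length-parameterized polygon (exact for polygons, no equal-spacing
   assumption; not an FFT). Descriptors are normalized by the
   first-harmonic ellipse — position dropped, starting point moved to the
   semi-major axis, plane rotation aligned to it, scale divided by its
   magnitude — making coefficients invariant to pose, size and start point.
   The first six harmonics give the 24-coefficient feature vector per
   specimen. Six harmonics capture essentially all harmonic power of
   seed-like outlines (≥ 95% is the admission criterion; the synthetic
   templates sit near 99.9%) while discarding the high-rank harmonics where
   digitization noise concentrates.

3. **Statistics.** PCA (covariance eigendecomposition; deterministic sign
   convention) reduces the 24 coefficients to uncorrelated scores; by
   default the components explaining 99% of cumulative variance feed the
   classifier, with a switch for raw coefficients. Variable selection is
   greedy stepwise minimization of Wilks' lambda with partial-F thresholds
   (enter 3.84, remove 2.71 — the long-standing defaults of mainstream
   stepwise discriminant analysis), with a collinearity tolerance guard and
   lowest-index tie-breaks. The classifier is multi-group linear
   discriminant analysis with pooled within-group covariance; posteriors
   are softmax of log prior − ½·Mahalanobis². Performance is reported by
   leave-one-out cross-validation with the variable set held fixed across
   folds (the model reported is the one selected on the full reference set;
   per-fold reselection is available as a sensitivity switch). Unknown
   specimens are projected through the same PCA and variables and assigned
   by maximum posterior; thresholded allocation additionally requires the
   maximum posterior to reach p ≥ 0.90 (inclusive), else the specimen is
   counted "unassigned".

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_points` | 360 | equidistant outline samples (arc length) |
| `k_harmonics` | 6 | harmonics kept → 4·6 = 24 coefficients |
| `n_harmonics_computed` | 20 | reference total for power fractions |
| `f_enter` / `f_remove` | 3.84 / 2.71 | stepwise partial-F thresholds |
| `priors` | equal | group sizes are sampling artifacts, not prevalences |
| `pca_variance` | 0.99 | cumulative variance kept before the classifier |
| `p_min` | 0.90 | posterior threshold for confident allocation |
| `ridge` | 1e-8·trace/dim | fallback for a singular pooled covariance |

## Normalization details

The first-harmonic phase formula fixes the starting point only up to a
half-turn, so both representatives are standardized and a deterministic
lexicographic rule (on coefficients rounded to 1e-9) picks the canonical
one. When the first-harmonic ellipse is nearly circular (axis ratio > 0.99)
its phase confounds plane rotation with start shift; the phase is then taken
from the strongest higher harmonic m, decomposed into circular and
anti-circular components whose standardized phases advance at (m−1) and
(m+1) times the shift. Both finite candidate families are exactly
pose-covariant, so the lexicographic pick keeps normalized coefficients
invariant to machine precision even for near-circular outlines. Traversal
direction is canonicalized so the normalized d₁ is positive. Degenerate
first harmonics (zero magnitude) are an error; near-degenerate ones are
handled by the covariant fallback, never by failure.

Two numerical facts worth knowing: (i) under chord-length parameterization a
2:1 ellipse is *not* exactly one harmonic (99.4% of its power is in
harmonic 1; the "one-harmonic ellipse" statement is exact only for the
elliptic parameterization), and (ii) compute → reconstruct → compute is a
genuine fixed point only for uniform-speed curves such as circles; for
general outlines each trip re-parameterizes the curve and perturbs
coefficients at the 1e-3–1e-4 level while leaving the represented shape
geometrically stable. The tests assert exactly these properties.

## Synthetic generator

The study's raw images are not redistributable, so validation uses synthetic
cohorts. Each class is a template: the normalized 20-harmonic descriptor of
a parametric seed silhouette (tapered ellipse with a Gaussian apical beak
and slight dorsoventral asymmetry), with per-coefficient standard deviations
that decay with harmonic rank. Specimens are drawn by Gaussian perturbation
*in normalized-EFD space*, so ground truth (class means, dispersions,
pairwise Mahalanobis separations) lives in the same coordinates the analysis
measures; outlines are reconstructed, scaled to a 6 mm seed length (typical
of wild grape pips), rasterized at 600 dpi as black-on-white PNGs, and
re-ingested through the full imaging chain, so tests exercise the pipeline
end to end rather than only the mathematics.

There are 17 default templates (11 elongate, tapered, strong-beak
"eurasian"-style classes including the flagged `sylvestris_like` reference,
and 6 rounder, weak-beak "north-american"-style classes), plus two ecotype
classes derived from the sylvestris template by a small symmetric parameter
shift. The shape-parameter grid and dispersion scale (0.010 at harmonic 1,
e-folding every 4 harmonics) were fixed at design time so that the
`sylvestris_like` class sits at Mahalanobis separation ≥ 5 from its
neighbours in the five-class subset while some other class pairs overlap
(separations down to ≈1.4), yielding realistic, imperfect cross-validated
accuracies rather than a trivially separable toy.

"Fossil distortion" emulates the deformation of compressed or mummified
seeds with two components per unit of the distortion parameter: amplitude
jitter on harmonics 2–3 (SD 0.010 per coefficient) and smoothed Gaussian
roughening along the outline normal (SD 0.030 mm, correlation length ≈ 6 of
360 points). It inflates within-class variance monotonically and flattens
posteriors, which is what drives specimens under the p ≥ 0.90 threshold into
the unassigned category.

What the generator does *not* emulate: ventral-view infolds and chalaza
detail, illumination/segmentation artifacts of real scans, taphonomic bias
in which seeds survive intact, and between-accession structure within a
species. Passing tests therefore demonstrate that the pipeline recovers
known class structure from silhouettes with realistic noise — not that any
particular fossil assemblage is correctly identified.

## Study-shaped fixture and problem sizes

`end_to_end_fixture` mirrors the study design: 30 specimens per reference
class (510 modern seeds), 70 unknowns drawn from `sylvestris_like` with
distortion 1.0, split 60/10 into two assemblages, then the six-analysis
cascade (assemblage PCA; Eurasian vs North American; 11 Eurasian classes;
the five-class subset; thresholded allocation; western vs eastern ecotypes).
The test suite runs the cascade at 12 specimens per class and 28 unknowns
across three distortion levels; the package's own demo uses the full sizes.

## Design choices on genuinely open points

* The 24-coefficient feature vector retains the near-constant normalized
  a₁ (=1) and near-zero b₁, c₁; stepwise selection ignores constant columns,
  so keeping the conventional dimension costs nothing.
* Harmonic-power totals use 20 harmonics as the reference ceiling
  (configurable); power fractions are computed on unnormalized descriptors.
* Size (the first-ellipse magnitude in mm) is recoverable from the outline
  but excluded from classification; shape alone drives identification.
* Equal priors by default, proportional available; posterior ties break to
  the lowest group index; report tables round one decimal, half away from
  zero.
* PCA for classification is fitted on the reference specimens only and held
  fixed for unknown projection and across LOOCV folds, exactly like the
  stepwise variable set.

## Limitations

* Stepwise Wilks selection inherits the known optimism of selection-then-
  validation when selection is not repeated per fold; the per-fold switch
  exists precisely to quantify that on a given dataset.
* LDA assumes a shared within-group covariance; strong distortion violates
  it for the unknown set, which the threshold mechanism absorbs but does
  not model.
* The ridge fallback handles numerical rank deficiency, not genuinely
  informative sub-rank structure.
* Physical units matter only for diagnostics; normalization removes size
  before classification, so dpi errors do not bias assignment.
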