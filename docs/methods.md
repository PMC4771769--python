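# Methods

## Measurement model

The pipeline treats a multi-channel confocal section as a set of calibrated
2D intensity rasters (nm-scale pixel size attached; the native convention is
~64 nm/px, 2000×2000 px single optical sections). Regions of interest arrive
as integer label masks plus a CSV sidecar (`label, location_class,
brain_area, pair_id`); each AIS ROI is paired with a congruent non-AIS ROI —
identical pixel count, disjoint support. Congruence is checked exactly by
default, with an optional pixel tolerance because rasterising a translated
contour can alias.

### Background subtraction

`rolling_ball_subtract` estimates background as the grayscale **opening** of
the image by a spherical-cap structuring element of the configured radius
(default 50 px): an erosion (the ball rolled under the intensity surface)
followed by a dilation (the surface traced by the ball's top). The output is
`max(image − background, 0)` and never exceeds the input pointwise. No
down-scaling shortcut is used; the implementation delegates the two
morphological passes to `scipy.ndimage` with an explicit cap-height
structure, and is tested for exact equality against a brute-force
shift-stack erosion/dilation oracle. Opening is not idempotent on the
residual, and the tests deliberately do not assert that.

### Triangle threshold

The histogram uses 256 equal bins spanning `[min, max]` of the scoped pixels
(the 8-bit-like convention; the source imagery peaks below gray level 50). A
chord is drawn from the peak bin to the farthest non-empty bin on the longer
tail (tie → higher-intensity tail), and the threshold bin maximises the
perpendicular distance to that chord, ties broken toward the peak. The
threshold value is the selected bin's centre and masks are **strict**
(`intensity > threshold`). A constant image is degenerate: the single
occupied value becomes the threshold and the mask is empty. The selected bin
is property-tested against an independent brute-force distance maximiser.

### Costes auto-threshold

The unnamed auto-threshold applied before intensity correlation is
implemented as the Costes procedure: a major-axis (orthogonal) regression of
channel B on channel A over the ROI, then a candidate threshold walked down
channel A (with the B threshold taken from the regression line) until the
Pearson correlation of the pixels at or below both thresholds first reaches
≤ 0. Constant below-threshold sets carry no anticorrelation evidence and are
skipped; if the correlation never vanishes (e.g. B ≡ A) the thresholds fall
below the minimum so every pixel is retained. A fixed-threshold fallback
exists. This choice of algorithm is a documented interpretation, not a
stated fact of the source workflow.

### Particle analysis

Clusters are connected components of `mask ∧ roi` (default 8-connectivity,
configurable to 4), **clipped to the ROI before measurement** — quantification
is ROI-restricted, at the cost of biasing the circularity of border-clipped
clusters. Area is pixel count × pixel area. Perimeter uses Moore boundary
tracing through pixel centres with the Vossepoel–Smeulders corrected
weights (orthogonal steps 0.980, diagonal steps 1.406, corner penalty
0.091); circularity = 4πA/P², capped at 1.0 so rasterised discs pass the
closed upper gate. The default gates are areas 0.05–10.00 µm² and
circularities 0.10–1.00, both closed intervals. Note that moderately
elongated shapes still pass the circularity gate under any standard
perimeter estimator — a 1×20 px line sits near 0.18, and only around 40 px
of length does a 1-px-wide line fall below 0.10.

Per-ROI statistics: density is clusters per 100 µm² of ROI area (the density
denominator is not fixed by convention in the field; per-100-µm² is this
package's explicit, configurable choice), percent area is
100 × covered ROI pixels / ROI pixels, and a zero-puncta ROI has density 0
with a **missing** mean size (NaN), which downstream analyses drop listwise.

### Enrichment ratio

The reported statistic is the ratio of arithmetic means of percent area,
AIS over non-AIS, pooling ROIs across images (per-image averaging is
available but off by default). Per-pair ratios are auxiliary: they feed the
across-area one-way ANOVA and differ from the ratio of means on skewed data
(Jensen gap), which the tests demonstrate. A zero non-AIS mean percent area
yields a missing ratio with a warning. Percent area contributes 0 (not
missing) for empty ROIs, because coverage is well-defined there.

### Colocalization

Manders coefficients are computed on binarised channels, where they reduce
to overlap-area fractions: M1 = |A∩B∩roi|/|A∩roi|, M2 with the roles
swapped; an intensity-weighted variant exists but is not the default.
Pearson correlation is evaluated over ROI pixels, by default restricted to
pixels above the Costes threshold pair, falling back to the whole ROI when
the procedure degenerates. AIS-ROI validation accepts a candidate when ≥ 50 %
(configurable) of its subunit-positive pixels fall on ankyrin-G-positive
pixels.

### Statistics

Two-way ANOVA (location × brain area, with interaction) uses Type III sums
of squares with sum-to-zero contrasts via statsmodels OLS — the factorial
default of the commercial packages this replicates, appropriate for the
unequal ROI counts per cell. Balanced designs are verified against
closed-form sums of squares. Tukey–Kramer uses
q = |Δmean| / √(MSE/2 · (1/nᵢ + 1/nⱼ)) with p-values from
`scipy.stats.studentized_range`, verified against direct numerical
quadrature of the studentized-range CDF to 1e-4. Bonferroni adjustment is
`min(1, p·n)` over the declared family. Degenerate inputs (zero residual
variance) produce missing statistics with warnings rather than exceptions.
ROIs are treated as independent observations, replicating the source
convention; the nesting of ROIs within images/animals is documented here as
a limitation, not modelled.

## Synthetic scenes

`SceneConfig` defaults describe the study conditions at native scale
(64 nm/px, 1024×1024 ≈ 65×65 µm, 2D only — the quantification targets single
optical sections). Each scene is a pure function of its seed; every random
choice draws from a named, platform-stable substream.

- **Geometry.** AIS trajectories are cubic splines through jittered
  waypoints, laid out on a deterministic tile grid: the trajectory occupies
  the upper band of its tile and the non-AIS ROI is the *same pixel set*
  translated into the lower band — congruence and disjointness hold by
  construction, and infeasible layouts raise immediately. The AnkG channel
  renders the ribbon (trajectory dilated to the configured width).
- **Puncta.** Subunit puncta are uniform discs (radius ~N(0.25, 0.04) µm,
  clipped) placed (a) along trajectories as beads with jittered spacing at
  the configured AIS density and (b) as a field at the non-AIS density
  everywhere at least 0.5 µm away from ribbons. Placement uses **sequential
  spatial inhibition** with a minimum separation of about one punctum
  diameter: receptor clusters are discrete, non-interpenetrating objects,
  and a pure Poisson process would merge enough neighbours at 40 per 100 µm²
  to corrupt density recovery. Partner puncta (gephyrin/vGAT, 0.8× radius)
  appose a Bernoulli subset of subunit puncta at a 0.12 µm offset,
  alternating sides along the trajectory — the 2D rendering of the spiral
  apposition — plus an independent field of their own; the apposition
  probability can differ between AIS and non-AIS puncta.
- **Rendering.** Discs are stamped at their amplitude over a planar
  background gradient, blurred by a small Gaussian (default σ = 0.02 µm:
  the discs model already-resolved, post-optics punctum footprints, and the
  blur only softens edges — a physically sharper PSF would make planted
  sizes unrecoverable from thresholded footprints), then Poisson shot noise
  on signal + background and additive Gaussian read noise (sd 2), quantised
  to uint16.
- **Ground truth** is recorded before noise: the full punctum table, per-ROI
  densities, mean planted sizes (πr² of centred puncta) and percent areas
  (rasterised coverage), plus the config-level enrichment ratio (the planted
  density ratio, exact when size distributions match). Per-ROI true counts
  use a minimum-footprint rule: a punctum counts toward an ROI when ≥
  0.05 µm² of it lies inside — the same minimum quantifiable area as the
  particle filter's lower gate — because a punctum contributing two or three
  border pixels is not an observable of that ROI. Centre-based counts are
  recorded alongside.
- **Knockout scenes** re-render after thinning one channel's puncta with an
  independent Bernoulli substream, leaving every other channel bit-identical
  at the same seed.

### What the generator does not emulate

Realistic optics (vectorial PSF, depth aberration), autofluorescence
texture, somata and dendritic shafts, intensity heterogeneity along a single
AIS, and the hand-drawn character of real ROIs. Passing recovery tests shows
the measurement chain is faithful to its own model of punctate signal; it
does not certify performance on tissue with out-of-focus haze or touching
clusters beyond the planted separation.

## Problem sizes used in validation

Simulation-based tests and `scripts/acceptance.py` run at a desk scale
chosen by this package: scenes rasterised at 128 nm/px with the rolling-ball
radius at 25 px (preserving the 3.2 µm physical ball), fields of
102 × 82 µm holding 50 congruent ROI pairs (16 µm × 1.6 µm ribbons),
non-AIS density 10 per 100 µm². Enrichment recovery uses 20 seeded
replicates per planted ratio in the test suite (8 in the acceptance script);
ANOVA/Tukey calibration uses 2000/4000 null replicates in the suite and
1000/4000 in the script — enough that the Monte-Carlo standard error of a
0.05 rejection rate is well inside the [0.035, 0.065] acceptance band.

## Known limitations

- Merged puncta are not watershed-split; at planted separations below the
  inhibition distance, counts would drop.
- Border-clipped clusters bias circularity and, through the area gate,
  slightly inflate counts in field ROIs relative to centre-based bookkeeping
  (hence the footprint-based truth convention above).
- The Costes identification of the pre-correlation auto-threshold is an
  interpretation; a fixed-threshold mode is provided for sensitivity checks.
- Pseudo-replication (ROIs pooled across images) is reproduced by design and
  not corrected with mixed models.
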