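# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `puncta` package.

## Coordinate and unit conventions

Physical coordinates are continuous micrometres, origin at the ROI top-left,
x rightward, y downward. Pixel `(row, col)` indices are 0-based; pixel
`(row, col)` covers the half-open square
`[col/s, (col+1)/s) × [row/s, (row+1)/s)` with `s` the pixel scale
(default 9.6679 px/µm, the scale of 63× wide-field acquisition). This makes
µm↔pixel conversions invert to within half a pixel pitch, which the tests
enforce. Supported field sizes in the drivers are 52 × 52, 180 × 180 and
211 × 211 µm, the three ROI sizes of the source datasets.

Feret's diameter is the maximum caliper over the *corner points* of a
punctum's member pixels (standard particle-analysis convention), so a
single pixel has Feret equal to its diagonal. Puncta loaded from coordinate
tables carry no pixel sets; when a pixel-overlap operation needs a
footprint they are materialized as discs of their recorded Feret diameter —
the minimal shape consistent with the recorded caliper. Centroid-distance
operations use table values directly. Table readers sniff whether
coordinates are in µm or pixels (by comparing their range to the ROI extent
in each unit) and record the decision in provenance.

## Segmentation

Suprathreshold pixels (strict `>`) are grouped with 8-connectivity; every
component, including single pixels, becomes a punctum with area =
pixel count / s², an intensity-unweighted centroid, corner-point Feret, and
total/mean intensity from the raw pixel values. The threshold is the lowest
value at which the object count on the matched negative-control image is at
most `max_allowed` (default 3 %, the looser of the reported 1–3 % bounds;
both exposed) of the experimental object count, searched over a 256-level
grid spanning the experimental intensity range. Otsu's threshold is offered
as an alternative initializer only. There is no manual-curation step; the
nearest automatable proxy is an optional minimum-area filter (default
1 px), recorded in provenance.

Nuclear exclusion interprets "DAPI + 10 % surrounding area" as isotropic
dilation growing each nucleus component's area by 10 %: a component of
equivalent-circle radius R is dilated by `r = R(√1.1 − 1)` (implemented via
a Euclidean distance transform with per-component radii). Whether the
growth should instead be 10 % of radius or a fixed ring is not decidable
from the description; the fraction is config-exposed.

## Colocalization

Two criteria:

- **pixel mode** — reference punctum shares ≥ `min_pixels` (default 1)
  pixels with the union mask of the target channel;
- **centroid mode** — some target punctum satisfies
  `d < f·(Feret_A + Feret_B)/2`. The inequality is strict, matching the
  "less than" wording of the source definition; `f = 0.99` and `f = 0.50`
  are the lenient and stringent presets.

Counting is per reference punctum (≥ 1 partner counts once), never per
pair: a hub overlapping three partners contributes 1 to its own channel's
count and 1 to each partner's count in the reverse direction. The pair
normalization `100·(|coloc A| + |coloc B|)/(|A| + |B|)` counts colocalized
ids on both sides rather than 2× a pair matching, so hubs are not
double-counted and the quantity is symmetric. Centroid queries use a k-d
tree with per-reference query radius `f·(r_A + max r_B)` followed by an
exact per-pair check. Puncta straddling the ROI edge are kept (no edge
correction is applied); edge effects on the CSR closed form are
sub-percent at the radii and field sizes used and are absorbed by the
3-SE test bands.

## Rotation nulls

Rotation acts on coordinates and pixel footprints, not on rendered images,
so the null is available for coordinate-table inputs and is exact for
binary data. 180°: `(x, y) → (W − x, H − y)`; 90° is clockwise in image
coordinates, `(x, y) → (W − y, x)`, and requires a square ROI. Every
per-punctum attribute is preserved, so rotation preserves per-channel
abundance and all marginal distributions exactly. In the random-subtracted
matrix the *reference* channel of each cell is rotated. Negative subtracted
cells are reported as-is (with a warning), never clipped — clipping would
bias averages across replicates.

The rotation null assumes the field is statistically homogeneous; it does
not model cytoarchitecture (holes, laminae) that rotation fails to map onto
itself. The analysis drivers show this concretely: with asymmetric nuclear
exclusion holes the subtracted matrix acquires small positive residuals.
No correction is applied beyond this documentation.

## Composition

A focal punctum's category is determined by the set of *distinct partner
channels* it colocalizes with: singleton (none), dimer (one, recorded per
partner), multimer with / without the designated special partner (≥ 2).
Partner multiplicity within a channel is deliberately invisible — the
union-of-intersection-layers construction this reproduces cannot
distinguish it — so a focal punctum overlapping two puncta of one channel
is a dimer. Marker gating (e.g. an FMRP immunostain mask) reduces every
channel to marker-colocalized puncta before analysis; the gate defaults to
pixel overlap because protein markers arrive as masks.

## Distributions and clustering

Relative-% histograms use half-open bins `[k·w, (k+1)·w)` with an open tail
bin; area histograms default to `w = 0.1 µm²` with the tail from 1.0 µm²
(the reporting convention of the empirical tables), intensity histograms to
`w = 10 a.u.`. Replicates are averaged on the percentage scale — each
replicate contributes equally regardless of its puncta count — with SEM
attached.

Normalized total intensity is `total / mean` *per punctum*, which equals
the pixel count exactly on pixel-backed puncta and hence is an
acquisition-free proxy for area; this per-punctum reading (rather than
dividing by a per-channel mean) is forced by the requirement that the
quantity correlate with area. A per-channel variant is available behind a
flag.

Hierarchical clustering uses a precomputed distance matrix (manhattan for
size/intensity profiles, euclidean for colocalization profiles) under
Ward-D2 linkage — the Lance–Williams recurrence on squared distances.
`scipy.cluster.hierarchy.linkage(..., method="ward")` on a condensed
distance matrix implements exactly this update; the tests pin its merge
heights against values computed independently with R's
`hclust(..., "ward.D2")`. Pairing Ward with manhattan distances is
geometrically unorthodox (Ward's variance interpretation assumes squared
Euclidean); it is retained deliberately for fidelity to the established
analysis. Clustering is deterministic given input order, and the flat-cut
partition is order-invariant.

The abundance regression is an ordinary least squares fit of a reference
channel's colocalization percentages (raw or random-subtracted) against
partner abundances, reporting slope and R².

## Synthetic scenes

The generator emulates the statistical structure of the imaged fields, not
their optics or biology:

- **Counts** are Poisson around per-channel means (a fixed-count mode
  exists for closed-form comparisons). The bundled 12-channel panel uses
  the observed per-image means (≈ 1,160 – 12,800 per 211 µm field, an ~11×
  spread).
- **Areas** are log-normal per size class. Each of the four empirical size
  clusters is summarized by its median area m (small 0.23, small-broad
  0.27, large-broad 0.285, large 0.347 µm², cluster averages of the
  observed per-RNA medians) and its observed mass above 1 µm² (2.5 %,
  9.4 %, 2.7 %, 3.1 %); `µ = ln m` and `σ = ln(1/m)/Φ⁻¹(1 − p_tail)` pin
  both. The log-normal is the minimal positive-support family fitting a
  median plus a tail mass; the implied 0.6–1.0 µm² band masses land close
  to (though are not fitted to) the observed cluster summaries.
- **Feret** = `2√(area/π)` × a shape factor uniform in [1, 1.3].
- **Placement** is uniform outside nuclei (discs of ~8 µm diameter placed
  uniformly, a stand-in for DAPI exclusion). Planted heterotypic granules
  re-place a chosen fraction of channel-A puncta within a jitter radius
  (default 0.1 µm) of distinct channel-B partners, which keeps planted
  pairs colocalized under both the lenient and the stringent criterion.
- **Rendering** paints each punctum as a disc of its area carrying its
  total intensity, applies a Gaussian PSF (default σ = 0.1 µm), and adds
  background and Gaussian noise; the negative control has identical
  background and noise with no signal. The source images' SNR is not
  reported anywhere, so the default render intensities (per-pixel SNR 5–15,
  with an SNR-10 setting used for validation) are calibration choices, not
  reproductions.

What passing tests on these scenes demonstrate: the estimators are
unbiased and consistent under the stated models (CSR, planted mixtures),
the closed forms hold, and the pipeline recovers known ground truth. What
they do not demonstrate: performance on real microscope images with
spatially varying background, clustered (non-Poisson) spatial structure,
dendrite morphology, or 3-D effects — the package analyzes 2-D maximum
projections only.

## Dilution model

Labeled copies per punctum are `Binomial(K, q)`; detection requires
labeled intensity ≥ threshold (default: one transcript equivalent).
Apparent diameter uses the fixed monotone map
`d = d₀·√(I_detected/I_full)` (apparent spot area proportional to detected
intensity); only monotonicity, not the functional form, is scientifically
constrained. "Bootstrap-sampled values from the minimum-to-maximum range"
in the abundance simulation is read as resampling observed attribute
vectors with replacement (jointly, preserving per-punctum covariance and
bounded by the observed min–max by construction); a uniform-over-range
alternative is behind a flag since the phrase admits both readings.
Duplicate-centroid checks use exact float equality, as specified for the
original analysis. Augmentation samples the full ROI and ignores nuclear
masks, matching the source analysis, which deliberately segmented these
images without DAPI removal to avoid biasing the simulated coordinates.

## Problem sizes

Validation runs use fields and counts chosen to keep every check
statistically decisive at modest cost: CSR ladders at 180 µm with 300
reference puncta over 30–50 seeds (3-SE bands), planted-recovery scenes at
200/300 puncta over 15–20 seeds, segmentation at 150 puncta per 52 µm
render, clustering at 3 replicates × 2,000 draws per family over 50 seeds,
and the cell-type simulation at the observed per-image counts
(1,248/2,973/8,840 per 180 µm field) with 10 bootstrap iterations.

## Known limitations

- The rotation null underestimates chance colocalization in structured
  tissue (see above); no correction is implemented.
- Touching spots are not split (no watershed); merged detections are the
  main F1 cost at high density.
- 3-D objects, sub-pixel spot fitting, denoising/deconvolution and
  multi-round registration are out of scope; inputs are assumed
  preprocessed, registered, maximum-projected 2-D images or tables.
- Pixel-intensity correlation metrics (Pearson/Manders) are deliberately
  absent; the analysis is object-based throughout.
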