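# Methods

This note records the models, defaults, and design choices behind
histoquant, and what the synthetic-phantom tests do and do not establish
about real histology.

## Image normalization

Acquisition is assumed 12-bit grayscale per channel (8- and 16-bit are also
accepted). Conversion to 8-bit is the fixed linear map
`v ↦ floor(v·255/(2^b−1))`: full-range and image-independent, so identical
grey values always convert identically. A per-image min–max stretch was
deliberately rejected — it would make downstream thresholds, and therefore
counts, depend on a section's brightest outlier pixel. Gamma correction is
`v ↦ round((v/vmax)^γ · vmax)` with γ = 1 by default: correction is applied
only when explicitly requested, never silently. Note that for integer
rasters a compressive gamma (γ > 1) collapses low grey levels to 0
irrecoverably; the γ ↔ 1/γ round-trip is lossless (±1 grey level) only when
the expanding direction is applied first.

Mosaics are assembled by plain pasting at the grid offsets, the later tile
overwriting the overlap band. No blending or registration is attempted:
counting operates on segmented objects, and a seam that shifts a boundary
pixel does not change an object count, whereas blending would alter grey
values inside objects. Default overlap is 0 px.

## Cell segmentation

The counting pipeline is blur → binarize → markers → watershed → size
filter.

- **Blur**: Gaussian, σ = 2 px default — enough to suppress single-pixel
  noise without merging nuclei a few radii apart.
- **Binarize**: Otsu on the blurred histogram by default, with a fixed-grey
  alternative. Foreground is *strictly above* the threshold. A constant
  image yields an empty mask with a warning rather than an error.
- **Markers**: within each 8-connected foreground component, marker pixels
  are those with EDT ≥ f · (component EDT maximum); their 8-connected
  components seed the watershed, and the object count equals the marker
  count by construction. The fraction f is the one genuinely free knob in
  the whole pipeline. Its default is 0.8: for two equal touching disks the
  discrete EDT saddle between the centers sits at ≈ 0.74 of the maximum
  (e.g. 6.0 vs 8.06 for radius-8 disks 12 px apart), so any f below that
  merges the pair into one marker. f = 0.8 splits every two-maximum pair in
  the touching-disk suite while keeping exactly one marker per isolated
  round object; raising f further shrinks markers and eventually fragments
  noisy objects.
- **Watershed**: floods the inverted EDT from the markers, restricted to
  the foreground mask (scikit-image implementation).
- **Size filter**: "based on the image data" is made operational as
  dropping objects below `fraction × median(object area)`, default fraction
  0.25 — scale-free across magnifications because the median tracks the
  typical nucleus area. A fixed minimum-area mode is available when a
  physical cutoff is known. Filtering is monotone: raising either knob can
  only reduce the count.

Conventions: rasters are row-major `(row, col)`, origin top-left;
connectivity is 8-connected throughout; areas are counted in pixels and
converted by `area_mm² = n·(pixel_size_µm/1000)²`.

## Volumetry

Tissue/background classification is done in HSV space: background is the
near-white slide, `S < 0.08 ∧ V > 0.85`; everything else is stained tissue,
after removal of stained specks below 64 px. The two thresholds are
interpretable (how colorless and how bright the slide is) and are the only
color parameters.

The lesion cavity is defined as background 8-connected regions with no path
to the raster border — i.e. holes fully enclosed by tissue, found by
flood-filling the tissue silhouette. Lesions that breach the cortical
surface are not enclosed and would score zero; an optional morphological
closing of the silhouette (radius configurable, **off by default**) bridges
a narrow breach first. This is an explicit modelling decision: whether a
surface-open defect counts as "cavity" is ambiguous, so the package makes
the closed-cavity reading the default and the breach-tolerant reading an
opt-in.

Volumes use the plain Cavalieri sum `V = d·ΣA` over the sectioning scheme
(default six levels, bregma +1 … −4 mm, d = 1 mm, ten sections per level),
with technical replicates at a level averaged first. No end-correction or
shrinkage correction is applied, and no coefficient-of-error estimate is
produced. On analytic phantoms the estimator recovers the discrete sum to
rasterization error (< 0.1% for a 5 mm-radius cylinder at 50 µm/px); for a
convex solid, refining the spacing converges monotonically toward the true
volume, which the cone test exercises.

## Counts, ratios, validation

Technical replicates are averaged (arithmetic mean, unrounded) to one value
per animal and channel before any statistics; a channel with no data for an
animal is flagged missing, never imputed as zero. Marker ratios
(Iba1/DAPI, ED1/DAPI, Iba1/ED1) are computed per animal after aggregation;
a zero denominator flags the ratio undefined rather than dropping the row.
Counts are per-channel independent object counts — no nuclear
co-localization gating.

Validation against blinded manual counts uses the manual count as the
denominator (ground-truth convention): per image
`|auto − manual|/manual × 100`, summarized per stain as mean ± sample SD
(n−1). Pairs with manual count 0 are excluded with a warning; unmatched
images are an error, not a silent drop.

## Group statistics

Routing: every group's Shapiro-Wilk p > α **and** median-centered Levene
p > α → one-way ANOVA with Tukey HSD; otherwise tie-corrected
Kruskal-Wallis with Dunn's post hoc. α = 0.05 throughout, two-sided;
normality is assessed per group, not on pooled residuals — both readings
are defensible, this one is fixed and stated. Dunn's z statistics use the
standard tie-corrected variance
`(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)` with Holm adjustment by
default (Bonferroni and unadjusted available). Post hoc tables are
produced only when the omnibus test is significant. Degenerate all-equal
data short-circuits to statistic 0, p = 1.

The router is a two-stage procedure, so its realized type-I error is not
automatically the nominal α. The Monte-Carlo harness measures it: under a
Normal null at n = 8 × 3 groups it stays within [0.02, 0.08] (2000
replicates), and power for a 5-SD shifted group is ≈ 1. A side effect worth
knowing: with truly normal data, per-group Shapiro testing at α = 0.05
diverts roughly 15% of datasets to the rank route — harmless for validity,
and visible in the routing-frequency tests.

## Synthetic phantoms: what they emulate and what they don't

Fluorescence phantoms are isotropic Gaussian intensity blobs (σ = radius/2,
default radius 6 px) on a constant background with additive Gaussian noise
(clipped to the bit range; optional Poisson shot noise), amplitude
defaulting to max(10 × noise SD, 40% of range). Placement is rejection
sampling with a minimum separation; an `overlap_fraction` instead drops
that share of cells within ~1–1.6 radii of an existing cell to create
touching clumps. Requests exceeding raster capacity raise an explicit
placement error. HES phantoms are rasterized disks/annuli in eosin-pink on
near-white, with truth areas recorded as the *rasterized* pixel tallies —
exactly what pixel counting should return. The cohort generator reproduces
the study design: 25 operated − 1 death = 24 animals randomly split 8/8/8.

Defaults the data do not dictate, chosen once: raster 1024 × 1024 px,
pixel size 0.65 µm/px (plausible for a 10× objective with a standard
camera), blob radius 6 px, background 5% of range, noise SD 20 (12-bit).

These phantoms establish algorithmic correctness — exact recovery when
objects are separable, correct splitting of two-maximum clumps, exact area
accounting — not biological performance. Real sections add texture,
uneven illumination, staining variability, out-of-focus light, and
irregular nucleus shapes, none of which the phantoms model; published
manual-validation error rates on real stains are therefore not reproducible
from synthetic data, and passing tests here should be read as "the
algorithm does what it claims on images satisfying its assumptions".

## Demo problem sizes

The end-to-end demo uses 192² px fluorescence phantoms (mean true counts
50/20/12 for DAPI/Iba1/ED1, one or two replicates per animal) and 256² px
HES phantoms at 50 µm/px with per-level area profiles peaking at 90 mm²
(tissue) and 9 mm² (cavity), giving per-animal Cavalieri volumes of a few
hundred mm³ (tissue) and tens of mm³ (cavity) — the scale of a rat-brain
lesion study — while a full 24-animal run completes in seconds. Animal-level
variability is log-free multiplicative (CV 8% tissue, 15% cavity), and
optional group-effect multipliers on counts or cavity areas exist to
exercise the statistics under a true effect.

## Known limitations

- The watershed marker rule assumes roughly convex, similar-sized nuclei;
  long overlapping chains with shallow saddles under-split.
- The HSV tissue rule assumes a bright, low-saturation slide; dust or
  mounting artifacts darker than the V threshold would count as tissue
  beyond the speck clean-up size.
- Stitching assumes a perfectly regular grid; no correction for stage
  drift or illumination falloff.
- The Cavalieri estimator reports no coefficient of error.
- Morphological phenotyping of microglia and co-localization analysis are
  out of scope.
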