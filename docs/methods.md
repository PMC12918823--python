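# Methods

This note documents the models and procedures `tglow` implements, the
defaults and why they were chosen, what the synthetic fixtures do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Image model and conventions

Stacks are 4-D arrays indexed `(channel, z, y, x)`, 0-based, floating point
in memory and 16-bit unsigned on disk (clip to [0, 65535], round). Physical
pixel sizes are carried in μm as `(z, y, x)`. Translations are expressed as
the integer voxel offset `(dz, dy, dx)` applied to the cycle-2 stack to land
it on cycle 1; `estimate_translation(a, b)` therefore returns the negative
of the shift that produced `b` from `a`. Fields live in a
`plate/row/col/field.ome.tiff` layout; per-cell crops go to HDF5 with one
group per cell and the binary cell and nucleus masks appended as the last
two channels.

## Flatfield

The illumination surface is the full bivariate quartic (15 monomials
`x^i y^j`, `i + j ≤ 4`). Pixel coordinates are rescaled to [−1, 1] per axis
before fitting; the raw monomial basis on pixel indices is catastrophically
ill-conditioned at degree 4, and the rescaling changes nothing else because
the model is refit per image shape. Foreground selection is deliberately
lenient: a two-class Otsu threshold (256-bin histogram) divided by four.
Because sparse fields give unstable Otsu values, thresholds are computed on
*compound* images — pixelwise maxima of `n_per_compound` (default 20)
randomly sampled fields — and `n_compound` (default 200) such compounds are
pooled into one regression. The fitted surface is normalized to mean 1 over
the image domain so that division preserves average intensity; the
normalization constant is a free choice and mean-1 makes the identity model
literally all-ones. Fitting is ordinary least squares on raw intensities
(not log), which treats the additive noise floor evenly at the cost of
weighting bright pixels more.

The fit assessment divides held-out images by the surface, bins foreground
into a 20×20 grid and regresses bin mean intensity on bin mean surface
value; the reported slope is standardized (a correlation), so a
well-corrected field sits near 0. Assessment uses the *full* Otsu threshold
rather than the lenient /4 one: the lenient rule exists to feed the fit
generously, while the assessment wants clean foreground averages — with /4,
background admixture varies bin-to-bin and swamps the signal being tested.

A fitted surface that is not strictly positive over the domain is refused
rather than clamped; in practice this only happens when the training images
leave whole regions (e.g. corners) without foreground, and the right fix is
more coverage, not a patched surface.

## PSF and resolution

Bead spots are found with a multiscale Laplacian-of-Gaussian detector; any
spot with a neighbour within 20 voxels is dropped (both members of a close
pair go). The first retained spot serves as reference; the rest are aligned
to it by integer phase-correlation translation, and beads whose
post-alignment RMSE exceeds mean + 1.645 sd of the others are rejected. The
averaged bead is background-subtracted (background = mean of the 1-voxel
border shell of the stack), clipped at zero, centred on its centre of mass
by sub-voxel linear interpolation, and normalized to maximum 1. Resampling
a finely stepped PSF to a coarser acquisition spacing takes every n-th
plane symmetrically outward from the central plane and refuses non-integer
plane ratios — no z-interpolation is ever performed on a kernel.

FWHM is measured per axis by fitting a four-parameter Gaussian (amplitude,
mean, sigma, offset; initial sigma from the second moment) to the
centre-line profile of each bead crop and reporting `2.35482 σ`. Two
numerical choices matter here. First, beads are centred on their centre of
mass *to the nearest voxel only* (an integer roll); the fit's free mean
absorbs the residual sub-voxel offset exactly, whereas interpolated
sub-voxel resampling measurably broadens a σ ≈ 1 profile. Second, the fit
includes a constant offset term so a uniform background does not inflate
sigma; the flag is recorded in the report. Intensity outliers (peak
deviating > 3 MADs from the median) are removed before fitting and per-axis
FWHM outliers (> 3 MADs) after, each rule skipped below 3 beads where a MAD
is meaningless.

## Deconvolution

Richardson–Lucy with the standard multiplicative update
`u ← u · ((d / (u ∗ P)) ∗ P̂)`. Convolutions are FFT-based with the image
reflect-padded by the kernel half-support and cropped afterwards, which
suppresses the wrap-around artefacts a circulant implementation produces at
stack borders. The kernel is normalized to unit sum internally so flux is
approximately conserved (the suite checks ≤ 5 % drift on an interior point
source at 100 iterations). No regularization term is applied. After
deconvolution, one shared factor maps the global maximum across all stacks
of a run to a common maximum, default 5 × 65335 = 326675; sharing a single
factor keeps intensities comparable across images, unlike per-image max
scaling. The printed default is kept verbatim and is configurable (the
round value 5 × 65535 is one keystroke away for anyone who prefers it).

## Registration and per-cell QC

One integer translation per field is estimated from the DNA channel by
masked phase cross-correlation, with per-image full-strength Otsu
foreground masks. Sub-pixel refinement is deliberately absent: the per-cell
QC that follows tolerates residual error, and integer shifts keep
finalization free of interpolation. Per cell, the Pearson correlation
between the two cycles' DNA channels inside the cell mask decides pass/fail
at r < 0.6; a constant crop has undefined r and fails with an explicit
reason. Correlation is computed on whatever dimensionality the crops have
(3-D crops → 3-D r).

## Batch scaling

Per plate and channel, the scale factor is the mean control-cell intensity
(per-cell means, then the mean across cells) divided by the grand mean of
those per-plate means — anchoring on the grand mean avoids privileging any
single plate as reference. The sigmoid weight `y(x) = 1/(1 + e^{−a(x−b)})`
is pinned to `y(x₁) = 10⁻³` and `y(x₂) = 1 − 10⁻³`, with
`a = (L₂ − L₁)/(x₁ − x₂)` and `b = (x₁L₂ − x₂L₁)/(L₂ − L₁)` where
`Lᵢ = ln(1/yᵢ − 1)`; x₁ is the median 75th-percentile intensity of
cell-masked control images (background anchor) and x₂ the median Otsu
threshold of control cells (foreground anchor). The weighted correction is
`out = x / (1 + w(x)(s − 1))` — the one interpolation consistent with both
required limits (background unchanged, foreground divided by s). If x₁ ≥ x₂
the sigmoid is skipped with a warning and plain division is used; with a
single plate the per-plate offset and sigmoid are omitted entirely and only
dynamic-range scaling remains (default target: the 99.9th percentile of
control foreground maps to 90 % of the 16-bit range).

A strong factor (s near 2) necessarily compresses the sigmoid transition
band and can locally reorder pixel intensities there; the ordering of
background and foreground plateaus is always preserved, and `scale_pixels`
logs the affected fraction of the intensity range when it is nonzero. For
mild factors (s within roughly ±20 % of 1) the map is strictly monotone.

## Feature pipeline

QC runs image → feature → cell. Images keep between 5 and 1000 cells
inclusive. Multivariate image outliers are found per control group: z-score
the features, PCA, retain the fewest components reaching 75 % cumulative
variance, sum the squared standardized retained scores, refer to χ²(k), and
BH-adjust within the group at FDR 0.05 — Benjamini–Hochberg is used for
every multiple-testing correction in the package. Feature filters cover
blacklists, missingness, unique-value counts and coefficient of variation;
cell filters are hard min/max thresholds on metadata columns plus the
registration flag.

Box–Cox: features with non-positive minima are first shifted by
`|min| + x + 1` (implemented as `x − min + 1`, which lands the minimum on
exactly 1.0 in floating point). λ is selected by profile log-likelihood on
a grid over [−5, 5] in steps of 0.1, computed on a seeded random subsample
of up to 20 000 cells; ties break toward the λ closest to 1, then the
smaller. A fudge of 0.2 snaps |λ| ≤ 0.2 to the log transform and
|λ − 1| ≤ 0.2 to the identity. Scaling afterwards is a plain z-score with
zero-variance features set to 0 under a warning.

Feature sets: within each scope (channel, or channel × category), Pearson
correlations are computed on the transformed assay, negatives set to 0,
dissimilarity 1 − r, complete-linkage clustering, dendrogram cut at 0.3.
Clearing negative correlations keeps theoretically opposite feature pairs
(homogeneity vs heterogeneity) in separate sets on purpose. The flat cut is
inclusive of its height (merges at exactly the cut height stay merged),
matching the semantics of the standard hierarchical cut in R and SciPy. Set
ids are renumbered by first feature appearance so the partition is
deterministic under column order.

## Phenotyping

Cell-cycle gates are named polygons in raw integrated nuclear DNA (x)
versus log₁₀ integrated nuclear Ki67 (y), evaluated first-wins in
declaration order; polygon boundaries count as inside; anything ungated is
"Other", which enters composition models as its own category (a flag can
exclude it). Per-feature association models are fixed-effect OLS with the
term's coefficient test plus a likelihood-ratio test of the full against
the reduced model; the record shape (feature, term, coef, se, p, adjusted
p, formula, backend) is the contract an external mixed-model backend must
also satisfy, making the two interchangeable downstream. Marker detection
fits a no-intercept class-means model and tests contrasts — vs-rest (1 on
the class, −1/(K−1) elsewhere) or vs-reference (1/−1). Composition models
regress per-sample category percentages on the design; because percentages
sum to 100, category slopes sum to ~0 and the suite checks this. Represent-
ative cells: per group, the cell minimizing the sum of squared group-
centred reduced coordinates (index cell) plus its k nearest neighbours; for
continuous features, the cells at the requested quantiles (default 5th,
50th, 95th) extended by the k rank-neighbours on each side.

## Synthetic fixtures

The generators produce every input the pipeline consumes, each fully
determined by its seed and returning a manifest with the ground truth a
recovery test needs (true polynomial coefficients, bead centres and sigmas,
injected shifts, moved-cell ids, batch factors, block structure, true
betas, intended phase labels). Defaults aim at the plate geometry of a
confocal 40× acquisition: 0.8 μm z-spacing against ~0.3 μm in-plane, cell
diameters spanning 5–12 μm (resting to activated lymphocytes), ellipsoidal
(z-flattened) cell bodies with nuclei at 55 % of the cell radius and
bright organelle puncta, Poisson photon plus Gaussian read noise available
but off by default so oracle tests stay exact. Cells may overhang field
edges as in real acquisitions; fixtures that inject global translations use
an explicit edge margin instead, because a shifted edge cell is genuinely
(not spuriously) corrupted. Bead fields respect the 20-px exclusion by
construction, and a "corrupted" bead is a 2.5× defocused Gaussian — a
single detectable spot that the RMSE rule, not the neighbour rule, must
catch. Skewed features are built by inverse Box–Cox of a latent normal with
mean 5, sd 1.5 — wide enough that the exponent is sharply identifiable and
safely inside the transform's support, so no clipping distorts the tail.

What the fixtures do *not* emulate: optical PSF structure beyond Gaussian
blur, spectral bleed-through, autofluorescence, segmentation errors (masks
are ground truth by construction), uneven cell morphology, or the
heavy-tailed intensity distributions of real stains. Passing recovery tests
therefore demonstrates correctness of the estimators under their stated
models, not robustness to every failure mode of real microscopy data.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: 96–128 px fields with 4–6 z-planes, tens of fields per plate,
≤ 5000-cell feature tables, ≤ 100 RL iterations on ≤ 16×48×48 stacks.
These sizes keep the full suite under half a minute while leaving every
estimator's statistical behaviour measurable; all of them scale linearly
or n log n in pixels.

## Known limitations

- The RL implementation is CPU/FFT-based; a GPU non-circulant backend is an
  integration point, not included.
- Sub-pixel registration is out of scope by design; rotation and
  deformation are not modelled.
- `estimate_flatfield` requires enough spatial foreground coverage to
  constrain 15 coefficients; it refuses (rather than regularizes) degenerate
  fits.
- The internal association backend is fixed-effects OLS; nested random
  effects (plate:well) require plugging in an external mixed-model engine
  through the documented record contract.
- Gate polygons are first-wins; overlapping gates are legal but
  order-sensitive by documented intent.
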