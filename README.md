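# tglow

Image restoration and single-cell feature analytics for cyclic
immunofluorescence, high-content imaging of lymphocytes.

Plate-based cyclic imaging multiplies the number of markers measurable per
channel by staining, imaging and bleaching the same fixed cells over several
rounds. Before any biology can be read off the images, a chain of
computational corrections has to run: the microscope's illumination profile
varies across the field of view, the optics blur along z far more than in
xy, imaging cycles are shifted relative to each other, staining intensity
drifts between plates, and markers sharing a channel must be separated into
nuclear and non-nuclear components. Downstream, the per-cell morphological
feature tables need quality control, variance-stabilising transformation and
de-redundancy before statistical modelling. `tglow` implements that chain
for people who build and validate such pipelines, with a synthetic-fixture
generator so every stage is testable without microscope data.

## What it computes

**Flatfield correction.** The illumination surface is a full bivariate
polynomial of degree four,
`I(x, y) = Σ_{i+j≤4} c_ij x^i y^j` (15 terms), fit by ordinary least squares
to lenient-foreground pixels (two-class Otsu threshold divided by 4, taken
on compound max-projection images so sparse fields get a stable threshold)
and normalized to mean 1; images are divided by the surface.

**PSF metrology and deconvolution.** An empirical point spread function is
built from fluorescent bead stacks (LoG spot detection, 20-px neighbour
exclusion, cross-correlation alignment, RMSE outlier rejection at
mean + 1.645 sd, background subtraction, centre-of-mass centring, max-1
normalization). Effective resolution is the Gaussian-fit full width at half
maximum per axis, `FWHM = 2.35482 σ`. Richardson–Lucy deconvolution
(multiplicative updates, reflect-padded FFT convolutions, 100 iterations by
default) restores the stacks, which are then rescaled by one shared factor
so the run's global maximum sits at 5 × 65335 = 326675 before 16-bit
storage.

**Registration and batch scaling.** Cycle-to-cycle translation is estimated
from the DNA channel by masked phase cross-correlation on Otsu foreground;
cells whose two DNA channels correlate with Pearson r < 0.6 after alignment
are discarded. Plate-level intensity offsets are anchored on shared control
wells and applied through a sigmoid soft threshold
`y(x) = 1 / (1 + e^{−a(x−b)})` pinned to weight 10⁻³ at the background
anchor x₁ and 1 − 10⁻³ at the foreground anchor x₂, so background pixels
stay untouched while foreground is divided by the full per-plate factor.

**Feature analytics.** Image QC (5–1000 cells per image, PCA-distance
outliers at FDR < 0.05 within control groups), feature and cell filters,
Box–Cox transformation (λ from a profile-likelihood grid over [−5, 5] in
steps of 0.1 on a 20 000-cell subsample, with a 0.2 fudge snapping to the
log or identity transform; non-positive features first shifted by
`|min(x)| + x + 1`), z-scoring, and "feature sets": complete-linkage
clusters of the dissimilarity 1 − max(correlation, 0), cut at 0.3. On top of
that: polygon-gate cell-cycle assignment in DNA × log₁₀ Ki67 space, fixed-
effect marker models with vs-rest / vs-reference contrasts, composition
(proportion) regressions and representative-cell selection.

## Worked example

```python
import numpy as np
from tglow import simulate, estimate_flatfield, estimate_translation
from tglow.flatfield import design_matrix, _normalized_coords

# a plate whose true illumination surface is a known quartic vignette
coeffs = simulate.quartic_field_coefficients(0.4)
images, manifest = simulate.simulate_flatfield_images(
    n_images=40, flatfield_coeffs=coeffs, seed=2)

model = estimate_flatfield(images, n_compound=60, n_per_compound=20, seed=1)
yy, xx = _normalized_coords((96, 96))
truth = (design_matrix(yy, xx) @ coeffs).reshape(96, 96)
r = np.corrcoef(truth.ravel(), model.surface((96, 96)).ravel())[0, 1]
print(f"flatfield recovery r = {r:.5f}")

# a second imaging cycle shifted by (+1, +5, -3) voxels
data, _ = simulate.simulate_plate_fields(
    n_plates=1, n_fields=1, cells_per_field=10, seed=7,
    shape=(6, 128, 128), edge_margin_px=10)
(stack, masks), = data.values()
cycle2, man = simulate.simulate_cycle_pair(stack, masks, shift=(1, 5, -3), seed=4)
offset = estimate_translation(stack.channel("dna"), cycle2.voxels[0])
print(f"recovered offset (dz, dy, dx) = {offset.offset}")
```

prints

```
flatfield recovery r = 0.99995
recovered offset (dz, dy, dx) = (-1, -5, 3)
```

The recovered surface matches the injected quartic almost exactly
(correlation 0.99995 against the stored ground truth), and the estimated
translation is exactly the inverse of the injected shift — the offset one
applies to cycle 2 to land it back on cycle 1.

A `tglow` command-line entry point wraps the same operations
(`tglow flatfield fit`, `tglow psf build`, `tglow register`,
`tglow finalize`, `tglow simulate …`, `tglow run --config …`).

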