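"""Polynomial flatfield (illumination) estimation and correction.

The illumination profile across the field of view is modelled as a full
bivariate polynomial of degree four in the in-plane coordinates,

    I(x, y) = c0 + c1·x + c2·y + c3·xy + c4·x² + c5·y² + c6·x³ + c7·x²y
            + c8·xy² + c9·y³ + c10·x⁴ + c11·x³y + c12·x²y² + c13·xy³ + c14·y⁴

fit by ordinary least squares to foreground pixels and normalized to mean 1
over the image domain, so that dividing by the surface preserves the average
intensity. Foreground is defined leniently: sparse fields are first combined
into compound max-projection images so a stable two-class Otsu threshold can
be computed, and that threshold is divided by four.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .imaging import ImageStack

N_COEFFS = 15

# exponent pairs (i, j) for x^i * y^j in the fixed basis order
BASIS_EXPONENTS = [
    (0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (3, 0), (2, 1),
    (1, 2), (0, 3), (4, 0), (3, 1), (2, 2), (1, 3), (0, 4),
]


def _normalized_coords(shape_yx: tuple[int, int]):
    """Pixel-centre coordinates scaled to [-1, 1] per axis, for conditioning."""
    ny, nx = shape_yx
    y = np.linspace(-1.0, 1.0, ny) if ny > 1 else np.zeros(1)
    x = np.linspace(-1.0, 1.0, nx) if nx > 1 else np.zeros(1)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return yy, xx


def design_matrix(yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    cols = [xx.ravel() ** i * yy.ravel() ** j for i, j in BASIS_EXPONENTS]
    return np.stack(cols, axis=1)


@dataclass
class FlatfieldModel:
    """Fitted multiplicative illumination surface for one plate + channel."""

    coefficients: np.ndarray  # 15 basis coefficients, post-normalization
    plate: str
    channel: str
    shape_yx: tuple[int, int]
    normalization: bool = True
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (N_COEFFS,):
            raise ValueError(f"expected {N_COEFFS} coefficients")

    def surface(self, shape_yx: tuple[int, int] | None = None) -> np.ndarray:
        """Evaluate the normalized surface over an image domain."""
        shape_yx = tuple(shape_yx or self.shape_yx)
        yy, xx = _normalized_coords(shape_yx)
        surf = design_matrix(yy, xx) @ self.coefficients
        return surf.reshape(shape_yx)

    @classmethod
    def identity(cls, shape_yx, plate: str = "", channel: str = "") -> "FlatfieldModel":
        coef = np.zeros(N_COEFFS)
        coef[0] = 1.0
        return cls(coef, plate, channel, tuple(shape_yx))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "coefficients": self.coefficients.tolist(),
            "plate": self.plate,
            "channel": self.channel,
            "shape_yx": list(self.shape_yx),
            "normalization": self.normalization,
            "fit_diagnostics": self.fit_diagnostics,
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FlatfieldModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["coefficients"]), d["plate"], d["channel"],
                   tuple(d["shape_yx"]), d.get("normalization", True),
                   d.get("fit_diagnostics", {}))


def _as_planes(images, channel: str | None) -> list[np.ndarray]:
    """Coerce ImageStacks / 3-D / 2-D arrays to a list of 2-D max projections."""
    planes = []
    for im in images:
        if isinstance(im, ImageStack):
            arr = im.channel(channel) if channel else im.voxels[0]
        else:
            arr = np.asarray(im, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr.max(axis=0)
        planes.append(arr)
    return planes


def lenient_foreground_threshold(compound: np.ndarray) -> float:
    """Two-class Otsu on a 256-bin histogram, divided by four."""
    return float(threshold_otsu(compound, nbins=256)) / 4.0


def estimate_flatfield(
    images,
    plate: str = "",
    channel: str | None = None,
    n_compound: int = 200,
    n_per_compound: int = 20,
    seed: int = 0,
) -> FlatfieldModel:
    """Fit a FlatfieldModel from sampled images of one plate + channel.

    ``n_compound`` compound images are built, each the pixelwise max of
    ``n_per_compound`` randomly sampled images (with replacement when the
    plate has fewer images). For each compound a lenient foreground threshold
    (Otsu/4) is computed; foreground pixels of all compounds are pooled and
    fit by OLS to the degree-four basis, then normalized to mean 1.
    """
    planes = _as_planes(images, channel)
    if not planes:
        raise ValueError("no images supplied")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("images must share shape")
    rng = np.random.default_rng(seed)

    yy, xx = _normalized_coords(shape)
    X_full = design_matrix(yy, xx)

    rows, targets = [], []
    stackarr = np.stack(planes)
    for _ in range(n_compound):
        take = rng.choice(len(planes), size=n_per_compound,
                          replace=len(planes) < n_per_compound)
        compound = stackarr[take].max(axis=0)
        thr = lenient_foreground_threshold(compound)
        fg = compound.ravel() > thr
        if fg.any():
            rows.append(X_full[fg])
            targets.append(compound.ravel()[fg])
    if not rows:
        raise ValueError("no foreground pixels after thresholding")
    X = np.concatenate(rows)
    y = np.concatenate(targets)

    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < N_COEFFS:
        raise np.linalg.LinAlgError(
            f"rank-deficient flatfield design (rank {rank} < {N_COEFFS})")

    surf = (X_full @ coef).reshape(shape)
    mean = surf.mean()
    if mean <= 0:
        raise ValueError("fitted surface has non-positive mean")
    coef = coef / mean
    surf = surf / mean
    if surf.min() <= 0:
        raise ValueError("normalized surface not strictly positive over the domain")

    fitted = X @ (coef * mean) / mean  # fitted values on the normalized scale
    resid = y / mean - fitted
    return FlatfieldModel(
        coef, plate, channel or "", shape,
        fit_diagnostics={
            "n_foreground_pixels": int(len(y)),
            "n_compound": n_compound,
            "seed": seed,
            "residual_sd": float(resid.std()),
            "surface_min": float(surf.min()),
            "surface_max": float(surf.max()),
        },
    )


def apply_flatfield(stack: ImageStack, model: FlatfieldModel) -> ImageStack:
    """Divide one channel by the normalized surface; other channels untouched."""
    surf = model.surface(stack.shape_zyx[1:])
    if surf.min() <= 0:
        raise ValueError("flatfield surface must be strictly positive")
    idx = stack.channel_index(model.channel)
    vox = stack.voxels.copy()
    vox[idx] = vox[idx] / surf  # broadcasts over z
    return ImageStack(vox, list(stack.channel_names), stack.pixel_size)


def assess_flatfield_fit(images, model: FlatfieldModel, grid: int = 20,
                         correct: bool = True) -> dict:
    """Evaluate residual position↔intensity structure on held-out images.

    Held-out images are corrected, foreground pixels binned into a
    ``grid × grid`` raster, and bin mean intensity regressed on the bin mean
    surface value. A well-corrected field shows a standardized slope near 0;
    with ``correct=False`` the raw images are binned instead, exposing the
    positive surface↔intensity slope present before correction.
    """
    planes = _as_planes(images, model.channel or None)
    if not planes:
        raise ValueError("no held-out images")
    shape = planes[0].shape
    surf = model.surface(shape)

    ny, nx = shape
    iy = np.minimum((np.arange(ny) * grid) // ny, grid - 1)
    ix = np.minimum((np.arange(nx) * grid) // nx, grid - 1)
    bin_id = (iy[:, None] * grid + ix[None, :]).ravel()

    sums = np.zeros(grid * grid)
    surf_sums = np.zeros(grid * grid)
    counts = np.zeros(grid * grid)
    for p in planes:
        corrected = p / surf if correct else p
        # full-strength Otsu here: the /4 lenient rule serves the fit, while
        # assessment wants clean foreground averages per bin
        fg = (p > threshold_otsu(p, nbins=256)).ravel()
        np.add.at(sums, bin_id[fg], corrected.ravel()[fg])
        np.add.at(surf_sums, bin_id[fg], surf.ravel()[fg])
        np.add.at(counts, bin_id[fg], fg[fg].astype(float))

    keep = counts > 0
    n_empty = int((~keep).sum())
    bin_mean = sums[keep] / counts[keep]
    bin_surf = surf_sums[keep] / counts[keep]
    if keep.sum() < 3 or bin_surf.std() == 0 or bin_mean.std() == 0:
        warnings.warn("degenerate assessment: too few informative bins", stacklevel=2)
        return {"slope": 0.0, "correlation": 0.0, "n_bins": int(keep.sum()),
                "n_empty_bins": n_empty}
    r = float(np.corrcoef(bin_surf, bin_mean)[0, 1])
    # standardized slope == correlation of z-scored variables
    zx = (bin_surf - bin_surf.mean()) / bin_surf.std()
    zy = (bin_mean - bin_mean.mean()) / bin_mean.std()
    slope = float(np.polyfit(zx, zy, 1)[0])
    return {"slope": slope, "correlation": r, "n_bins": int(keep.sum()),
            "n_empty_bins": n_empty}
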