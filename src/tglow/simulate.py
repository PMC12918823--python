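"""Synthetic fixtures for every pipeline stage: bead stacks, plate fields
with known illumination and batch distortions, cycle pairs with injected
shifts, and structured single-cell feature tables.

Every generator is fully deterministic given its seed and returns a
:class:`FixtureManifest` recording the ground truth (true flatfield
coefficients, bead positions and sigmas, injected shifts, moved-cell ids,
batch factors, feature-block structure, true betas, intended phase labels)
so recovery tests can score estimates against the construction.

Cell bodies are z-anisotropic ellipsoids, mimicking the coarser axial
sampling of confocal stacks; the noise model is Poisson photon noise plus
Gaussian read noise. Radii default to the 5–12 μm range spanning resting to
activated lymphocyte sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .flatfield import N_COEFFS, FlatfieldModel, design_matrix, _normalized_coords
from .imaging import ImageStack, MaskPair, PlateAddress, translate_int, write_plate_stack


@dataclass
class FixtureManifest:
    """Seed, generator parameters and ground truth for one fixture."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"seed": self.seed, "kind": self.kind, "params": self.params,
             "truth": self.truth}, indent=1, default=_jsonable))
        return path


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _add_noise(img: np.ndarray, rng: np.random.Generator,
               poisson: bool, read_sd: float) -> np.ndarray:
    out = img
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if read_sd > 0:
        out = out + rng.normal(0.0, read_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Beads


def simulate_beads(
    n_beads: int = 5,
    sigmas: tuple[float, float, float] = (2.0, 1.0, 1.0),
    shape: tuple[int, int, int] = (24, 128, 128),
    amplitude: float = 5000.0,
    background: float = 0.0,
    jitter: float = 0.0,
    poisson_noise: bool = False,
    read_noise_sd: float = 0.0,
    exclusion_px: float = 20.0,
    n_corrupted: int = 0,
    pixel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    seed: int = 0,
) -> tuple[ImageStack, FixtureManifest]:
    """Anisotropic Gaussian point sources on a constant background.

    Bead centres are placed at least ``exclusion_px`` apart (and away from
    the borders) so the neighbour-exclusion rule never fires by accident;
    ``jitter`` adds a recorded sub-voxel offset per bead. ``n_corrupted``
    beads are replaced by uniform noise blobs to exercise the RMSE filter.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    # keep beads clear of the borders so a full crop window always fits
    margin = np.array([max(int(4 * sigmas[0]) + 2, 7),
                       max(int(4 * sigmas[1]) + 2, 10),
                       max(int(4 * sigmas[2]) + 2, 10)])
    if any(2 * m >= s for m, s in zip(margin, shape)):
        raise ValueError("cannot place beads: field too small for the margins")
    centers = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 2000 * n_beads:
            raise ValueError("cannot place beads without overlap; enlarge field")
        c = np.array([
            rng.uniform(margin[0], nz - margin[0]),
            rng.uniform(margin[1], ny - margin[1]),
            rng.uniform(margin[2], nx - margin[2]),
        ])
        if all(np.linalg.norm(c - p) >= exclusion_px + 4 for p in centers):
            centers.append(c)
    centers = np.asarray(centers)
    if jitter > 0:
        centers = centers + rng.uniform(-jitter, jitter, size=centers.shape)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij", sparse=True)
    img = np.full(shape, float(background))
    corrupted_ids = list(range(n_beads - n_corrupted, n_beads))
    for i, (cz, cy, cx) in enumerate(centers):
        if i in corrupted_ids:
            # defocused bead: detected as one spot but mismatching the rest
            sz, sy, sx = (2.5 * s for s in sigmas)
        else:
            sz, sy, sx = sigmas
        g = np.exp(-0.5 * (((zz - cz) / sz) ** 2
                           + ((yy - cy) / sy) ** 2
                           + ((xx - cx) / sx) ** 2))
        img += amplitude * g
    img = _add_noise(img, rng, poisson_noise, read_noise_sd)

    stack = ImageStack(img[None], ["beads"], pixel_size)
    manifest = FixtureManifest(
        seed=seed, kind="beads",
        params={"n_beads": n_beads, "shape": list(shape),
                "amplitude": amplitude, "background": background,
                "jitter": jitter, "exclusion_px": exclusion_px,
                "n_corrupted": n_corrupted},
        truth={"positions": centers.tolist(), "sigmas": list(sigmas),
               "corrupted_ids": corrupted_ids,
               "pixel_size": list(pixel_size)},
    )
    return stack, manifest


# ---------------------------------------------------------------------------
# Plate fields


def quartic_field_coefficients(strength: float = 0.4) -> np.ndarray:
    """A smooth, strictly positive degree-four illumination surface: a
    centre-bright vignette 1 + strength·(1 − (x² + y²)/2) shaped profile."""
    coef = np.zeros(N_COEFFS)
    coef[0] = 1.0 + strength          # constant
    coef[4] = -strength * 0.6         # x²
    coef[5] = -strength * 0.6         # y²
    coef[12] = strength * 0.15        # x²y²
    return coef


def _ellipsoid_mask(shape_zyx, center, radii) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape_zyx),
                             indexing="ij", sparse=True)
    return (((zz - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((xx - center[2]) / radii[2]) ** 2) <= 1.0


def simulate_field(
    cells: int,
    shape: tuple[int, int, int] = (8, 160, 160),
    channels: tuple[str, ...] = ("dna", "marker"),
    pixel_size: tuple[float, float, float] = (0.8, 0.3, 0.3),
    cell_radius_um: tuple[float, float] = (5.0, 12.0),
    cell_intensity: tuple[float, float] = (800.0, 1400.0),
    nucleus_fraction: float = 0.55,
    marker_factor_range: tuple[float, float] = (0.6, 1.0),
    edge_margin_px: float | None = None,
    n_puncta: int = 4,
    background: float = 80.0,
    read_noise_sd: float = 0.0,
    poisson_noise: bool = False,
    flatfield_surface: np.ndarray | None = None,
    intensity_factor: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, MaskPair, dict]:
    """One field of ellipsoidal cells with nuclei and organelle puncta.

    Per-channel intensities are multiplied by the evaluated flatfield surface
    (a (y, x) array) and the plate ``intensity_factor`` before noise.
    """
    rng = rng or np.random.default_rng(0)
    nz, ny, nx = shape
    vox = np.full((len(channels), nz, ny, nx), float(background))
    cell_lab = np.zeros(shape, dtype=np.int32)
    nuc_lab = np.zeros(shape, dtype=np.int32)
    truth_cells = []
    placed = 0
    attempts = 0
    while placed < cells:
        attempts += 1
        if attempts > 300 * max(cells, 1):
            raise ValueError("field overcrowded; cannot place all cells")
        r_um = rng.uniform(*cell_radius_um) / 2.0  # radius from diameter range
        ry = rx = max(r_um / pixel_size[1], 3.0)
        rz = max(r_um / pixel_size[0], 1.5)
        cz = nz / 2 + rng.uniform(-1, 1)
        if edge_margin_px is None:
            # cells may overhang the field edge, as in real acquisitions
            cy = rng.uniform(-0.8 * ry, ny + 0.8 * ry)
            cx = rng.uniform(-0.8 * rx, nx + 0.8 * rx)
        else:
            # fully contained with a clearance, for translation fixtures
            cy = rng.uniform(ry + edge_margin_px, ny - ry - edge_margin_px)
            cx = rng.uniform(rx + edge_margin_px, nx - rx - edge_margin_px)
        body = _ellipsoid_mask(shape, (cz, cy, cx), (rz, ry, rx))
        if (cell_lab[body] > 0).any():
            continue
        placed += 1
        label = placed
        cell_lab[body] = label
        nuc = _ellipsoid_mask(shape, (cz, cy, cx),
                              (rz * nucleus_fraction, ry * nucleus_fraction,
                               rx * nucleus_fraction))
        nuc_lab[nuc] = label
        amp = rng.uniform(*cell_intensity)
        vox[0][nuc] += amp * 1.6                  # DNA concentrated in the nucleus
        for ci in range(1, len(channels)):
            vox[ci][body] += amp * rng.uniform(*marker_factor_range)
            for _ in range(n_puncta):             # organelle puncta
                pz = int(np.clip(cz + rng.uniform(-rz, rz) * 0.5, 0, nz - 1))
                py = int(np.clip(cy + rng.uniform(-ry, ry) * 0.6, 0, ny - 1))
                px = int(np.clip(cx + rng.uniform(-rx, rx) * 0.6, 0, nx - 1))
                vox[ci][pz, max(py - 1, 0):py + 2, max(px - 1, 0):px + 2] += amp * 0.8
        truth_cells.append({"label": label, "center": [cz, cy, cx],
                            "radii": [rz, ry, rx], "amplitude": amp})

    if flatfield_surface is not None:
        vox = vox * flatfield_surface[None, None, :, :]
    vox = vox * intensity_factor
    for ci in range(len(channels)):
        vox[ci] = _add_noise(vox[ci], rng, poisson_noise, read_noise_sd)

    stack = ImageStack(vox, list(channels), pixel_size)
    return stack, MaskPair(cell_lab, nuc_lab), {"cells": truth_cells}


def simulate_plate_fields(
    n_plates: int = 2,
    n_fields: int = 4,
    cells_per_field: int = 6,
    flatfield_coeffs: np.ndarray | None = None,
    batch_factors: list[float] | None = None,
    control_wells: tuple[str, ...] = ("r01/c01",),
    shape: tuple[int, int, int] = (6, 128, 128),
    channels: tuple[str, ...] = ("dna", "marker"),
    seed: int = 0,
    out_dir: str | Path | None = None,
    **field_kwargs,
) -> tuple[dict, FixtureManifest]:
    """Plates of fields sharing one illumination surface, with per-plate
    multiplicative batch factors; control wells are marked in the manifest.

    Returns ``(data, manifest)`` where ``data`` maps PlateAddress →
    (ImageStack, MaskPair). When ``out_dir`` is given, stacks are also
    written under the plate/row/col/field layout.
    """
    if flatfield_coeffs is None:
        flatfield_coeffs = np.zeros(N_COEFFS)
        flatfield_coeffs[0] = 1.0
    flatfield_coeffs = np.asarray(flatfield_coeffs, dtype=np.float64)
    if flatfield_coeffs.shape != (N_COEFFS,):
        raise ValueError(f"flatfield coefficients must have length {N_COEFFS}")
    batch_factors = list(batch_factors or [1.0] * n_plates)
    if len(batch_factors) != n_plates:
        raise ValueError("one batch factor per plate required")

    yy, xx = _normalized_coords(shape[1:])
    surface = (design_matrix(yy, xx) @ flatfield_coeffs).reshape(shape[1:])
    if surface.min() <= 0:
        raise ValueError("true flatfield surface must be strictly positive")

    rng = np.random.default_rng(seed)
    data = {}
    for pi in range(n_plates):
        plate = f"plate{pi + 1}"
        for fi in range(n_fields):
            well = control_wells[fi % len(control_wells)] if fi % 2 == 0 \
                else f"r{2 + fi:02d}/c{2 + fi:02d}"
            row, col = well.split("/")
            addr = PlateAddress(plate, row, col, field=fi + 1)
            stack, masks, _ = simulate_field(
                cells=cells_per_field, shape=shape, channels=channels,
                flatfield_surface=surface,
                intensity_factor=batch_factors[pi], rng=rng, **field_kwargs)
            data[addr] = (stack, masks)
            if out_dir is not None:
                write_plate_stack(out_dir, addr, stack)
    manifest = FixtureManifest(
        seed=seed, kind="plate_fields",
        params={"n_plates": n_plates, "n_fields": n_fields,
                "cells_per_field": cells_per_field, "shape": list(shape),
                "channels": list(channels)},
        truth={"flatfield_coefficients": flatfield_coeffs.tolist(),
               "flatfield_surface_mean": float(surface.mean()),
               "batch_factors": batch_factors,
               "control_wells": list(control_wells)},
    )
    return data, manifest


def simulate_flatfield_images(
    n_images: int = 40,
    flatfield_coeffs: np.ndarray | None = None,
    shape_yx: tuple[int, int] = (96, 96),
    foreground: float = 1000.0,
    background: float = 20.0,
    fg_fraction: float = 0.35,
    disc_radius: tuple[int, int] = (6, 14),
    read_noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], FixtureManifest]:
    """Sparse images of uniform-intensity foreground discs under a known
    multiplicative quartic illumination surface — the clean fixture for
    flatfield recovery tests (truth stored in the manifest)."""
    if flatfield_coeffs is None:
        flatfield_coeffs = quartic_field_coefficients()
    flatfield_coeffs = np.asarray(flatfield_coeffs, dtype=np.float64)
    yy, xx = _normalized_coords(shape_yx)
    surface = (design_matrix(yy, xx) @ flatfield_coeffs).reshape(shape_yx)
    if surface.min() <= 0:
        raise ValueError("true surface must be strictly positive")
    rng = np.random.default_rng(seed)
    ny, nx = shape_yx
    gy, gx = np.mgrid[:ny, :nx]
    images = []
    for _ in range(n_images):
        img = np.full(shape_yx, float(background))
        covered = 0
        while covered < fg_fraction * ny * nx:
            r = rng.integers(disc_radius[0], disc_radius[1] + 1)
            cy, cx = rng.uniform(0, ny), rng.uniform(0, nx)
            disc = (gy - cy) ** 2 + (gx - cx) ** 2 <= r ** 2
            img[disc] = foreground
            covered = (img > background).sum()
        img = img * surface
        if read_noise_sd > 0:
            img = np.clip(img + rng.normal(0, read_noise_sd, shape_yx), 0, None)
        images.append(img)
    manifest = FixtureManifest(
        seed=seed, kind="flatfield_images",
        params={"n_images": n_images, "shape_yx": list(shape_yx),
                "foreground": foreground, "background": background,
                "fg_fraction": fg_fraction},
        truth={"flatfield_coefficients": flatfield_coeffs.tolist(),
               "surface": surface.tolist()},
    )
    return images, manifest


# ---------------------------------------------------------------------------
# Cycle pairs


def simulate_cycle_pair(
    stack: ImageStack,
    masks: MaskPair,
    shift: tuple[int, int, int] = (0, 0, 0),
    moved_fraction: float = 0.0,
    move_px: int = 8,
    seed: int = 0,
) -> tuple[ImageStack, FixtureManifest]:
    """Second-cycle stack: the field globally translated by ``shift``, with a
    random ``moved_fraction`` of cells additionally displaced independently
    (in-plane, by ``move_px`` pixels). Moved cell ids are recorded; cells
    pushed out of the field are dropped and recorded."""
    for s, dim in zip(shift, stack.shape_zyx):
        if abs(s) > 0.25 * dim:
            raise ValueError("shift exceeds 25% of the field extent")
    rng = np.random.default_rng(seed)
    cell3d = masks.cell_labels
    if cell3d.ndim == 2:
        cell3d = np.broadcast_to(cell3d, stack.shape_zyx)
    ids = np.unique(cell3d)
    ids = ids[ids > 0]
    n_moved = int(round(moved_fraction * len(ids)))
    moved = sorted(rng.choice(ids, size=n_moved, replace=False).tolist()) \
        if n_moved else []

    vox = stack.voxels.copy()
    background = float(np.median(vox))
    dropped = []
    actually_moved = []
    for cid in moved:
        sel = cell3d == cid
        coords = np.argwhere(sel)
        # try displacement directions until one stays in-field and does not
        # land on another cell (which would corrupt that cell's crop too)
        placed = False
        for sy, sx in rng.permutation([(1, 1), (1, -1), (-1, 1), (-1, -1)]):
            new_yx = coords[:, 1:] + np.array([sy * move_px, sx * move_px])
            if (new_yx < 0).any() or (new_yx[:, 0] >= sel.shape[1]).any() \
                    or (new_yx[:, 1] >= sel.shape[2]).any():
                continue
            dest_labels = cell3d[coords[:, 0], new_yx[:, 0], new_yx[:, 1]]
            if np.any((dest_labels != 0) & (dest_labels != cid)):
                continue
            for ci in range(vox.shape[0]):
                ch = vox[ci]
                patch = ch[sel].copy()
                ch[sel] = background
                ch[coords[:, 0], new_yx[:, 0], new_yx[:, 1]] = patch
            placed = True
            break
        if placed:
            actually_moved.append(int(cid))
        else:
            dropped.append(int(cid))
            vox[:, sel] = background
    moved = actually_moved
    shifted = np.stack([translate_int(ch, shift) for ch in vox])
    out = ImageStack(shifted, [f"{n}2" for n in stack.channel_names],
                     stack.pixel_size)
    manifest = FixtureManifest(
        seed=seed, kind="cycle_pair",
        params={"shift": list(shift), "moved_fraction": moved_fraction,
                "move_px": move_px},
        truth={"shift": list(shift),
               "expected_offset": [-s for s in shift],
               "moved_ids": [int(m) for m in moved],
               "dropped_ids": dropped},
    )
    return out, manifest


# ---------------------------------------------------------------------------
# Feature tables


def _block_correlated(rng, n, sizes_r: list[tuple[int, float]]) -> np.ndarray:
    cols = []
    for size, r in sizes_r:
        if not -1 < r < 1:
            raise ValueError(f"infeasible within-block correlation {r}")
        shared = rng.standard_normal(n)
        uniq = rng.standard_normal((n, size))
        cols.append(np.sqrt(r) * shared[:, None] + np.sqrt(1 - r) * uniq)
    return np.concatenate(cols, axis=1)


def _inverse_boxcox(z: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0:
        return np.exp(z)
    return np.power(np.clip(lam * z + 1.0, 1e-9, None), 1.0 / lam)


DEFAULT_GATES = {
    # (x = integrated DNA, y = log10 integrated Ki67); 2N ≈ 100, 4N ≈ 200
    "G0": [(60, 0.0), (140, 0.0), (140, 2.0), (60, 2.0)],
    "G1": [(60, 2.0), (140, 2.0), (140, 4.0), (60, 4.0)],
    "S": [(140, 2.0), (170, 2.0), (170, 4.0), (140, 4.0)],
    "G2M": [(170, 2.0), (260, 2.0), (260, 4.0), (170, 4.0)],
}

_PHASE_CENTERS = {
    # (DNA mean, log10 Ki67 mean) well inside each default gate
    "G0": (100.0, 1.0),
    "G1": (100.0, 3.0),
    "S": (155.0, 3.0),
    "G2M": (200.0, 3.0),
}


def simulate_feature_table(
    n_cells: int = 2000,
    blocks: list[tuple[int, float]] = ((10, 0.9), (10, 0.9), (10, 0.9)),
    group_effects: dict[str, float] | None = None,
    n_extra_features: int = 0,
    boxcox_lambdas: dict[str, float] | None = None,
    phase_structure: dict[str, float] | None = None,
    n_donors: int = 4,
    n_wells_per_plate: int = 4,
    n_plates: int = 2,
    missingness: float = 0.0,
    seed: int = 0,
    channels: tuple[str, ...] = ("dna", "actin", "mito"),
) -> tuple["FeatureTable", FixtureManifest]:
    """Structured cells × features table with known ground truth.

    Features come in correlated blocks (``blocks`` = list of (size, within-
    block correlation)); optional group effects add a mean difference between
    two groups on the first block; ``boxcox_lambdas`` appends skewed features
    built by inverse Box–Cox of standard normals with recorded λ₀;
    ``phase_structure`` (phase → fraction) draws DNA/Ki67 intensity columns
    inside the matching default gate polygons.
    """
    from .features import FeatureTable  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    X = _block_correlated(rng, n_cells, list(blocks))
    names = []
    block_map = {}
    for bi, (size, r) in enumerate(blocks):
        chan = channels[bi % len(channels)]
        for j in range(size):
            nm = f"cell_intensity_b{bi}f{j}_{chan}"
            names.append(nm)
            block_map[nm] = bi
    if n_extra_features:
        X = np.concatenate(
            [X, rng.standard_normal((n_cells, n_extra_features))], axis=1)
        for j in range(n_extra_features):
            names.append(f"cell_texture_extra{j}_{channels[j % len(channels)]}")

    meta = pd.DataFrame(index=pd.RangeIndex(n_cells, name="cell"))
    meta["donor"] = [f"d{1 + i % n_donors}" for i in range(n_cells)]
    meta["plate"] = [f"plate{1 + (i // max(n_cells // n_plates, 1)) % n_plates}"
                     for i in range(n_cells)]
    meta["well"] = [f"w{1 + i % n_wells_per_plate}" for i in range(n_cells)]
    meta["field"] = 1
    meta["group"] = np.where(rng.random(n_cells) < 0.5, "treated", "control")
    meta["control_group"] = meta["group"]

    true_betas = dict(group_effects or {})
    for nm, beta in true_betas.items():
        if nm not in names:
            raise KeyError(f"group effect on unknown feature {nm!r}")
        X[:, names.index(nm)] += beta * (meta["group"] == "treated").to_numpy()

    values = pd.DataFrame(X, index=meta.index, columns=names)

    lambda_truth = dict(boxcox_lambdas or {})
    for nm, lam in lambda_truth.items():
        # latent normal kept well inside the transform's support (so the
        # inverse power transform is exact) and wide enough that the
        # profile likelihood identifies the exponent sharply
        values[nm] = _inverse_boxcox(rng.normal(5.0, 1.5, n_cells), lam)

    phase_labels = None
    if phase_structure:
        phases = list(phase_structure)
        probs = np.asarray([phase_structure[p] for p in phases], dtype=float)
        probs = probs / probs.sum()
        phase_labels = rng.choice(phases, size=n_cells, p=probs)
        dna = np.empty(n_cells)
        ki67 = np.empty(n_cells)
        for p in phases:
            sel = phase_labels == p
            cx, cy = _PHASE_CENTERS[p]
            dna[sel] = rng.normal(cx, 6.0, size=sel.sum())
            ki67[sel] = 10.0 ** rng.normal(cy, 0.25, size=sel.sum())
        values["nucleus_intensity_integrated_dna"] = dna
        values["nucleus_intensity_integrated_ki67"] = ki67
        meta["true_phase"] = phase_labels

    if missingness > 0:
        mask = rng.random(values.shape) < missingness
        values = values.mask(mask)

    table = FeatureTable(values, meta)
    manifest = FixtureManifest(
        seed=seed, kind="feature_table",
        params={"n_cells": n_cells, "blocks": [list(b) for b in blocks],
                "missingness": missingness},
        truth={"block_map": block_map,
               "true_betas": true_betas,
               "boxcox_lambdas": lambda_truth,
               "phase_fractions": dict(phase_structure or {}),
               "gate_vertices": DEFAULT_GATES},
    )
    return table, manifest
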