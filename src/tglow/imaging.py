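"""Plate-organized multi-channel z-stacks: data model, OME-TIFF I/O, projection,
nuclear demultiplexing and per-cell crop export.

Arrays are indexed ``(channel, z, y, x)``, 0-based. On disk stacks are stored as
16-bit unsigned OME-TIFF (values clipped to [0, 65535] and rounded); in memory
everything is floating point.
"""

from __future__ import annotations

import logging
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import tifffile
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

UINT16_MAX = 65535


@dataclass
class ImageStack:
    """A CZYX voxel array with channel names and physical pixel sizes (μm)."""

    voxels: np.ndarray
    channel_names: list[str]
    pixel_size: tuple[float, float, float]  # (z, y, x) in μm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected 4-D CZYX array, got ndim={self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError("all dimensions must be >= 1")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel sizes must be positive")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")

    def channel(self, name: str) -> np.ndarray:
        """3-D (z, y, x) view of one named channel."""
        return self.voxels[self.channel_index(name)]

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), list(self.channel_names), self.pixel_size)


@dataclass(frozen=True, order=True)
class PlateAddress:
    """Identifies one field stack in the plate/row/col/field layout."""

    plate: str
    row: str
    column: str
    field: int = 1
    cycle: int = 1

    def __post_init__(self) -> None:
        if self.field < 1 or self.cycle < 1:
            raise ValueError("field and cycle are 1-based")

    def relpath(self) -> Path:
        return Path(self.plate) / self.row / self.column / f"{self.field}.ome.tiff"

    @property
    def well(self) -> str:
        return f"{self.row}{self.column}"


@dataclass
class MaskPair:
    """Cell and nucleus label images (label 0 = background)."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        if self.cell_labels.shape != self.nucleus_labels.shape:
            raise ValueError("cell and nucleus masks must share shape")

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]

    def orphan_nuclei(self) -> np.ndarray:
        """Nucleus labels with no matching cell label id."""
        nuc = np.unique(self.nucleus_labels)
        nuc = nuc[nuc > 0]
        return np.setdiff1d(nuc, self.cell_ids())


@dataclass
class CellCrop:
    cell_id: int
    voxels: np.ndarray  # CZYX with cell+nucleus masks as last two channels
    address: PlateAddress | None = None
    bbox: tuple | None = None


def _ome_metadata(stack: ImageStack) -> dict:
    pz, py, px = stack.pixel_size
    return {
        "axes": "CZYX",
        "Channel": {"Name": list(stack.channel_names)},
        "PhysicalSizeZ": pz,
        "PhysicalSizeY": py,
        "PhysicalSizeX": px,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as non-pyramidal CZYX OME-TIFF, 16-bit unsigned.

    Values outside [0, 65535] are clipped (with a warning) and rounded.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vox = stack.voxels
    if vox.max(initial=0) > UINT16_MAX or vox.min(initial=0) < 0:
        warnings.warn(
            f"{path.name}: values outside [0, {UINT16_MAX}] clipped on write",
            stacklevel=2,
        )
    data = np.clip(np.rint(vox), 0, UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(path, data, ome=True, photometric="minisblack",
                     metadata=_ome_metadata(stack))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a CZYX OME-TIFF written by :func:`write_stack`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tf.ome_metadata
    # singleton C/Z axes are squeezed by the reader; restore CZYX order
    unknown = set(axes) - set("CZYX")
    if unknown:
        raise ValueError(f"{path}: unsupported axes {axes!r}")
    for i, ax in enumerate("CZYX"):
        if ax not in axes:
            data = np.expand_dims(data, i)
            axes = axes[:i] + ax + axes[i:]
    if axes != "CZYX":
        data = np.moveaxis(data, [axes.index(a) for a in "CZYX"], range(4))
    if data.ndim != 4:
        raise ValueError(f"{path}: expected CZYX stack, got shape {data.shape}")
    names, pixel_size = _parse_ome(ome, n_channels=data.shape[0])
    return ImageStack(data.astype(np.float64), names, pixel_size)


def _parse_ome(ome_xml: str | None, n_channels: int):
    names = [f"ch{i}" for i in range(n_channels)]
    pixel_size = (1.0, 1.0, 1.0)
    if not ome_xml:
        return names, pixel_size
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is not None:
        pixel_size = (
            float(px.get("PhysicalSizeZ", 1.0)),
            float(px.get("PhysicalSizeY", 1.0)),
            float(px.get("PhysicalSizeX", 1.0)),
        )
        chan = [c.get("Name") for c in px.findall("ome:Channel", ns)]
        if len(chan) == n_channels and all(chan):
            names = list(chan)
    if len(names) != n_channels:
        raise ValueError("channel-name count does not match channel axis")
    return names, pixel_size


def write_plate_stack(root: str | Path, address: PlateAddress, stack: ImageStack) -> Path:
    return write_stack(Path(root) / address.relpath(), stack)


def enumerate_plate(root: str | Path, cycle: int = 1) -> Iterator[PlateAddress]:
    """Yield every PlateAddress under a plate/row/col/field.ome.tiff tree."""
    root = Path(root)
    pattern = re.compile(r"^(\d+)\.ome\.tiff?$")
    for tiff in sorted(root.glob("*/*/*/*.ome.tif*")):
        m = pattern.match(tiff.name)
        if not m:
            continue
        plate, row, col = tiff.parts[-4], tiff.parts[-3], tiff.parts[-2]
        yield PlateAddress(plate=plate, row=row, column=col, field=int(m.group(1)), cycle=cycle)


def read_plate_stack(root: str | Path, address: PlateAddress) -> ImageStack:
    return read_stack(Path(root) / address.relpath())


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z; metadata preserved, z becomes 1."""
    return ImageStack(
        stack.voxels.max(axis=1, keepdims=True),
        list(stack.channel_names),
        stack.pixel_size,
    )


def demultiplex_nuclear(
    stack: ImageStack,
    masks: MaskPair,
    channel: str,
    nuclear_name: str,
    nonnuclear_name: str,
) -> ImageStack:
    """Split one channel into nuclear and non-nuclear components.

    Hard mask assignment: the nuclear output keeps the source intensity where
    the nucleus label is positive and is zero elsewhere; the non-nuclear output
    is the complement. The two outputs sum to the source channel exactly.
    """
    idx = stack.channel_index(channel)
    src = stack.voxels[idx]
    nuc_mask = _broadcast_mask(masks.nucleus_labels, src.shape) > 0
    nuclear = np.where(nuc_mask, src, 0.0)
    nonnuclear = np.where(nuc_mask, 0.0, src)
    vox = np.concatenate(
        [stack.voxels[:idx], nuclear[None], nonnuclear[None], stack.voxels[idx + 1 :]],
        axis=0,
    )
    names = (
        stack.channel_names[:idx]
        + [nuclear_name, nonnuclear_name]
        + stack.channel_names[idx + 1 :]
    )
    return ImageStack(vox, names, stack.pixel_size)


def _broadcast_mask(mask: np.ndarray, shape_zyx: tuple) -> np.ndarray:
    """Accept 2-D (y, x) or 3-D (z, y, x) masks against a 3-D channel."""
    if mask.shape == shape_zyx:
        return mask
    if mask.ndim == 2 and mask.shape == shape_zyx[1:]:
        return np.broadcast_to(mask, shape_zyx)
    raise ValueError(f"mask shape {mask.shape} incompatible with image {shape_zyx}")


def extract_cell_crops(stack: ImageStack, masks: MaskPair, address: PlateAddress | None = None) -> list[CellCrop]:
    """Crop every labelled cell to its bounding box, appending binary cell and
    nucleus masks as the last two channels."""
    cell3d = _broadcast_mask(masks.cell_labels, stack.shape_zyx)
    nuc3d = _broadcast_mask(masks.nucleus_labels, stack.shape_zyx)
    crops = []
    slices = ndi.find_objects(cell3d.astype(np.int64))
    for label, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        box = (slice(None),) + sl
        sub = stack.voxels[box]
        cell_bin = (cell3d[sl] == label).astype(np.float64)
        nuc_bin = ((nuc3d[sl] == label) & (cell3d[sl] == label)).astype(np.float64)
        crops.append(
            CellCrop(
                cell_id=label,
                voxels=np.concatenate([sub, cell_bin[None], nuc_bin[None]], axis=0),
                address=address,
                bbox=tuple((s.start, s.stop) for s in sl),
            )
        )
    return crops


def export_cell_crops(
    stack: ImageStack,
    masks: MaskPair,
    path: str | Path,
    address: PlateAddress | None = None,
) -> Path:
    """Write per-cell crops to an HDF5 container, one group per cell.

    Layout: ``/<plate>/<well>/<field>/cell_<id>`` → CZYX dataset with the cell
    and nucleus masks appended as the last two channels.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    crops = extract_cell_crops(stack, masks, address)
    if not crops:
        warnings.warn("no cells in masks; writing empty crop container", stacklevel=2)
    addr = address or PlateAddress("plate", "r", "c", 1)
    with h5py.File(path, "w") as f:
        base = f.require_group(f"{addr.plate}/{addr.well}/{addr.field}")
        base.attrs["channel_names"] = list(stack.channel_names) + ["cell_mask", "nucleus_mask"]
        for crop in crops:
            ds = base.create_dataset(f"cell_{crop.cell_id}", data=crop.voxels)
            ds.attrs["cell_id"] = crop.cell_id
            ds.attrs["bbox"] = np.asarray(crop.bbox).ravel()
    return path


def translate_int(arr: np.ndarray, offset: Sequence[int]) -> np.ndarray:
    """Integer-voxel translation with zero fill (no wrap-around)."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for size, off in zip(arr.shape, offset):
        off = int(off)
        if abs(off) >= size:
            return out
        if off >= 0:
            src.append(slice(0, size - off))
            dst.append(slice(off, size))
        else:
            src.append(slice(-off, size))
            dst.append(slice(0, size + off))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def finalize_image(
    stack_c1: ImageStack,
    stack_c2: ImageStack | None = None,
    flatfields: dict | None = None,
    offset: Sequence[int] | None = None,
    scaling=None,
    plate: str | None = None,
    demux_spec: tuple[str, str, str] | None = None,
    masks: MaskPair | None = None,
    project: bool = False,
) -> ImageStack:
    """Compose the restoration steps into one analysis-ready stack.

    Fixed order: flatfield correction → translation of cycle-2 channels onto
    cycle 1 → channel concatenation → nuclear demultiplexing → batch scaling →
    optional max projection. Output channel order is cycle-1 channels followed
    by cycle-2 channels (with any demultiplexed pair replacing its source
    in place). Deterministic for fixed inputs.

    Parameters
    ----------
    flatfields : mapping channel name → FlatfieldModel (applied per channel)
    offset : (dz, dy, dx) integer translation applied to every cycle-2 channel
    scaling : ScalingModel covering this plate's channels, or None
    demux_spec : (source_channel, nuclear_name, nonnuclear_name); needs masks
    """
    from . import flatfield as ff_mod
    from . import scaling as sc_mod

    def correct(stack: ImageStack) -> ImageStack:
        out = stack
        for name in stack.channel_names:
            model = (flatfields or {}).get(name)
            if model is not None:
                out = ff_mod.apply_flatfield(out, model)
        return out

    c1 = correct(stack_c1)
    if stack_c2 is not None:
        c2 = correct(stack_c2)
        if offset is not None:
            shifted = np.stack([translate_int(ch, offset) for ch in c2.voxels])
            c2 = ImageStack(shifted, list(c2.channel_names), c2.pixel_size)
        merged = ImageStack(
            np.concatenate([c1.voxels, c2.voxels], axis=0),
            list(c1.channel_names) + list(c2.channel_names),
            c1.pixel_size,
        )
    else:
        merged = c1

    if demux_spec is not None:
        if masks is None:
            raise ValueError("demultiplexing requires masks")
        merged = demultiplex_nuclear(merged, masks, *demux_spec)

    if scaling is not None:
        if plate is None:
            raise ValueError("batch scaling requires the plate id")
        merged = sc_mod.apply_scaling(merged, scaling, plate=plate)

    if project:
        merged = max_project(merged)
    return merged
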