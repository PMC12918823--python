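"""Plate/batch intensity normalization anchored on common-control wells.

Staining and acquisition drift between plates shows up as a multiplicative
offset in foreground intensity. A shared control line imaged on every plate
anchors a per-plate, per-channel scale factor; because background intensity
is stable across plates, the correction is weighted by a sigmoid
"soft threshold" in pixel intensity

    y(x) = 1 / (1 + exp(-a (x - b)))

whose slope a and bias b are solved so that y(x1) = y1 (≈0 at the background
anchor) and y(x2) = y2 (≈1 at the foreground anchor). Background pixels are
thus left untouched while foreground pixels are fully divided by the scale
factor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .imaging import ImageStack

DEFAULT_Y1 = 1e-3
DEFAULT_Y2 = 1 - 1e-3


@dataclass
class SoftThreshold:
    """Sigmoid weight in intensity, pinned to (x1, y1) and (x2, y2)."""

    x1: float
    x2: float
    y1: float = DEFAULT_Y1
    y2: float = DEFAULT_Y2
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2):
            raise ValueError("anchors must satisfy x1 < x2")
        if not (0 < self.y1 < self.y2 < 1):
            raise ValueError("weights must satisfy 0 < y1 < y2 < 1")
        L1 = np.log(1.0 / self.y1 - 1.0)
        L2 = np.log(1.0 / self.y2 - 1.0)
        # slope: a = (L2 - L1) / (x1 - x2); bias solves y(x1)=y1, y(x2)=y2
        self.a = (L2 - L1) / (self.x1 - self.x2)
        self.b = (self.x1 * L2 - self.x2 * L1) / (L2 - L1)
        if self.a <= 0:
            raise ValueError("degenerate anchors: nonpositive slope")

    def weight(self, x) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.a * (np.asarray(x, dtype=np.float64) - self.b)))

    def as_dict(self) -> dict:
        return {"x1": self.x1, "x2": self.x2, "y1": self.y1, "y2": self.y2,
                "a": self.a, "b": self.b}


def soft_threshold_params(x1: float, x2: float,
                          y1: float = DEFAULT_Y1, y2: float = DEFAULT_Y2) -> SoftThreshold:
    """Solve the sigmoid slope and bias from the two intensity anchors."""
    return SoftThreshold(x1=x1, x2=x2, y1=y1, y2=y2)


@dataclass
class ChannelScaling:
    """Scaling entry for one plate + channel."""

    scale_factor: float
    soft_threshold: SoftThreshold | None
    dynamic_range_factor: float = 1.0
    n_control_cells: int = 0


@dataclass
class ScalingModel:
    """Per plate+channel scale factors with sigmoid soft thresholds."""

    entries: dict[tuple[str, str], ChannelScaling]
    single_plate: bool = False

    def get(self, plate: str, channel: str) -> ChannelScaling:
        key = (plate, channel)
        if key not in self.entries:
            raise KeyError(f"no scaling entry for plate={plate!r} channel={channel!r}")
        return self.entries[key]

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "single_plate": self.single_plate,
            "entries": [
                {
                    "plate": p, "channel": c,
                    "scale_factor": e.scale_factor,
                    "dynamic_range_factor": e.dynamic_range_factor,
                    "n_control_cells": e.n_control_cells,
                    "soft_threshold": e.soft_threshold.as_dict() if e.soft_threshold else None,
                }
                for (p, c), e in self.entries.items()
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingModel":
        d = json.loads(Path(path).read_text())
        entries = {}
        for e in d["entries"]:
            st = e["soft_threshold"]
            entries[(e["plate"], e["channel"])] = ChannelScaling(
                scale_factor=e["scale_factor"],
                soft_threshold=SoftThreshold(st["x1"], st["x2"], st["y1"], st["y2"]) if st else None,
                dynamic_range_factor=e["dynamic_range_factor"],
                n_control_cells=e["n_control_cells"],
            )
        return cls(entries, d.get("single_plate", False))


REQUIRED_COLUMNS = ("plate", "channel", "mean_intensity",
                    "upper_quartile_intensity", "otsu_threshold")


def estimate_scaling(
    control_features: pd.DataFrame,
    registration_pass: pd.Series | np.ndarray | None = None,
    target_foreground_max: float = 0.9 * 65535,
    y1: float = DEFAULT_Y1,
    y2: float = DEFAULT_Y2,
) -> ScalingModel:
    """Fit a ScalingModel from per-cell control-well intensity summaries.

    ``control_features`` has one row per control cell × channel with columns
    plate, channel, mean_intensity (per-cell mean), upper_quartile_intensity
    (75th percentile of the cell-masked source image, the background anchor)
    and otsu_threshold (Otsu threshold of the cell's image, the foreground
    anchor). Rows from cells failing registration QC are dropped first.

    The scale factor for a plate+channel is its mean control intensity over
    the grand mean across plates, so factors average to ~1 and no plate is
    privileged as reference. With a single plate the per-plate offset and
    sigmoid are omitted and only the dynamic-range scaling is retained.
    """
    df = control_features
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"control features missing columns: {missing}")
    if registration_pass is not None:
        df = df.loc[np.asarray(registration_pass, dtype=bool)]
    if df.empty:
        raise ValueError("no control cells after the registration filter")

    plates = sorted(df["plate"].unique())
    single_plate = len(plates) == 1
    entries: dict[tuple[str, str], ChannelScaling] = {}
    for channel, chan_df in df.groupby("channel", sort=True):
        per_plate_mean = chan_df.groupby("plate")["mean_intensity"].mean()
        grand_mean = per_plate_mean.mean()
        for plate in plates:
            if plate not in per_plate_mean.index:
                raise ValueError(f"plate {plate!r} has no control cells for {channel!r}")
            sub = chan_df[chan_df["plate"] == plate]
            s = 1.0 if single_plate else float(per_plate_mean[plate] / grand_mean)
            x1 = float(sub["upper_quartile_intensity"].median())
            x2 = float(sub["otsu_threshold"].median())
            st: SoftThreshold | None = None
            if not single_plate:
                if x1 >= x2:
                    warnings.warn(
                        f"plate {plate} channel {channel}: background anchor "
                        f">= foreground anchor; falling back to unweighted scaling",
                        stacklevel=2)
                else:
                    st = SoftThreshold(x1, x2, y1, y2)
            # dynamic-range factor: dividing by it maps the high quantile of
            # control foreground onto ~90% of the 16-bit range
            fg_hi = float(np.quantile(sub["mean_intensity"], 0.999))
            dr = fg_hi / target_foreground_max if fg_hi > 0 else 1.0
            entries[(plate, channel)] = ChannelScaling(
                scale_factor=s,
                soft_threshold=st,
                dynamic_range_factor=dr,
                n_control_cells=len(sub),
            )
    return ScalingModel(entries, single_plate=single_plate)


def scale_pixels(values: np.ndarray, entry: ChannelScaling,
                 apply_dynamic_range: bool = False) -> np.ndarray:
    """Apply the soft-thresholded batch correction to raw intensities.

    Per pixel the effective factor interpolates between 1 (background,
    weight→0) and the full scale factor s (foreground, weight→1):

        s_eff = 1 + w(x) · (s − 1);   out = x / s_eff
    """
    x = np.asarray(values, dtype=np.float64)
    s = entry.scale_factor
    if entry.soft_threshold is None or s == 1.0:
        out = x / s
    else:
        w = entry.soft_threshold.weight(x)
        out = x / (1.0 + w * (s - 1.0))
        # strong factors can locally reorder intensities inside the sigmoid
        # transition band; report how much of the range is affected
        probe = np.linspace(x.min(), x.max(), 512)
        wp = entry.soft_threshold.weight(probe)
        frac = float((np.diff(probe / (1.0 + wp * (s - 1.0))) < 0).mean())
        if frac > 0:
            logger.info("soft-threshold scaling (s=%.3g) non-monotone over "
                        "%.1f%% of the intensity range", s, 100 * frac)
    if apply_dynamic_range and entry.dynamic_range_factor > 0:
        out = out / entry.dynamic_range_factor
    return out


def apply_scaling(stack: ImageStack, model: ScalingModel, plate: str,
                  apply_dynamic_range: bool = False) -> ImageStack:
    """Scale every channel of a stack by its plate+channel entry."""
    vox = stack.voxels.copy()
    for i, name in enumerate(stack.channel_names):
        entry = model.get(plate, name)
        vox[i] = scale_pixels(vox[i], entry, apply_dynamic_range)
    return ImageStack(vox, list(stack.channel_names), stack.pixel_size)
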