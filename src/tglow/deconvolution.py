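"""Richardson–Lucy restoration with an empirical PSF, and common-max
intensity rescaling so 16-bit storage does not clip restored intensities.

The multiplicative Richardson–Lucy update is

    u_{t+1} = u_t · ( (d / (u_t ∗ P)) ∗ P̂ )

where d is the observed image, P the PSF kernel and P̂ its mirror. To avoid
circular wrap-around the image is reflect-padded by the kernel half-support
before the FFT convolutions and cropped afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .imaging import ImageStack
from .psf import PSFModel

# printed pipeline default for the shared post-deconvolution maximum
DEFAULT_COMMON_MAX = 5 * 65335  # 326675

_EPS = 1e-12


def _rl_single(channel: np.ndarray, kernel: np.ndarray, iterations: int) -> np.ndarray:
    pad = [(s // 2, s // 2) for s in kernel.shape]
    d = np.pad(channel, pad, mode="reflect")
    mirrored = kernel[::-1, ::-1, ::-1]
    u = np.full_like(d, max(d.mean(), _EPS))
    for _ in range(iterations):
        blurred = fftconvolve(u, kernel, mode="same")
        ratio = d / np.maximum(blurred, _EPS)
        u = u * fftconvolve(ratio, mirrored, mode="same")
        np.clip(u, 0.0, None, out=u)
    crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pad, channel.shape))
    return u[crop]


def richardson_lucy(stack: ImageStack, psf: PSFModel, iterations: int = 100) -> ImageStack:
    """Deconvolve every channel with the PSF kernel; returns floating point.

    The kernel is normalized to unit sum internally so total flux is
    approximately conserved. Output is nonnegative.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    kernel = np.asarray(psf.kernel, dtype=np.float64)
    if kernel.sum() <= 0:
        raise ValueError("PSF kernel must have positive mass")
    if any(k > s for k, s in zip(kernel.shape, stack.shape_zyx)):
        raise ValueError("PSF larger than the image")
    kernel = kernel / kernel.sum()
    out = np.stack([_rl_single(ch, kernel, iterations) for ch in stack.voxels])
    return ImageStack(out, list(stack.channel_names), stack.pixel_size)


def rescale_common_max(
    stacks: list[ImageStack],
    common_max: float = DEFAULT_COMMON_MAX,
) -> tuple[list[ImageStack], float]:
    """Scale a deconvolved run by one shared factor so the global maximum over
    all stacks equals ``common_max``; relative intensities across stacks are
    preserved. Returns the rescaled (float) stacks and the factor applied."""
    if not stacks:
        raise ValueError("no stacks to rescale")
    global_max = max(float(s.voxels.max()) for s in stacks)
    if not np.isfinite(global_max) or global_max <= 0:
        raise ValueError("all-zero or non-finite input; cannot rescale")
    factor = common_max / global_max
    out = [
        ImageStack(s.voxels * factor, list(s.channel_names), s.pixel_size)
        for s in stacks
    ]
    return out, factor
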